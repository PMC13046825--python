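"""LUV dye-release kinetics: normalization, asymmetric sigmoid fitting, maximal rate.

Large unilamellar vesicles loaded with an ANTS/DPX dye-quencher pair report
pore formation as a fluorescence increase. Raw kinetic traces are normalized
to percent permeabilization against the plate's own controls,

    %perm = (F - F0) / (F100 - F0) * 100,

where F0 is the minimum buffer-control reading over the whole assay and F100
the mean reading of vesicles solubilized in 1% CHAPS detergent. Normalized
kinetics are then fit with an asymmetric five-parameter sigmoid

    y(x) = B + (T - B) / (1 + (E/x)^H)^S,        0 < S <= 10, T >= B,

whose asymmetry exponent S lets the fast-rise/slow-saturation shape typical
of permeabilization kinetics be captured. The slope at the inflection point
("maximal rate") has the closed form

    dy/dx |_{x_ip} = H*S*(T-B) * ((H+1)/(H*S-1))^((H+1)/H)
                     / ( E * (1 + (H+1)/(H*S-1))^(S+1) ),
    x_ip = E * ((H*S-1)/(H+1))^(1/H),

defined whenever H*S > 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DataError,
    DegenerateControlsError,
    NoInflectionError,
    ParameterDomainError,
    PlateMapError,
)
from .io_formats import Plate

MIN_TIMEPOINTS = 8


@dataclass(frozen=True)
class KineticTrace:
    """A time-ordered fluorescence series for one well or condition."""

    time: np.ndarray
    signal: np.ndarray
    condition: str = ""
    replicate: str | int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        if self.time.ndim != 1 or self.time.shape != self.signal.shape:
            raise DataError("time and signal must be 1-D arrays of equal length")
        if self.time.size < MIN_TIMEPOINTS:
            raise DataError(
                f"kinetic trace needs >= {MIN_TIMEPOINTS} timepoints, got {self.time.size}"
            )
        if np.any(np.diff(self.time) <= 0):
            raise DataError("time must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise DataError("missing/non-finite readings within the series")


@dataclass(frozen=True)
class NormalizationRefs:
    """0% / 100% fluorescence references from the plate's own controls."""

    f0: float
    f100: float

    def __post_init__(self) -> None:
        if not self.f100 > self.f0:
            raise DegenerateControlsError(
                f"degenerate controls: f100 ({self.f100}) must exceed f0 ({self.f0})"
            )


@dataclass
class Fit5PL:
    """Five-parameter sigmoid fit with derived inflection quantities.

    ``x_ip`` and ``max_rate`` are populated only when H*S > 1 (the curve has
    an inflection on x > 0); otherwise they are None.
    """

    b: float
    t: float
    e: float
    h: float
    s: float
    rss: float = float("nan")
    converged: bool = False
    degenerate: bool = False
    n_points: int = 0
    x_ip: float | None = field(default=None)
    max_rate: float | None = field(default=None)

    def params(self) -> tuple[float, float, float, float, float]:
        return (self.b, self.t, self.e, self.h, self.s)


def five_pl(x, b: float, t: float, e: float, h: float, s: float):
    """Evaluate the asymmetric sigmoid; the x -> 0+ limit (B) is used at x = 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        y = b + (t - b) / (1.0 + (e / x) ** h) ** s
    return np.where(x > 0, y, b)


def validate_5pl_params(b: float, t: float, e: float, h: float, s: float) -> None:
    if not (t >= b):
        raise ParameterDomainError(f"T ({t}) must be >= B ({b})")
    if not (0 < s <= 10):
        raise ParameterDomainError(f"S must satisfy 0 < S <= 10, got {s}")
    if not h > 0:
        raise ParameterDomainError(f"H must be > 0, got {h}")
    if not e > 0:
        raise ParameterDomainError(f"E must be > 0, got {e}")


def compute_refs(plate: Plate) -> NormalizationRefs:
    """Normalization references from the plate's control wells.

    F0 is the global minimum over all buffer-well readings across the whole
    assay; F100 is the mean over all detergent-max (1% CHAPS) readings across
    the whole assay.
    """
    buffer_wells = plate.plate_map.wells_for_role("buffer")
    chaps_wells = plate.plate_map.wells_for_role("detergent_max")
    if not buffer_wells:
        raise PlateMapError("plate map has no buffer wells")
    if not chaps_wells:
        raise PlateMapError("plate map has no detergent_max wells")
    f0 = float(plate.signals[buffer_wells].to_numpy().min())
    f100 = float(plate.signals[chaps_wells].to_numpy().mean())
    return NormalizationRefs(f0=f0, f100=f100)


def normalize_percent(trace: KineticTrace, refs: NormalizationRefs) -> KineticTrace:
    """Affine map of raw fluorescence to percent permeabilization.

    Values outside [0, 100] are preserved (the detergent reference is a mean,
    so samples may legitimately exceed it); clipping, if any, belongs to the
    synergy stage.
    """
    pct = (trace.signal - refs.f0) / (refs.f100 - refs.f0) * 100.0
    return replace(trace, signal=pct)


def _shift_time_origin(time: np.ndarray, policy: str = "midpoint") -> np.ndarray:
    """Reassign an exact t=0 first read, where the sigmoid is singular.

    ``midpoint`` moves it to the midpoint of the first interval; ``drop`` is
    handled by the caller; ``keep`` leaves it (the model evaluates to B there).
    """
    if time[0] != 0.0 or policy == "keep":
        return time
    if policy == "midpoint":
        out = time.copy()
        out[0] = time[1] / 2.0
        return out
    raise ValueError(f"unknown time-origin policy {policy!r}")


def fit_5pl(
    trace: KineticTrace,
    init: Fit5PL | None = None,
    time_origin: str = "midpoint",
) -> Fit5PL:
    """Bounded least-squares fit of the five-parameter sigmoid.

    T >= B is enforced by fitting the rise amplitude T - B on [0, inf) rather
    than rejecting iterates. Initialization: B0=min(y), T0=max(y), E0=time of
    half-rise by linear interpolation, H0=S0=1. A constant trace returns a
    degenerate, non-converged fit with T ~= B instead of raising.
    """
    x = _shift_time_origin(trace.time, time_origin)
    y = trace.signal
    if x.size < 6:
        raise DataError("fewer free points than parameters")
    ymin, ymax = float(y.min()), float(y.max())
    rng = ymax - ymin
    if rng <= 0:
        return Fit5PL(
            b=ymin, t=ymin, e=float(np.median(x)), h=1.0, s=1.0,
            rss=0.0, converged=False, degenerate=True, n_points=x.size,
        )
    # half-rise time by linear interpolation for E0
    half = ymin + rng / 2.0
    above = np.nonzero(y >= half)[0]
    if above.size and above[0] > 0:
        i = above[0]
        frac = (half - y[i - 1]) / (y[i] - y[i - 1])
        e0 = x[i - 1] + frac * (x[i] - x[i - 1])
    else:
        e0 = float(np.median(x))
    e0 = float(np.clip(e0, x[0], x[-1]))

    if init is not None:
        p0 = [init.b, max(init.t - init.b, 0.0), init.e, init.h, init.s]
    else:
        p0 = [ymin, rng, e0, 1.0, 1.0]
    lo = [ymin - rng, 0.0, x[0] * 1e-3, 1e-6, 1e-6]
    hi = [ymax, 2.0 * rng, 10.0 * x[-1], 20.0, 10.0]
    p0 = np.clip(p0, lo, hi)

    def resid(p):
        b, dt, e, h, s = p
        return five_pl(x, b, b + dt, e, h, s) - y

    sol = least_squares(
        resid, p0, bounds=(lo, hi), method="trf",
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000,
    )
    b, dt, e, h, s = sol.x
    fit = Fit5PL(
        b=float(b), t=float(b + dt), e=float(e), h=float(h), s=float(s),
        rss=float(np.sum(sol.fun**2)),
        converged=bool(sol.success),
        degenerate=bool(dt < 1e-8 * max(1.0, abs(ymax) + abs(ymin))),
        n_points=int(x.size),
    )
    if fit.h * fit.s > 1.0:
        rate, x_ip = maximal_rate(fit)
        fit.max_rate, fit.x_ip = rate, x_ip
    return fit


def maximal_rate(fit: Fit5PL) -> tuple[float, float]:
    """Closed-form slope at the inflection point and its location.

    Derived by setting the second derivative of the sigmoid to zero; requires
    H*S > 1, otherwise the curve is inflection-free on x > 0 and a
    :class:`NoInflectionError` is raised.
    """
    b, t, e, h, s = fit.params()
    q = h * s - 1.0
    if q <= 0:
        raise NoInflectionError(f"H*S = {h * s:.6g} <= 1: maximal rate undefined")
    x_ip = e * (q / (h + 1.0)) ** (1.0 / h)
    rate = (
        h * s * (t - b) * ((h + 1.0) / q) ** ((h + 1.0) / h)
        / (e * (1.0 + (h + 1.0) / q) ** (s + 1.0))
    )
    return float(rate), float(x_ip)


def endpoint_percent(trace: KineticTrace, k_last: int = 1) -> float:
    """Mean of the final ``k_last`` normalized readings (default: last reading)."""
    if k_last < 1 or k_last > trace.signal.size:
        raise DataError(
            f"k_last must be in [1, {trace.signal.size}], got {k_last}"
        )
    return float(trace.signal[-k_last:].mean())


def fit_plate(
    plate: Plate,
    average_replicates: bool = True,
    k_last: int = 1,
    conditions: Sequence[str] | None = None,
) -> list[dict]:
    """Normalize and fit every sample condition of a LUV plate.

    Replicate wells are averaged before fitting by default (matching how
    triplicate kinetic data are usually reported); with
    ``average_replicates=False`` each well is fit separately.
    """
    refs = compute_refs(plate)
    results = []
    names = conditions or plate.plate_map.conditions("sample")
    for cond in names:
        wells = plate.plate_map.wells_for_condition(cond)
        groups = (
            [(None, plate.condition_mean(cond))]
            if average_replicates
            else [(w, plate.well(w)) for w in wells]
        )
        for well, sig in groups:
            raw = KineticTrace(plate.axis, sig, condition=cond, replicate=well)
            norm = normalize_percent(raw, refs)
            fit = fit_5pl(norm)
            results.append(
                {
                    "condition": cond,
                    "well": well if well is not None else "replicate_mean",
                    "endpoint_percent": endpoint_percent(norm, k_last=k_last),
                    "f0": refs.f0,
                    "f100": refs.f100,
                    "b": fit.b, "t": fit.t, "e": fit.e, "h": fit.h, "s": fit.s,
                    "rss": fit.rss,
                    "converged": fit.converged,
                    "degenerate": fit.degenerate,
                    "x_ip": fit.x_ip,
                    "max_rate": fit.max_rate,
                }
            )
    return results
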