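"""Microscale thermophoresis: one-phase decay fits, temperature jump, EC50.

An MST timetrace records the fluorescence of labeled protein before and
after the IR laser switches on (t = 0 here). The heated phase follows a
one-phase exponential decay

    y(x) = (Y0 - Yplateau) * exp(-K x) + Yplateau,

fit only inside a stated window (5-35 s by default) to avoid the initial
temperature-jump transient and late convective drift. The decay constant can
also be read off any single point algebraically:

    K = -ln((y - Yplateau) / (Y0 - Yplateau)) / x.

Binding is quantified from the temperature-jump response (mean fluorescence
after minus before IR-on) as a function of ligand concentration, fit with a
four-parameter log-logistic (Hill) curve to estimate the EC50, or summarized
as a linear concentration-response slope when the titration does not span a
full transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DataError, ParameterDomainError

DEFAULT_FIT_WINDOW = (5.0, 35.0)
DEFAULT_PRE_WINDOW = (-1.0, 0.0)
DEFAULT_POST_WINDOW = (0.5, 1.5)


@dataclass(frozen=True)
class MstTrace:
    """Fluorescence timetrace for one capillary; IR-on at t = 0."""

    time: np.ndarray
    fluorescence: np.ndarray
    concentration: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(
            self, "fluorescence", np.asarray(self.fluorescence, dtype=float)
        )
        if self.time.shape != self.fluorescence.shape or self.time.ndim != 1:
            raise DataError("time and fluorescence must be 1-D arrays of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise DataError("time must be strictly increasing")


@dataclass
class DecayFit:
    y0: float
    plateau: float
    k: float
    window: tuple[float, float]
    rss: float = float("nan")
    converged: bool = False
    non_decaying: bool = False


def one_phase_decay(x, y0: float, plateau: float, k: float):
    x = np.asarray(x, dtype=float)
    return (y0 - plateau) * np.exp(-k * x) + plateau


def fit_decay(
    trace: MstTrace, window: tuple[float, float] = DEFAULT_FIT_WINDOW
) -> DecayFit:
    """Least-squares one-phase decay fit restricted to the stated time window."""
    lo, hi = window
    mask = (trace.time >= lo) & (trace.time <= hi)
    x, y = trace.time[mask], trace.fluorescence[mask]
    if x.size < 6:
        raise DataError(f"need >= 6 points inside window {window}, got {x.size}")
    span = float(y.max() - y.min())
    if span == 0.0:
        return DecayFit(
            y0=float(y[0]), plateau=float(y[0]), k=0.0, window=window,
            rss=0.0, converged=False, non_decaying=True,
        )
    # log-linear initial guess for K over the window span
    k0 = max(1.0 / (x[-1] - x[0]), 1e-6)
    p0 = [float(y[0]), float(y[-1]), k0]
    sol = least_squares(
        lambda p: one_phase_decay(x, *p) - y,
        p0,
        bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
        method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000,
    )
    y0, plateau, k = (float(v) for v in sol.x)
    return DecayFit(
        y0=y0, plateau=plateau, k=k, window=window,
        rss=float(np.sum(sol.fun**2)),
        converged=bool(sol.success),
        non_decaying=bool(k <= 1e-12 or abs(y0 - plateau) < 1e-12 * max(1.0, abs(y0))),
    )


def decay_constant(x: float, y: float, fit: DecayFit) -> float:
    """Algebraic inverse of the decay model at a single point (x > 0)."""
    if x <= 0:
        raise ParameterDomainError(f"x must be > 0, got {x}")
    denom = fit.y0 - fit.plateau
    if denom == 0:
        raise ParameterDomainError("Y0 equals Yplateau: decay constant undefined")
    ratio = (y - fit.plateau) / denom
    if not (0.0 < ratio <= 1.0):
        raise ParameterDomainError(
            f"(y - Yplateau)/(Y0 - Yplateau) = {ratio:.6g} outside (0, 1]"
        )
    return float(-np.log(ratio) / x)


def temperature_jump(
    trace: MstTrace,
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
    post_window: tuple[float, float] = DEFAULT_POST_WINDOW,
) -> float:
    """Mean fluorescence in the post-IR window minus the pre-IR window."""
    if pre_window[1] > post_window[0] and post_window[1] > pre_window[0]:
        raise DataError(f"windows {pre_window} and {post_window} overlap")
    vals = []
    for win in (pre_window, post_window):
        mask = (trace.time >= win[0]) & (trace.time <= win[1])
        if mask.sum() < 3:
            raise DataError(f"window {win} holds {int(mask.sum())} points, need >= 3")
        vals.append(float(trace.fluorescence[mask].mean()))
    return vals[1] - vals[0]


@dataclass
class HillFit:
    """Four-parameter log-logistic concentration-response fit.

    ``ec50_ci95`` is a Wald interval propagated from the fitted
    log10(EC50) standard error; (nan, nan) when not estimable.
    """

    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float = float("nan")
    converged: bool = False
    degenerate: bool = False
    extrapolated: bool = False
    ec50_ci95: tuple[float, float] = (float("nan"), float("nan"))


def hill_curve(conc, bottom: float, top: float, ec50: float, hill: float):
    """Log-logistic response; the c -> 0 limit (bottom) is used at c = 0."""
    c = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        y = bottom + (top - bottom) / (1.0 + (ec50 / c) ** hill)
    return np.where(c > 0, y, bottom)


def dose_response_ec50(concentrations, responses) -> HillFit:
    """Estimate EC50 by fitting the Hill curve to (concentration, response) pairs.

    EC50 is fit on a log scale for conditioning. A response span too small to
    define a transition yields a degenerate flag; an EC50 outside the tested
    concentration range is flagged extrapolated rather than rejected.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape or c.ndim != 1:
        raise DataError("concentrations and responses must be 1-D and equal length")
    if c.size < 5:
        raise DataError(f"need >= 5 concentrations, got {c.size}")
    if np.any(c < 0):
        raise DataError("concentrations must be >= 0")
    pos = c[c > 0]
    if pos.size < 3:
        raise DataError("need >= 3 non-zero concentrations")
    span = float(r.max() - r.min())
    scale = max(abs(float(r.max())), abs(float(r.min())), 1.0)
    if span < 1e-12 * scale:
        return HillFit(
            bottom=float(r.mean()), top=float(r.mean()),
            ec50=float(np.sqrt(pos.min() * pos.max())), hill=1.0,
            rss=0.0, converged=False, degenerate=True,
        )
    lg_lo, lg_hi = np.log10(pos.min()), np.log10(pos.max())
    p0 = [float(r[np.argmin(c)]), float(r[np.argmax(c)]), (lg_lo + lg_hi) / 2.0, 1.0]
    sol = least_squares(
        lambda p: hill_curve(c, p[0], p[1], 10.0 ** p[2], p[3]) - r,
        p0,
        bounds=(
            [-np.inf, -np.inf, lg_lo - 6.0, 0.01],
            [np.inf, np.inf, lg_hi + 6.0, 20.0],
        ),
        method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000,
    )
    bottom, top, lg_ec50, hill = (float(v) for v in sol.x)
    ec50 = 10.0 ** lg_ec50
    ci = (float("nan"), float("nan"))
    dof = c.size - 4
    if dof > 0:
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * np.sum(sol.fun**2) / dof
            se_lg = float(np.sqrt(abs(cov[2, 2])))
            lo_e, hi_e = lg_ec50 - 1.96 * se_lg, lg_ec50 + 1.96 * se_lg
            ci = (
                float(10.0 ** max(lo_e, -300.0)),
                float("inf") if hi_e > 300.0 else float(10.0 ** hi_e),
            )
        except np.linalg.LinAlgError:
            pass
    return HillFit(
        bottom=bottom, top=top, ec50=ec50, hill=hill,
        rss=float(np.sum(sol.fun**2)),
        converged=bool(sol.success),
        extrapolated=bool(ec50 < pos.min() or ec50 > pos.max()),
        ec50_ci95=ci,
    )


def response_slope(concentrations, responses, log_x: bool = False) -> float:
    """Ordinary least-squares slope of response vs concentration.

    Linear concentration axis by default; ``log_x=True`` regresses on
    log10(concentration) instead (zero doses are then rejected).
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape or c.size < 3:
        raise DataError("need >= 3 (concentration, response) points")
    if log_x:
        if np.any(c <= 0):
            raise DataError("log-axis slope requires strictly positive concentrations")
        c = np.log10(c)
    slope, _ = np.polyfit(c, r, 1)
    return float(slope)
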