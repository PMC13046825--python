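"""Thermal-shift (differential scanning fluorimetry) melting temperatures.

SYPRO Orange fluorescence rises as a protein unfolds along a 25 -> 95 °C
ramp; the apparent melting temperature Tm is the temperature at which the
first derivative dF/dT is maximal. The derivative is taken by central
differences after optional moving-average smoothing (vendor software
differentiates normalized data the same way). Boundary maxima and flat
derivative ties are flagged rather than silently reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, NoTransitionError

MIN_MELT_POINTS = 20
DEFAULT_SMOOTH_WINDOW = 5


@dataclass(frozen=True)
class MeltCurve:
    temperature: np.ndarray
    fluorescence: np.ndarray
    condition: str = ""
    replicate: str | int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "temperature", np.asarray(self.temperature, dtype=float))
        object.__setattr__(self, "fluorescence", np.asarray(self.fluorescence, dtype=float))
        if self.temperature.shape != self.fluorescence.shape or self.temperature.ndim != 1:
            raise DataError("temperature and fluorescence must be 1-D and equal length")
        if self.temperature.size < MIN_MELT_POINTS:
            raise DataError(f"melt curve needs >= {MIN_MELT_POINTS} points")
        if np.any(np.diff(self.temperature) <= 0):
            raise DataError("temperature must be strictly increasing")


@dataclass
class TmResult:
    tm: float
    index: int
    boundary: bool  # argmax at the first/last point: unreliable
    tie: bool       # flat derivative plateau at the maximum
    smooth_window: int


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    half = window // 2
    padded = np.pad(y, half, mode="reflect")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def melt_tm(curve: MeltCurve, smooth_window: int = DEFAULT_SMOOTH_WINDOW) -> TmResult:
    """Tm as the temperature of the maximal (smoothed) first derivative.

    ``smooth_window`` is an odd moving-average width in points (1 = raw). A
    curve with no positive derivative anywhere has no unfolding transition
    and raises :class:`NoTransitionError`. Ties report the first maximum with
    the tie flag set; maxima at the ramp boundary set the boundary flag.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise DataError(f"smooth_window must be a positive odd count, got {smooth_window}")
    if smooth_window >= curve.temperature.size:
        raise DataError("smooth_window must be smaller than the series length")
    f = _moving_average(curve.fluorescence, smooth_window)
    deriv = np.gradient(f, curve.temperature)
    i = int(np.argmax(deriv))
    dmax = deriv[i]
    if dmax <= 0:
        raise NoTransitionError("no positive dF/dT: curve shows no melting transition")
    tol = 1e-9 * abs(dmax)
    tie = int(np.sum(deriv >= dmax - tol)) > 1
    return TmResult(
        tm=float(curve.temperature[i]),
        index=i,
        boundary=bool(i == 0 or i == curve.temperature.size - 1),
        tie=tie,
        smooth_window=smooth_window,
    )


@dataclass
class DeltaTm:
    delta: float
    condition_tms: list[float]
    reference_tms: list[float]


def delta_tm(condition_tms, reference_tms) -> DeltaTm:
    """Mean Tm difference between a condition and its reference.

    Per-replicate values are retained so downstream statistics (paired t,
    ANOVA) can be run externally.
    """
    cond = [float(v) for v in condition_tms]
    ref = [float(v) for v in reference_tms]
    if not cond or not ref:
        raise DataError("need >= 1 replicate Tm per group")
    return DeltaTm(
        delta=float(np.mean(cond) - np.mean(ref)),
        condition_tms=cond,
        reference_tms=ref,
    )
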