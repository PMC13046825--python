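"""Bliss-independence synergy scoring on endpoint dose matrices.

Two agents acting independently on vesicle permeabilization are expected to
combine as probabilities: e = a + b - a*b, where a and b are the fractional
monotherapy responses at the combination's component doses. The per-cell
Bliss excess is observed - expected; a positive excess means the combination
permeabilizes more than independence predicts (synergy), a negative one less
(antagonism). The matrix summary score is the mean excess over all true
combination cells (both doses > 0), in percentage points.

This is the plain Bliss reference model; web tools layer response-surface
smoothing on top, so scores are comparable in sign and ordering rather than
guaranteed numerically identical to them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError


def to_fraction(percent):
    """Percent permeabilization -> response fraction, clipped to [0, 1]."""
    p = np.asarray(percent, dtype=float)
    if not np.all(np.isfinite(p)):
        raise DataError("non-finite endpoint value")
    out = np.clip(p / 100.0, 0.0, 1.0)
    return float(out) if np.isscalar(percent) or out.ndim == 0 else out


def bliss_excess(observed_ab: float, a: float, b: float) -> float:
    """Observed combination response minus the Bliss expectation a + b - a*b."""
    for name, v in (("observed_ab", observed_ab), ("a", a), ("b", b)):
        if not (0.0 <= v <= 1.0):
            raise DataError(f"{name} = {v} outside [0, 1]")
    return float(observed_ab - (a + b - a * b))


@dataclass
class DoseMatrix:
    """Fractional endpoint responses on a two-compound concentration grid.

    Rows follow ``doses_a``, columns ``doses_b``; each axis is ascending and
    includes 0, so the first row/column hold monotherapy margins and the
    (0, 0) cell the double vehicle.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        for name, d in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            if d.ndim != 1 or d.size < 2:
                raise DataError(f"{name} must be a 1-D axis with >= 2 doses")
            if np.any(np.diff(d) <= 0):
                raise DataError(f"{name} must be strictly ascending")
            if d[0] != 0.0:
                raise DataError(f"{name} must include dose 0 as its first entry")
        if self.response.shape != (self.doses_a.size, self.doses_b.size):
            raise DataError(
                f"response shape {self.response.shape} does not match dose axes "
                f"({self.doses_a.size}, {self.doses_b.size})"
            )
        if not np.all(np.isfinite(self.response)):
            raise DataError("response matrix contains non-finite entries")
        if np.any((self.response < 0) | (self.response > 1)):
            raise DataError("responses must be fractions in [0, 1]")

    @classmethod
    def from_endpoint_table(cls, table: pd.DataFrame) -> "DoseMatrix":
        """Build from a tidy table (dose_a, dose_b, endpoint_percent), clipping to [0, 1]."""
        pivot = table.pivot_table(
            index="dose_a", columns="dose_b", values="endpoint_percent", aggfunc="mean"
        ).sort_index(axis=0).sort_index(axis=1)
        if pivot.isna().any().any():
            raise DataError("endpoint table does not cover the full dose grid")
        return cls(
            doses_a=pivot.index.to_numpy(dtype=float),
            doses_b=pivot.columns.to_numpy(dtype=float),
            response=to_fraction(pivot.to_numpy()),
        )

    def transpose(self) -> "DoseMatrix":
        return DoseMatrix(self.doses_b.copy(), self.doses_a.copy(), self.response.T.copy())


@dataclass
class SynergyResult:
    excess: np.ndarray  # NaN outside combination cells
    score: float        # 100 x mean excess over combination cells


def synergy_matrix(m: DoseMatrix) -> SynergyResult:
    """Per-cell Bliss excess and the matrix-level summary score.

    Each combination cell (a > 0 and b > 0) is compared against the Bliss
    expectation built from its own row/column monotherapy margins; margin and
    vehicle cells carry NaN in the excess matrix and are excluded from the
    summary, so duplicate vehicle rows/columns cannot shift the score.
    """
    mono_a = m.response[:, m.doses_b == 0.0].mean(axis=1)
    mono_b = m.response[m.doses_a == 0.0, :].mean(axis=0)
    combo = np.outer(m.doses_a > 0, m.doses_b > 0)
    if not combo.any():
        raise DataError("dose matrix has no combination cells")
    expected = mono_a[:, None] + mono_b[None, :] - mono_a[:, None] * mono_b[None, :]
    excess = np.where(combo, m.response - expected, np.nan)
    score = 100.0 * float(np.nanmean(excess))
    return SynergyResult(excess=excess, score=score)


def excess_table(m: DoseMatrix, result: SynergyResult) -> pd.DataFrame:
    """Tidy per-cell excess for writing to CSV."""
    rows = []
    for i, da in enumerate(m.doses_a):
        for j, db in enumerate(m.doses_b):
            if da > 0 and db > 0:
                rows.append(
                    {"dose_a": da, "dose_b": db, "bliss_excess": result.excess[i, j]}
                )
    return pd.DataFrame(rows)
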