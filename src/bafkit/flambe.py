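"""FLAMBE kinetic fluorescence-polarization analysis.

FLAMBE follows early BAX activation through the polarization of a TAMRA-
labeled BAK-BH3 peptide: the peptide binds BAX (polarization rises) and is
displaced as activation proceeds (polarization falls), so a trace carries a
rise-then-decay shape whose peak time and endpoint summarize the kinetics.

Polarization in milli-Polarization units from raw intensities:

    mP = (I_par - I_perp) / (I_par + I_perp) * 1000.

Traces are treated non-parametrically. Each replicate-averaged trace is
reduced to two metrics: Tmax, the time of the highest polarization, and EP,
the endpoint polarization. Tmax of the free-peptide control, or of any trace
showing no binding kinetics, is set to 0 so noise cannot masquerade as a
peak. Both metrics are normalized so the ligand-only control maps to 0 and
the protein vehicle control to 1, and treatment effects are measured as the
Euclidean shift distance in the normalized (Tmax, EP) plane:

    delta_s = sqrt(dTmax^2 + dEP^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DataError, DegenerateControlsError

#: default "no binding kinetics" threshold: rise amplitude below this fraction
#: of the protein-control rise amplitude triggers the Tmax := 0 rule.
NO_BINDING_THRESHOLD = 0.10


@dataclass(frozen=True)
class PolarizationTrace:
    time: np.ndarray
    mp: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "mp", np.asarray(self.mp, dtype=float))
        if self.time.shape != self.mp.shape or self.time.ndim != 1:
            raise DataError("time and mp must be 1-D arrays of equal length")
        if self.time.size < 2 or np.any(np.diff(self.time) <= 0):
            raise DataError("time must be strictly increasing")
        if np.any(np.abs(self.mp) > 1000.0 + 1e-9):
            raise DataError("mP values must lie in [-1000, 1000]")


@dataclass(frozen=True)
class FlambeMetrics:
    """(Tmax, EP) pair, raw (seconds, mP) or control-normalized (unitless)."""

    tmax: float
    ep: float
    no_binding: bool = False
    normalized: bool = False


def polarization(i_par, i_perp):
    """mP from parallel/perpendicular emission intensities; scale-invariant."""
    p = np.asarray(i_par, dtype=float)
    q = np.asarray(i_perp, dtype=float)
    if np.any(p < 0) or np.any(q < 0):
        raise DataError("intensities must be non-negative")
    total = p + q
    if np.any(total <= 0):
        raise DataError("zero total intensity: polarization undefined")
    out = (p - q) / total * 1000.0
    return float(out) if out.ndim == 0 else out


def average_traces(traces: list[PolarizationTrace]) -> PolarizationTrace:
    """Replicate mean on a shared time grid (reduces noise before parameterization)."""
    if not traces:
        raise DataError("no traces to average")
    t0 = traces[0].time
    for tr in traces[1:]:
        if tr.time.shape != t0.shape or not np.allclose(tr.time, t0):
            raise DataError("replicate traces must share one time grid")
    mp = np.mean([tr.mp for tr in traces], axis=0)
    return PolarizationTrace(t0, mp, condition=traces[0].condition)


def parameterize(
    trace: PolarizationTrace,
    no_binding_threshold: float = NO_BINDING_THRESHOLD,
    reference_rise: float | None = None,
) -> FlambeMetrics:
    """Reduce a (replicate-averaged) trace to raw (Tmax, EP).

    ``reference_rise`` is the dynamic amplitude (max - min) of the protein
    vehicle control; a trace whose own dynamic amplitude is
    <= ``no_binding_threshold`` times that reference is flagged as showing no
    binding kinetics and gets Tmax := 0. Amplitude is measured max - min
    rather than max - first reading so that fast binders whose association
    completes before the first read are still recognized. Without a
    reference, only a trace with no dynamics at all triggers the rule.
    """
    if trace.mp.size == 0:
        raise DataError("empty trace")
    rise = float(trace.mp.max() - trace.mp.min())
    ref = rise if reference_rise is None else float(reference_rise)
    no_binding = rise <= no_binding_threshold * ref or rise <= 0.0
    tmax = 0.0 if no_binding else float(trace.time[int(np.argmax(trace.mp))])
    return FlambeMetrics(tmax=tmax, ep=float(trace.mp[-1]), no_binding=no_binding)


def normalize_metrics(
    m: FlambeMetrics, ligand_ctrl: FlambeMetrics, protein_ctrl: FlambeMetrics
) -> FlambeMetrics:
    """Affine-normalize each metric so ligand control -> 0, protein control -> 1."""
    out = []
    for axis in ("tmax", "ep"):
        lo = getattr(ligand_ctrl, axis)
        hi = getattr(protein_ctrl, axis)
        if hi == lo:
            raise DegenerateControlsError(
                f"{axis}: ligand and protein controls coincide ({lo})"
            )
        out.append((getattr(m, axis) - lo) / (hi - lo))
    return FlambeMetrics(
        tmax=out[0], ep=out[1], no_binding=m.no_binding, normalized=True
    )


def shift_distance(m_without: FlambeMetrics, m_with: FlambeMetrics) -> float:
    """Euclidean distance between two normalized (Tmax, EP) points."""
    return math.hypot(m_with.tmax - m_without.tmax, m_with.ep - m_without.ep)


def auc(trace: PolarizationTrace) -> float:
    """Raw trapezoidal area under the polarization trace (mP * s)."""
    return float(np.trapezoid(trace.mp, trace.time))


def auc_normalized(
    trace: PolarizationTrace,
    ligand_ctrl: PolarizationTrace,
    protein_ctrl: PolarizationTrace,
) -> float:
    """AUC on the controls' 0/1 scale, same affine convention as the metrics."""
    for ctrl in (ligand_ctrl, protein_ctrl):
        if ctrl.time.shape != trace.time.shape or not np.allclose(ctrl.time, trace.time):
            raise DataError("trace and controls must share one time grid")
    a_lig, a_prot = auc(ligand_ctrl), auc(protein_ctrl)
    if a_prot == a_lig:
        raise DegenerateControlsError("control AUCs coincide")
    return (auc(trace) - a_lig) / (a_prot - a_lig)
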