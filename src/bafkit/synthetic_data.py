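"""Seeded generators for every input the analysis pipeline consumes.

Each generator draws from the same model family the corresponding analysis
stage assumes, with additive i.i.d. Gaussian noise per reading (a plate-
reader shot-noise approximation), so zero-noise generation followed by
fitting must recover the generating parameters — the recovery oracle every
stage is tested against. Generators are pure functions of (spec, seed) and
emit the same plate-map schema the readers consume, so synthetic and real
data share one code path.

Defaults mirror the study's assay layouts: LUV plates read every 55 s for
90 min with buffer and 1% CHAPS controls; FLAMBE plates read every 30 s for
60 min with free-peptide and protein-vehicle controls; MST timetraces span a
pre-IR window and a 35 s heated phase; melt curves ramp 25 -> 95 °C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterDomainError
from .io_formats import PEAKLIST_COLUMNS, Plate, PlateMap
from .luv_kinetics import five_pl, validate_5pl_params
from .mst import MstTrace, one_phase_decay
from .synergy import DoseMatrix
from .thermal_shift import MeltCurve

_AA3 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "SER", "THR", "TRP", "TYR", "VAL",
]


@dataclass
class ConditionSpec:
    """One plate condition: label, role, model parameters, replicate count."""

    label: str
    role: str
    model_params: Mapping[str, float] = field(default_factory=dict)
    replicate_count: int = 1
    dose_a: float = 0.0
    dose_b: float = 0.0


@dataclass
class SimPlateSpec:
    """Layout and noise model for one simulated plate.

    The time grid is uniform: ``time_start + time_step * [0 .. time_count)``.
    """

    time_start: float
    time_step: float
    time_count: int
    conditions: Sequence[ConditionSpec]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.time_step <= 0 or self.time_count < 2:
            raise DataError("time grid must be strictly increasing (step > 0, count >= 2)")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")
        for c in self.conditions:
            if c.replicate_count < 1:
                raise DataError(f"{c.label}: replicate_count must be >= 1")

    @property
    def time_grid(self) -> np.ndarray:
        return self.time_start + self.time_step * np.arange(self.time_count, dtype=float)


def _well_ids(n: int) -> list[str]:
    rows = "ABCDEFGH"
    ids = [f"{r}{c:02d}" for r in rows for c in range(1, 13)]
    if n > len(ids):
        ids += [f"X{i:03d}" for i in range(n - len(ids))]
    return ids[:n]


def _assemble_plate(
    spec: SimPlateSpec, model_values: dict[str, np.ndarray], axis_name: str
) -> Plate:
    """Lay out replicate wells, add noise, and build the Plate + map."""
    rng = np.random.default_rng(spec.seed)
    t = spec.time_grid
    n_wells = sum(c.replicate_count for c in spec.conditions)
    wells = _well_ids(n_wells)
    columns: dict[str, np.ndarray] = {}
    rows = []
    k = 0
    for cond in spec.conditions:
        clean = model_values[cond.label]
        for rep in range(1, cond.replicate_count + 1):
            w = wells[k]
            k += 1
            noise = rng.normal(0.0, spec.noise_sd, t.size) if spec.noise_sd > 0 else 0.0
            columns[w] = clean + noise
            rows.append(
                {
                    "well": w, "condition": cond.label, "role": cond.role,
                    "dose_a": cond.dose_a, "dose_b": cond.dose_b, "replicate": rep,
                }
            )
    signals = pd.DataFrame(columns, index=pd.Index(t, name=axis_name))
    return Plate(signals=signals, plate_map=PlateMap(pd.DataFrame(rows)), axis_name=axis_name)


def gen_luv_plate(spec: SimPlateSpec) -> Plate:
    """Simulate a LUV dye-release plate.

    Sample conditions follow the asymmetric five-parameter sigmoid (params
    ``b, t, e, h, s`` in raw fluorescence units); ``buffer`` and
    ``detergent_max`` conditions fluctuate about a constant ``level``. Every
    plate must include at least one of each control role.
    """
    roles = {c.role for c in spec.conditions}
    if "buffer" not in roles or "detergent_max" not in roles:
        raise DataError("LUV plate needs >= 1 buffer and >= 1 detergent_max condition")
    t = spec.time_grid
    values: dict[str, np.ndarray] = {}
    for cond in spec.conditions:
        p = cond.model_params
        if cond.role == "sample":
            validate_5pl_params(p["b"], p["t"], p["e"], p["h"], p["s"])
            values[cond.label] = five_pl(t, p["b"], p["t"], p["e"], p["h"], p["s"])
        else:
            values[cond.label] = np.full(t.size, float(p["level"]))
    return _assemble_plate(spec, values, axis_name="time_s")


def rise_decay(t, p_free: float, amplitude: float, k_a: float, k_d: float):
    """Product rise-decay polarization model: P_free + A(1 - e^{-ka t}) e^{-kd t}."""
    t = np.asarray(t, dtype=float)
    return p_free + amplitude * (1.0 - np.exp(-k_a * t)) * np.exp(-k_d * t)


def rise_decay_peak_time(k_a: float, k_d: float) -> float:
    """Analytic peak time ln(1 + k_a/k_d)/k_a of the rise-decay model (k_d > 0)."""
    if k_d <= 0:
        return float("inf")
    return float(np.log1p(k_a / k_d) / k_a)


def gen_flambe_plate(spec: SimPlateSpec) -> Plate:
    """Simulate a FLAMBE polarization plate (values in mP).

    ``sample`` and ``vehicle_protein`` conditions follow the rise-decay model
    (params ``p_free, amplitude, k_a, k_d``; k_d = 0 gives a saturating,
    non-decaying binder); ``ligand_only`` conditions are flat at ``p_free``.
    """
    t = spec.time_grid
    values: dict[str, np.ndarray] = {}
    for cond in spec.conditions:
        p = cond.model_params
        if cond.role == "ligand_only":
            values[cond.label] = np.full(t.size, float(p["p_free"]))
            continue
        a, ka, kd = float(p["amplitude"]), float(p["k_a"]), float(p["k_d"])
        if a < 0 or ka <= 0 or kd < 0:
            raise ParameterDomainError(
                f"{cond.label}: need amplitude >= 0, k_a > 0, k_d >= 0"
            )
        values[cond.label] = rise_decay(t, float(p["p_free"]), a, ka, kd)
    return _assemble_plate(spec, values, axis_name="time_s")


def gen_mst_traces(
    decay_params: Mapping[float, tuple[float, float, float]],
    t_pre: float = 5.0,
    t_post: float = 35.0,
    step: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[MstTrace]:
    """Simulate MST timetraces, one per ligand concentration.

    ``decay_params`` maps concentration -> (Y0, Yplateau, K). IR-on is t = 0;
    the trace holds Y0 over the pre-heating window [-t_pre, 0) and follows
    the one-phase decay for t >= 0.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(-t_pre, t_post + step / 2, step)
    traces = []
    for conc in sorted(decay_params):
        y0, plateau, k = (float(v) for v in decay_params[conc])
        if k <= 0:
            raise ParameterDomainError(f"concentration {conc}: decay constant must be > 0")
        clean = np.where(t < 0, y0, one_phase_decay(np.maximum(t, 0.0), y0, plateau, k))
        noise = rng.normal(0.0, noise_sd, t.size) if noise_sd > 0 else 0.0
        traces.append(MstTrace(time=t, fluorescence=clean + noise, concentration=conc))
    return traces


def gen_melt_curves(
    tm: float,
    steepness: float = 1.2,
    baselines: tuple[float, float] = (0.0, 1.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
    t_start: float = 25.0,
    t_stop: float = 95.0,
    step: float = 0.5,
    condition: str = "sample",
) -> list[MeltCurve]:
    """Simulate two-state melt curves: logistic unfolding centered at ``tm``.

    F(T) = low + (high - low) / (1 + exp(-(T - tm)/steepness)); the logistic's
    derivative maximum sits exactly at the midpoint, so the generated Tm is
    the ground truth for the derivative-based estimator.
    """
    if steepness <= 0:
        raise ParameterDomainError("steepness must be > 0")
    rng = np.random.default_rng(seed)
    temp = np.arange(t_start, t_stop + step / 2, step)
    low, high = (float(b) for b in baselines)
    clean = low + (high - low) / (1.0 + np.exp(-(temp - tm) / steepness))
    curves = []
    for rep in range(1, n_replicates + 1):
        noise = rng.normal(0.0, noise_sd, temp.size) if noise_sd > 0 else 0.0
        curves.append(
            MeltCurve(
                temperature=temp, fluorescence=clean + noise,
                condition=condition, replicate=rep,
            )
        )
    return curves


def gen_hsqc_peaklists(
    n_residues: int,
    proline_positions: Sequence[int] = (),
    missing_positions: Sequence[int] = (),
    perturbed: Mapping[int, tuple[float, float]] | None = None,
    jitter_sd: float = 0.0,
    seed: int = 0,
    jitter_seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a reference/treated HSQC peak-list pair.

    Residues are numbered 1..n. ``perturbed`` maps residue number ->
    (d1H, d15N) shifts injected into the treated list; jitter (ppm, same SD
    on both dimensions) models peak-center uncertainty on every measured
    residue. Perturbed residues must be neither proline nor missing.
    ``jitter_seed`` decouples the jitter draw from the reference-coordinate
    draw so a titration series can share one reference list while each
    treated list gets independent peak-center noise.
    """
    perturbed = dict(perturbed or {})
    prolines = set(int(i) for i in proline_positions)
    missing = set(int(i) for i in missing_positions)
    bad = set(perturbed) & (prolines | missing)
    if bad:
        raise DataError(f"perturbed residues cannot be proline/missing: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    nums = np.arange(1, n_residues + 1)
    names = [
        "PRO" if i in prolines else _AA3[rng.integers(0, len(_AA3))] for i in nums
    ]
    h_ref = rng.uniform(7.0, 10.0, n_residues)
    n_ref = rng.uniform(105.0, 130.0, n_residues)
    assigned = np.array([i not in prolines and i not in missing for i in nums])

    h_trt = h_ref.copy()
    n_trt = n_ref.copy()
    if jitter_sd > 0:
        jrng = rng if jitter_seed is None else np.random.default_rng(jitter_seed)
        h_trt = h_trt + jrng.normal(0.0, jitter_sd, n_residues)
        n_trt = n_trt + jrng.normal(0.0, jitter_sd, n_residues)
    for res, (dh, dn) in perturbed.items():
        idx = int(res) - 1
        h_trt[idx] += dh
        n_trt[idx] += dn

    def _frame(h, n):
        df = pd.DataFrame(
            {
                "residue_number": nums,
                "residue_name": names,
                "h_ppm": np.where(assigned, h, np.nan),
                "n_ppm": np.where(assigned, n, np.nan),
                "assigned": assigned,
            }
        )
        return df[PEAKLIST_COLUMNS]

    return _frame(h_ref, n_ref), _frame(h_trt, n_trt)


def gen_dose_matrix(
    doses_a: Sequence[float],
    doses_b: Sequence[float],
    mono_a: Sequence[float],
    mono_b: Sequence[float],
    excess: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseMatrix:
    """Simulate an endpoint dose matrix with a known constant Bliss excess.

    ``mono_a``/``mono_b`` are the fractional monotherapy responses along each
    axis (first entry, the vehicle, must be 0). Every combination cell is the
    Bliss expectation plus ``excess``; ``noise_sd`` (fraction scale) adds
    Gaussian noise to all cells before clipping to [0, 1]. Combinations whose
    clean value would leave [0, 1] raise, so the injected excess stays exact.
    """
    a = np.asarray(mono_a, dtype=float)
    b = np.asarray(mono_b, dtype=float)
    da = np.asarray(doses_a, dtype=float)
    db = np.asarray(doses_b, dtype=float)
    if a.size != da.size or b.size != db.size:
        raise DataError("monotherapy responses must match dose axes")
    if a[0] != 0.0 or b[0] != 0.0:
        raise DataError("vehicle responses (first entries) must be 0")
    expected = a[:, None] + b[None, :] - a[:, None] * b[None, :]
    combo = np.outer(da > 0, db > 0)
    clean = np.where(combo, expected + excess, expected)
    clean[0, :] = b
    clean[:, 0] = a
    if np.any((clean < 0) | (clean > 1)):
        raise DataError("injected excess pushes clean responses outside [0, 1]")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        clean = np.clip(clean + rng.normal(0.0, noise_sd, clean.shape), 0.0, 1.0)
    return DoseMatrix(doses_a=da, doses_b=db, response=clean)


def gen_dose_response(
    concentrations: Sequence[float],
    bottom: float,
    top: float,
    ec50: float,
    hill: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate temperature-jump responses on a Hill curve for EC50 recovery."""
    from .mst import hill_curve

    if ec50 <= 0 or hill <= 0:
        raise ParameterDomainError("ec50 and hill must be > 0")
    c = np.asarray(concentrations, dtype=float)
    y = hill_curve(c, bottom, top, ec50, hill)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, c.size)
    return y
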