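"""Chemical-shift-perturbation analysis of paired 1H-15N HSQC peak lists.

Ligand binding perturbs backbone amide resonances; per residue the weighted
combined perturbation between a reference and a treated spectrum is

    delta_delta = sqrt( (dH^2 + 0.2 * dN^2) / 2 )   [ppm],

the 0.2 weight compressing the wider 15N dispersion onto the 1H scale.
Prolines (no backbone amide) and residues whose resonance is overlapped or
missing in either spectrum carry a status instead of a value and never enter
the statistics. Significance thresholds are the mean perturbation across all
measurable residues plus one or two standard deviations; residues strictly
exceeding them are classed ``above_1sd`` / ``above_2sd``. For titration
series, perturbations can be averaged across concentrations per residue
before thresholding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError

NITROGEN_WEIGHT = 0.2

STATUS_MEASURED = "measured"
STATUS_PROLINE = "proline"
STATUS_MISSING = "missing"

CLASS_NS = "ns"
CLASS_1SD = "above_1sd"
CLASS_2SD = "above_2sd"


def csp(d_h, d_n):
    """Weighted combined 1H/15N shift perturbation (ppm); even in each argument."""
    dh = np.asarray(d_h, dtype=float)
    dn = np.asarray(d_n, dtype=float)
    if not (np.all(np.isfinite(dh)) and np.all(np.isfinite(dn))):
        raise DataError("shift differences must be finite")
    out = np.sqrt((dh**2 + NITROGEN_WEIGHT * dn**2) / 2.0)
    return float(out) if out.ndim == 0 else out


def csp_table(reference: pd.DataFrame, treated: pd.DataFrame) -> pd.DataFrame:
    """Per-residue perturbation table from two peak lists.

    Lists must share residue numbering. A residue is ``measured`` only when
    assigned in both spectra; prolines and otherwise-unassigned residues are
    carried with their status and no delta_delta.
    """
    ref = reference.sort_values("residue_number").reset_index(drop=True)
    trt = treated.sort_values("residue_number").reset_index(drop=True)
    if len(ref) != len(trt) or not (
        ref["residue_number"].to_numpy() == trt["residue_number"].to_numpy()
    ).all():
        raise DataError("peak lists do not share residue numbering")

    is_pro = (ref["residue_name"].str.upper() == "PRO") | (
        trt["residue_name"].str.upper() == "PRO"
    )
    both_assigned = ref["assigned"].to_numpy() & trt["assigned"].to_numpy()
    status = np.where(is_pro, STATUS_PROLINE,
                      np.where(both_assigned, STATUS_MEASURED, STATUS_MISSING))

    d_h = trt["h_ppm"].to_numpy(dtype=float) - ref["h_ppm"].to_numpy(dtype=float)
    d_n = trt["n_ppm"].to_numpy(dtype=float) - ref["n_ppm"].to_numpy(dtype=float)
    measured = status == STATUS_MEASURED
    d_h = np.where(measured, d_h, np.nan)
    d_n = np.where(measured, d_n, np.nan)
    dd = np.full(len(ref), np.nan)
    dd[measured] = csp(d_h[measured], d_n[measured])
    return pd.DataFrame(
        {
            "residue_number": ref["residue_number"].to_numpy(),
            "residue_name": ref["residue_name"].to_numpy(),
            "d_h": d_h,
            "d_n": d_n,
            "delta_delta": dd,
            "status": status,
        }
    )


def significance_thresholds(
    table: pd.DataFrame, sd_mode: str = "sample"
) -> tuple[float, float, pd.DataFrame]:
    """Mean +1SD / +2SD thresholds over measured residues, plus classified table.

    ``sd_mode``: ``sample`` (n-1 denominator, default) or ``population``.
    Classes use strict exceedance; a residue above both thresholds is classed
    at the higher one.
    """
    if sd_mode not in ("sample", "population"):
        raise DataError(f"unknown sd_mode {sd_mode!r}")
    measured = table["status"] == STATUS_MEASURED
    vals = table.loc[measured, "delta_delta"].to_numpy(dtype=float)
    if vals.size < 2:
        raise DataError(f"need >= 2 measured residues, got {vals.size}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1 if sd_mode == "sample" else 0))
    theta1, theta2 = mean + sd, mean + 2.0 * sd

    out = table.copy()
    cls = np.full(len(out), "", dtype=object)
    dd = out["delta_delta"].to_numpy(dtype=float)
    cls[measured] = CLASS_NS
    cls[measured & (dd > theta1)] = CLASS_1SD
    cls[measured & (dd > theta2)] = CLASS_2SD
    out["class"] = cls
    return theta1, theta2, out


def average_across_concentrations(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-residue mean delta_delta over the tables where the residue is measured.

    A residue unmeasured in every table keeps its (proline/missing) status
    and stays value-less; thresholds are then computed on the averaged table.
    """
    if not tables:
        raise DataError("empty concentration series")
    base = tables[0]["residue_number"].to_numpy()
    for t in tables[1:]:
        if len(t) != len(base) or not (
            t.sort_values("residue_number")["residue_number"].to_numpy() == np.sort(base)
        ).all():
            raise DataError("tables do not share residue numbering")
    sorted_tables = [t.sort_values("residue_number").reset_index(drop=True) for t in tables]
    dd = np.vstack([t["delta_delta"].to_numpy(dtype=float) for t in sorted_tables])
    measured = np.vstack([(t["status"] == STATUS_MEASURED).to_numpy() for t in sorted_tables])
    n_measured = measured.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_dd = np.where(
            n_measured > 0, np.nansum(np.where(measured, dd, 0.0), axis=0)
            / np.maximum(n_measured, 1), np.nan
        )
    first = sorted_tables[0]
    status = np.where(
        n_measured > 0, STATUS_MEASURED, first["status"].to_numpy()
    )
    return pd.DataFrame(
        {
            "residue_number": first["residue_number"].to_numpy(),
            "residue_name": first["residue_name"].to_numpy(),
            "d_h": np.nan,
            "d_n": np.nan,
            "delta_delta": mean_dd,
            "status": status,
            "n_measured": n_measured,
        }
    )


def annotation_table(classified: pd.DataFrame) -> pd.DataFrame:
    """(residue_number, class) pairs for structure-viewer coloring."""
    meas = classified[classified["status"] == STATUS_MEASURED]
    return meas[["residue_number", "class"]].reset_index(drop=True)
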