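"""Chemical-shift perturbations: weighted combination, statuses, thresholds."""

import numpy as np
import pytest
from _oracles import csp_direct

from bafkit.errors import DataError
from bafkit.nmr_csp import (
    average_across_concentrations,
    annotation_table,
    csp,
    csp_table,
    significance_thresholds,
)
from bafkit.synthetic_data import gen_hsqc_peaklists


class TestCsp:
    def test_zero(self):
        assert csp(0.0, 0.0) == 0.0

    def test_worked_value(self):
        assert csp(0.1, 0.5) == pytest.approx(np.sqrt(0.03))
        assert csp(0.1, 0.5) == pytest.approx(0.17321, abs=1e-5)

    def test_even_in_each_argument(self, rng):
        for _ in range(100):
            dh, dn = rng.normal(size=2)
            assert csp(dh, dn) == csp(-dh, dn) == csp(dh, -dn)
            assert csp(dh, dn) == pytest.approx(csp_direct(dh, dn))

    def test_strictly_monotone_in_magnitudes(self):
        assert csp(0.2, 0.5) > csp(0.1, 0.5)
        assert csp(0.1, 0.6) > csp(0.1, 0.5)


class TestCspTable:
    def test_identical_lists_all_zero(self):
        ref, _ = gen_hsqc_peaklists(20, seed=3)
        table = csp_table(ref, ref)
        measured = table[table["status"] == "measured"]
        assert len(measured) == 20
        assert measured["delta_delta"].to_numpy() == pytest.approx(0.0)

    def test_proline_and_missing_statuses(self):
        ref, trt = gen_hsqc_peaklists(
            12, proline_positions=[4], missing_positions=[7], seed=0
        )
        table = csp_table(ref, trt)
        assert table.loc[table["residue_number"] == 4, "status"].item() == "proline"
        assert table.loc[table["residue_number"] == 7, "status"].item() == "missing"
        assert np.isnan(table.loc[table["residue_number"] == 4, "delta_delta"].item())

    def test_injected_perturbations_recovered(self):
        perturbed = {5: (0.1, 0.5), 9: (-0.08, 0.3)}
        ref, trt = gen_hsqc_peaklists(15, perturbed=perturbed, seed=1)
        table = csp_table(ref, trt).set_index("residue_number")
        for res, (dh, dn) in perturbed.items():
            assert table.loc[res, "delta_delta"] == pytest.approx(csp_direct(dh, dn))
        untouched = table.drop(index=list(perturbed))
        meas = untouched[untouched["status"] == "measured"]
        assert meas["delta_delta"].to_numpy() == pytest.approx(0.0)

    def test_numbering_mismatch_raises(self):
        ref, _ = gen_hsqc_peaklists(10, seed=0)
        other, _ = gen_hsqc_peaklists(11, seed=0)
        with pytest.raises(DataError):
            csp_table(ref, other)


class TestThresholds:
    def _table(self, deltas, statuses=None):
        import pandas as pd

        n = len(deltas)
        statuses = statuses or ["measured"] * n
        return pd.DataFrame(
            {
                "residue_number": np.arange(1, n + 1),
                "residue_name": ["ALA"] * n,
                "d_h": np.zeros(n),
                "d_n": np.zeros(n),
                "delta_delta": [d if s == "measured" else np.nan
                                for d, s in zip(deltas, statuses)],
                "status": statuses,
            }
        )

    def test_all_equal_no_significance(self):
        t1, t2, out = significance_thresholds(self._table([0.1] * 5))
        assert t1 == t2 == pytest.approx(0.1)
        assert (out["class"] == "ns").all()

    def test_hand_checked_example(self):
        """delta set {0,0,0,0,1}: sample SD sqrt(0.2), only the outlier is
        above_1sd and it does not reach above_2sd."""
        t1, t2, out = significance_thresholds(self._table([0.0, 0.0, 0.0, 0.0, 1.0]))
        assert t1 == pytest.approx(0.2 + np.sqrt(0.2), abs=1e-6)
        assert out["class"].tolist() == ["ns", "ns", "ns", "ns", "above_1sd"]

    def test_prolines_excluded_from_statistics(self):
        base = self._table([0.1, 0.2, 0.3, 0.4])
        with_pro = self._table(
            [0.1, 0.2, 0.3, 0.4, 9.9], statuses=["measured"] * 4 + ["proline"]
        )
        assert significance_thresholds(base)[:2] == significance_thresholds(with_pro)[:2]

    def test_reorder_and_scale_invariance(self, rng):
        vals = rng.uniform(0.0, 0.5, 12)
        t1, t2, out = significance_thresholds(self._table(vals))
        perm = rng.permutation(12)
        t1p, t2p, outp = significance_thresholds(self._table(vals[perm]))
        assert (t1p, t2p) == pytest.approx((t1, t2))
        assert (
            out["class"].to_numpy()[perm] == outp["class"].to_numpy()
        ).all()
        c = 3.7
        t1c, t2c, outc = significance_thresholds(self._table(c * vals))
        assert (t1c, t2c) == pytest.approx((c * t1, c * t2))
        assert (outc["class"].to_numpy() == out["class"].to_numpy()).all()

    def test_too_few_measured_raises(self):
        with pytest.raises(DataError):
            significance_thresholds(self._table([0.1]))


class TestConcentrationAveraging:
    def test_single_table_identity(self):
        ref, trt = gen_hsqc_peaklists(10, perturbed={3: (0.1, 0.2)}, seed=5)
        table = csp_table(ref, trt)
        avg = average_across_concentrations([table])
        assert avg["delta_delta"].to_numpy() == pytest.approx(
            table["delta_delta"].to_numpy(), nan_ok=True
        )

    def test_partial_measurement_mean(self):
        ref, t1 = gen_hsqc_peaklists(8, perturbed={2: (0.1, 0.0)}, seed=0)
        _, t2 = gen_hsqc_peaklists(8, perturbed={2: (0.3, 0.0)}, seed=0)
        tables = [csp_table(ref, t1), csp_table(ref, t2)]
        # make residue 2 unmeasured in a third table
        _, t3 = gen_hsqc_peaklists(8, seed=0)
        tab3 = csp_table(ref, t3)
        tab3.loc[tab3["residue_number"] == 2, "status"] = "missing"
        tab3.loc[tab3["residue_number"] == 2, "delta_delta"] = np.nan
        avg = average_across_concentrations(tables + [tab3])
        dd = avg.set_index("residue_number").loc[2]
        expected = (csp_direct(0.1, 0.0) + csp_direct(0.3, 0.0)) / 2.0
        assert dd["delta_delta"] == pytest.approx(expected)
        assert dd["n_measured"] == 2

    def test_never_measured_residue_stays_unmeasured(self):
        ref, trt = gen_hsqc_peaklists(8, missing_positions=[5], seed=0)
        avg = average_across_concentrations([csp_table(ref, trt)] * 3)
        row = avg.set_index("residue_number").loc[5]
        assert row["status"] == "missing" and np.isnan(row["delta_delta"])

    def test_empty_series_raises(self):
        with pytest.raises(DataError):
            average_across_concentrations([])


def test_annotation_table_only_measured_residues():
    ref, trt = gen_hsqc_peaklists(
        10, proline_positions=[2], missing_positions=[4],
        perturbed={6: (0.2, 0.8)}, jitter_sd=0.001, seed=7,
    )
    _, _, classified = significance_thresholds(csp_table(ref, trt))
    ann = annotation_table(classified)
    assert set(ann["residue_number"]) == set(range(1, 11)) - {2, 4}
    assert ann.set_index("residue_number").loc[6, "class"] == "above_2sd"
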