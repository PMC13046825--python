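"""LUV kinetics: normalization rules, sigmoid fitting, maximal-rate closed form."""

import numpy as np
import pytest
from _oracles import numeric_max_rate, random_valid_5pl, sigmoid5

from bafkit.errors import (
    DataError,
    DegenerateControlsError,
    NoInflectionError,
    PlateMapError,
)
from bafkit.luv_kinetics import (
    Fit5PL,
    KineticTrace,
    NormalizationRefs,
    compute_refs,
    endpoint_percent,
    fit_5pl,
    fit_plate,
    five_pl,
    maximal_rate,
    normalize_percent,
)


def _trace(time, signal, **kw):
    return KineticTrace(np.asarray(time, float), np.asarray(signal, float), **kw)


class TestComputeRefs:
    def test_min_buffer_mean_chaps(self, toy_luv_plate):
        refs = compute_refs(toy_luv_plate)
        assert refs.f0 == 9.0
        assert refs.f100 == 210.0

    def test_missing_role_raises(self, toy_luv_plate):
        plate = toy_luv_plate
        plate.plate_map.table.loc[1, "role"] = "sample"
        with pytest.raises(PlateMapError):
            compute_refs(plate)

    def test_degenerate_controls(self):
        with pytest.raises(DegenerateControlsError):
            NormalizationRefs(f0=100.0, f100=50.0)


class TestNormalization:
    refs = NormalizationRefs(f0=20.0, f100=220.0)

    @pytest.mark.parametrize(
        "raw,expected", [(20.0, 0.0), (220.0, 100.0), (120.0, 50.0), (270.0, 125.0)]
    )
    def test_affine_map(self, raw, expected):
        tr = _trace(np.arange(1, 9), np.full(8, raw))
        out = normalize_percent(tr, self.refs)
        assert out.signal == pytest.approx(np.full(8, expected))

    def test_values_outside_range_not_clipped(self):
        tr = _trace(np.arange(1, 9), [10.0, 20.0, 120.0, 220.0, 250.0, 240.0, 230.0, 260.0])
        out = normalize_percent(tr, self.refs)
        assert out.signal.min() < 0.0 and out.signal.max() > 100.0

    def test_affine_invariance_of_whole_plate(self, rng):
        """A gain/offset change applied to every well (samples and controls
        together) leaves normalized traces unchanged."""
        time = np.arange(1.0, 11.0)
        raw = rng.uniform(20.0, 200.0, 10)
        refs = NormalizationRefs(f0=15.0, f100=230.0)
        base = normalize_percent(_trace(time, raw), refs).signal
        for _ in range(10):
            scale, shift = float(rng.uniform(0.1, 5.0)), float(rng.uniform(-100, 100))
            refs2 = NormalizationRefs(refs.f0 * scale + shift, refs.f100 * scale + shift)
            out = normalize_percent(_trace(time, raw * scale + shift), refs2).signal
            assert out == pytest.approx(base, abs=1e-8)


class TestFit5PL:
    time = 60.0 * np.arange(1, 91)

    def test_zero_noise_roundtrip(self):
        y = five_pl(self.time, 0.0, 100.0, 1800.0, 2.0, 1.0)
        fit = fit_5pl(_trace(self.time, y))
        assert fit.converged
        for got, true in zip(fit.params(), (0.0, 100.0, 1800.0, 2.0, 1.0)):
            assert got == pytest.approx(true, rel=1e-6, abs=1e-6)

    def test_value_at_e_is_forced_midquantile(self, rng):
        """y(E) = B + (T-B)/2^S holds identically for the fitted curve."""
        for _ in range(20):
            b, t, e, h, s = random_valid_5pl(rng)
            assert five_pl(e, b, t, e, h, s) == pytest.approx(b + (t - b) / 2**s)

    def test_constant_trace_degenerate(self):
        fit = fit_5pl(_trace(self.time, np.full(90, 42.0)))
        assert fit.degenerate and not fit.converged
        assert fit.t == pytest.approx(fit.b)

    def test_zero_timestamp_reassigned(self):
        time = 60.0 * np.arange(0, 90)
        y = five_pl(np.where(time == 0, 30.0, time), 0.0, 100.0, 1800.0, 2.0, 1.0)
        fit = fit_5pl(_trace(time, y))
        assert fit.converged and fit.e == pytest.approx(1800.0, rel=1e-4)

    def test_too_short_raises(self):
        with pytest.raises(DataError):
            _trace(np.arange(1, 6), np.arange(5.0))


class TestMaximalRate:
    def test_against_numeric_oracle_worked_example(self):
        fit = Fit5PL(b=0.0, t=100.0, e=30.0, h=2.0, s=1.0)
        rate, x_ip = maximal_rate(fit)
        num_rate, num_x = numeric_max_rate(0.0, 100.0, 30.0, 2.0, 1.0)
        assert x_ip == pytest.approx(30.0 / np.sqrt(3.0), rel=1e-12)
        assert rate == pytest.approx(2.1651, abs=1e-4)
        assert rate == pytest.approx(num_rate, rel=1e-6)
        # the derivative is quadratically flat at its max, so the numeric
        # location carries ~sqrt of the value precision
        assert x_ip == pytest.approx(num_x, rel=1e-4)

    def test_against_numeric_oracle_random_sweep(self, rng):
        for _ in range(50):
            b, t, e, h, s = random_valid_5pl(rng)
            rate, x_ip = maximal_rate(Fit5PL(b=b, t=t, e=e, h=h, s=s))
            num_rate, _ = numeric_max_rate(b, t, e, h, s)
            assert rate == pytest.approx(num_rate, rel=1e-6)

    def test_flat_curve_zero_rate(self):
        rate, _ = maximal_rate(Fit5PL(b=40.0, t=40.0, e=30.0, h=2.0, s=1.0))
        assert rate == 0.0

    def test_no_inflection_raises(self):
        with pytest.raises(NoInflectionError):
            maximal_rate(Fit5PL(b=0.0, t=100.0, e=30.0, h=0.5, s=1.0))

    def test_monotone_in_amplitude_and_scale(self):
        base = Fit5PL(b=0.0, t=100.0, e=30.0, h=2.0, s=1.5)
        r0, _ = maximal_rate(base)
        r_bigger, _ = maximal_rate(Fit5PL(b=0.0, t=150.0, e=30.0, h=2.0, s=1.5))
        r_slower, _ = maximal_rate(Fit5PL(b=0.0, t=100.0, e=60.0, h=2.0, s=1.5))
        assert r_bigger > r0 > r_slower


class TestEndpoint:
    def test_last_reading(self):
        tr = _trace(np.arange(1, 9), [0, 10, 20, 40, 60, 70, 80, 85.0])
        assert endpoint_percent(tr) == 85.0

    def test_mean_of_final_k(self):
        tr = _trace(np.arange(1, 9), [0, 10, 20, 40, 60, 80, 82, 84.0])
        assert endpoint_percent(tr, k_last=3) == pytest.approx(82.0)

    def test_k_too_large_raises(self):
        tr = _trace(np.arange(1, 9), np.arange(8.0))
        with pytest.raises(DataError):
            endpoint_percent(tr, k_last=9)


def test_fit_plate_recovers_normalized_shape():
    """End-to-end: raw plate -> refs -> normalized fit reproduces the generating shape."""
    from bafkit.synthetic_data import ConditionSpec, SimPlateSpec, gen_luv_plate

    spec = SimPlateSpec(
        time_start=60.0, time_step=60.0, time_count=90,
        conditions=[
            ConditionSpec("buffer", "buffer", {"level": 10.0}),
            ConditionSpec("chaps", "detergent_max", {"level": 510.0}),
            ConditionSpec("bax", "sample",
                          {"b": 10.0, "t": 510.0, "e": 1800.0, "h": 2.0, "s": 1.0}),
        ],
        noise_sd=0.0, seed=0,
    )
    rows = fit_plate(gen_luv_plate(spec))
    (row,) = rows
    # raw b=10 -> 0 %, raw t=510 -> 100 % on the control scale
    assert row["b"] == pytest.approx(0.0, abs=1e-6)
    assert row["t"] == pytest.approx(100.0, rel=1e-6)
    assert row["e"] == pytest.approx(1800.0, rel=1e-6)
    assert row["max_rate"] == pytest.approx(
        numeric_max_rate(0.0, 100.0, 1800.0, 2.0, 1.0)[0], rel=1e-5
    )
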