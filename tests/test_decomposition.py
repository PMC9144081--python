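"""Frame validation, tare, aggregation, decomposition and calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enp.decomposition import (
    CELL_POSITIONS,
    CalibrationFit,
    CellPosition,
    LoadCellFrame,
    TareModel,
    aggregate_measurement,
    compute_percentages,
    compute_totals,
    fit_linear_calibration,
    read_frames_csv,
    tare_calibrate,
    validate_frame,
    write_frames_csv,
)
from enp.exceptions import CalibrationError, DataError, StructuralError, UsageError

from conftest import make_frame, random_frame


class TestValidateFrame:
    def test_zero_frame_accepted(self):
        f = validate_frame(make_frame(0.0))
        assert all(v == 0.0 for v in f.readings.values())

    def test_missing_cell_is_structural_error(self, uniform_frame):
        del uniform_frame.readings[CellPosition("right", "rear", "lateral")]
        with pytest.raises(StructuralError, match="R_rear_lat"):
            validate_frame(uniform_frame)

    def test_small_negative_clipped_to_zero(self, uniform_frame):
        p = CELL_POSITIONS[0]
        uniform_frame.readings[p] = -0.02
        assert validate_frame(uniform_frame).readings[p] == 0.0

    @pytest.mark.parametrize("bad", [-0.2, float("nan"), float("inf")])
    def test_bad_reading_is_data_error(self, uniform_frame, bad):
        uniform_frame.readings[CELL_POSITIONS[3]] = bad
        with pytest.raises(DataError):
            validate_frame(uniform_frame)


class TestTare:
    def test_constant_frames_give_exact_offsets_and_zero_noise(self):
        frames = [make_frame(0.5, timestamp=i) for i in range(10)]
        tare = tare_calibrate(frames, tolerance=0.1)
        assert all(v == 0.5 for v in tare.offsets.values())
        assert tare.residual_noise_sd == 0.0
        assert tare.n_frames == 10

    def test_noisy_plate_fails_calibration(self, rng):
        frames = [make_frame(rng.normal(0.0, 2.0, size=8)) for _ in range(40)]
        with pytest.raises(CalibrationError, match="not stable"):
            tare_calibrate(frames, tolerance=0.1)

    def test_tare_subtracts_offsets(self, uniform_frame):
        tare = tare_calibrate([make_frame(0.5)], tolerance=0.1)
        corrected = tare.apply(uniform_frame)
        assert all(v == pytest.approx(9.5) for v in corrected.readings.values())

    def test_taring_a_tared_stream_is_idempotent(self):
        tare = tare_calibrate([make_frame(0.7)] * 5, tolerance=0.1)
        retared = tare_calibrate([tare.apply(make_frame(0.7)) for _ in range(5)], tolerance=0.1)
        assert all(v == 0.0 for v in retared.offsets.values())

    def test_json_round_trip(self):
        tare = tare_calibrate([make_frame(0.5)], tolerance=0.1)
        back = TareModel.from_json(tare.to_json())
        assert back.offsets == tare.offsets
        assert back.n_frames == tare.n_frames


class TestAggregate:
    def test_identical_frames_average_to_themselves(self, uniform_frame):
        out = aggregate_measurement([uniform_frame] * 3)
        assert out.readings == uniform_frame.readings

    def test_mean_of_two_values(self):
        out = aggregate_measurement([make_frame(10.0), make_frame(20.0)])
        assert all(v == 15.0 for v in out.readings.values())

    def test_empty_window_rejected(self):
        with pytest.raises(UsageError):
            aggregate_measurement([])

    def test_noise_averages_out_within_clt_bound(self, rng):
        truth, sd, n = 12.0, 1.0, 50
        frames = [make_frame(rng.normal(truth, sd, size=8)) for _ in range(n)]
        out = aggregate_measurement(frames)
        bound = 3 * sd / math.sqrt(n)
        assert all(abs(v - truth) < bound for v in out.readings.values())

    def test_mean_commutes_with_totals(self, rng):
        frames = [random_frame(rng) for _ in range(20)]
        total_of_mean = compute_totals(aggregate_measurement(frames)).total
        mean_of_totals = np.mean([compute_totals(f).total for f in frames])
        assert total_of_mean == pytest.approx(mean_of_totals, rel=1e-12)


class TestComputeTotals:
    def test_uniform_symmetry(self, uniform_frame):
        w = compute_totals(uniform_frame)
        assert w.total == 80.0
        assert w.left == w.right == w.toes == w.heel == 40.0
        assert all(q == 20.0 for q in w.quadrants.values())

    def test_toes_and_heel_sections_sum_to_printed_total(self):
        # toes section 40.0 kg, heel section 37.7 kg -> 77.7 kg total
        frame = make_frame([10.0, 10.0, 9.4, 9.4, 10.0, 10.0, 9.45, 9.45])
        w = compute_totals(frame)
        assert w.toes == pytest.approx(40.0)
        assert w.heel == pytest.approx(37.7)
        assert w.total == pytest.approx(77.7)

    @given(st.lists(st.floats(min_value=0.0, max_value=60.0), min_size=8, max_size=8))
    @settings(deadline=None, max_examples=200)
    def test_conservation_identities(self, values):
        w = compute_totals(make_frame(values))
        # independent oracle: plain re-summation of the raw cell values
        oracle_total = sum(values)
        assert w.left + w.right == pytest.approx(oracle_total, rel=1e-9, abs=1e-12)
        assert w.toes + w.heel == pytest.approx(oracle_total, rel=1e-9, abs=1e-12)
        assert sum(w.quadrants.values()) == pytest.approx(oracle_total, rel=1e-9, abs=1e-12)
        assert w.total == pytest.approx(oracle_total, rel=1e-9, abs=1e-12)


class TestComputePercentages:
    def test_uniform_frame_is_25_50_split(self, uniform_frame):
        pct = compute_percentages(compute_totals(uniform_frame))
        assert all(pct[q] == pytest.approx(25.0) for q in ("L.toe", "R.toe", "L.heel", "R.heel"))
        assert all(pct[a] == pytest.approx(50.0) for a in ("left", "right", "toes", "heel"))

    def test_zero_total_is_degenerate(self):
        with pytest.raises(DataError, match="no load"):
            compute_percentages(compute_totals(make_frame(0.0)))

    def test_constructed_quadrant_shares_round_trip(self):
        # shares taken from the population quadrant setpoints
        shares = {"L.toe": 6.4, "R.toe": 6.4, "L.heel": 10.1, "R.heel": 9.8}
        total = sum(shares.values())  # treat the shares as percent of this total
        frame = make_frame(
            [
                shares["L.toe"] / 2, shares["L.toe"] / 2,
                shares["L.heel"] / 2, shares["L.heel"] / 2,
                shares["R.toe"] / 2, shares["R.toe"] / 2,
                shares["R.heel"] / 2, shares["R.heel"] / 2,
            ]
        )
        pct = compute_percentages(compute_totals(frame))
        for q, s in shares.items():
            assert pct[q] == pytest.approx(100.0 * s / total, rel=1e-12)

    @given(st.lists(st.floats(min_value=0.01, max_value=60.0), min_size=8, max_size=8))
    @settings(deadline=None, max_examples=200)
    def test_percent_normalization(self, values):
        pct = compute_percentages(compute_totals(make_frame(values)))
        quads = sum(pct[q] for q in ("L.toe", "R.toe", "L.heel", "R.heel"))
        assert quads == pytest.approx(100.0, rel=1e-9)
        assert pct["toes"] + pct["heel"] == pytest.approx(100.0, rel=1e-9)
        assert pct["left"] + pct["right"] == pytest.approx(100.0, rel=1e-9)
        assert all(0.0 <= v <= 100.0 + 1e-9 for v in pct.values.values())


class TestCalibration:
    def test_perfect_line_recovered(self):
        pairs = [(v, 2.0 * v + 1.0) for v in (0.5, 1.0, 1.5, 2.0)]
        fit = fit_linear_calibration(pairs)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noise_free_test_weights_give_unit_r_squared(self):
        # the four bench test weights mapped through a linear sensor response
        weights = [55.0, 58.0, 70.0, 83.0]
        pairs = [((w - 1.25) / 40.0, w) for w in weights]
        fit = fit_linear_calibration(pairs)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(40.0)
        for v, w in pairs:
            assert fit.predict(v) == pytest.approx(w)

    def test_half_residual_variance_gives_r_squared_half(self):
        # residuals e=(c,-2c,c) with c=1/sqrt(3) are orthogonal to x=(-1,0,1)
        # and make SSres exactly half of SStot
        c = 1.0 / math.sqrt(3.0)
        x = [-1.0, 0.0, 1.0]
        y = [xi + ei for xi, ei in zip(x, [c, -2 * c, c])]
        fit = fit_linear_calibration(list(zip(x, y)))
        assert fit.r_squared == pytest.approx(0.5, rel=1e-12)

    def test_identical_voltages_are_degenerate(self):
        with pytest.raises(DataError, match="degenerate"):
            fit_linear_calibration([(1.0, 55.0), (1.0, 83.0)])

    def test_slope_recovery_is_unbiased_on_noisy_data(self, rng):
        # Monte-Carlo: mean slope estimate within 4 SE of the truth
        true_slope, true_icpt, reps = 40.0, 1.0, 300
        v = np.linspace(1.0, 2.5, 12)
        slopes = []
        for _ in range(reps):
            w = true_slope * v + true_icpt + rng.normal(0, 0.5, v.size)
            slopes.append(fit_linear_calibration(list(zip(v, w))).slope)
        se_slope = 0.5 / math.sqrt(np.sum((v - v.mean()) ** 2))
        assert np.mean(slopes) == pytest.approx(true_slope, abs=4 * se_slope / math.sqrt(reps))

    def test_json_round_trip(self):
        fit = fit_linear_calibration([(1.0, 55.0), (2.0, 83.0)])
        assert CalibrationFit.from_json(fit.to_json()) == fit


@pytest.mark.parametrize("dialect", ["wide", "long"])
def test_frames_csv_round_trip(tmp_path, rng, dialect):
    frames = [random_frame(rng) for _ in range(5)]
    for i, f in enumerate(frames):
        f.timestamp = i * 0.02
    path = tmp_path / "frames.csv"
    write_frames_csv(frames, path, dialect=dialect)
    back = read_frames_csv(path)
    assert len(back) == 5
    for a, b in zip(frames, back):
        assert a.timestamp == b.timestamp
        assert a.readings == b.readings


def test_unrecognized_csv_header_rejected(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("a,b,c\n1,2,3\n")
    with pytest.raises(StructuralError, match="header"):
        read_frames_csv(path)
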