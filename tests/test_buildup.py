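"""Build-up model, calibration, detection and distance inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaii.buildup import (
    CALIBRATION_DISTANCES,
    BuildupParams,
    Curve,
    calibrate,
    detect_crosspeak,
    fit_distance,
    infer_distance,
    normalize_to_control,
    simulate_buildup,
)
from metaii.synthetic import (
    DEFAULT_NOISE_RMS,
    GroundTruthGeometry,
    NoiseModel,
    calibration_geometry,
    generate_buildup_dataset,
)


def make_curve(r, params, grid, noise_rms=0.0, rng=None, pair="x"):
    y = simulate_buildup(r, params, grid)
    if rng is not None and noise_rms > 0:
        y = y + rng.normal(0, noise_rms, y.shape)
    return Curve(grid, y, noise_rms=noise_rms, pair=pair)


class TestSimulate:
    def test_zero_mixing_time_gives_zero_intensity(self, params, grid):
        assert simulate_buildup(3.0, params, np.insert(grid, 0, 0.0))[0] == 0.0

    def test_reference_distance_recovers_reference_rate(self, params):
        assert params.rate(params.r_ref) == pytest.approx(params.k_ref)

    def test_rejects_nonpositive_distance(self, params, grid):
        with pytest.raises(ValueError):
            simulate_buildup(-1.0, params, grid)

    def test_closer_pair_is_brighter_everywhere(self, params, grid):
        i_near = simulate_buildup(2.4, params, grid)
        i_far = simulate_buildup(4.6, params, grid)
        assert np.all(i_near > i_far)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(r1=st.floats(1.2, 7.5), r2=st.floats(1.2, 7.5))
    def test_intensity_strictly_decreasing_in_distance(self, r1, r2):
        """Monotonicity makes the inversion unique on the search interval."""
        params, grid = BuildupParams(), np.asarray([50.0, 200.0, 800.0])
        if abs(r1 - r2) < 1e-6:
            return
        lo, hi = sorted((r1, r2))
        i_lo = simulate_buildup(lo, params, grid)
        i_hi = simulate_buildup(hi, params, grid)
        assert np.all(i_lo >= i_hi)
        # strict somewhere: saturated long-time points can be float-equal
        assert np.any(i_lo > i_hi)


class TestNormalization:
    def test_scale_invariance(self, params, grid):
        table = generate_buildup_dataset(calibration_geometry(), params)
        doubled = table.copy()
        doubled.df["intensity"] *= 2.0
        a = normalize_to_control(table, "C12-C20")
        b = normalize_to_control(doubled, "C12-C20")
        np.testing.assert_allclose(a.df["intensity"], b.df["intensity"], rtol=1e-8)

    def test_control_plateau_becomes_one(self, params):
        big = BuildupParams(amp=7.3)
        table = generate_buildup_dataset(calibration_geometry(), big)
        norm = normalize_to_control(table, "C12-C20")
        from metaii.buildup import fitted_plateau

        assert fitted_plateau(norm.curve("C12-C20")) == pytest.approx(1.0, abs=1e-6)

    def test_idempotence(self, calibration_table):
        again = normalize_to_control(calibration_table, "C12-C20")
        np.testing.assert_allclose(again.df["intensity"],
                                   calibration_table.df["intensity"], atol=1e-9)

    def test_missing_control_time_is_named(self, params, grid):
        table = generate_buildup_dataset(calibration_geometry(), params)
        df = table.df[~((table.df["pair"] == "C12-C20")
                        & (table.df["t_mix_ms"] == 400.0))]
        from metaii.buildup import CrosspeakTable

        with pytest.raises(ValueError, match="400"):
            normalize_to_control(CrosspeakTable(df), "C12-C20")


class TestCalibration:
    def test_noiseless_self_consistency(self, calibrated, params):
        assert calibrated.params.k_ref == pytest.approx(params.k_ref, rel=1e-6)
        assert calibrated.params.T_damp == pytest.approx(params.T_damp, rel=1e-6)
        assert calibrated.params.amp == pytest.approx(params.amp, rel=1e-6)

    def test_noiseless_residuals_vanish(self, calibrated):
        assert all(v < 1e-8 for v in calibrated.per_pair_rmsd.values())
        assert calibrated.outliers == []

    def test_underdetermined_set_rejected(self, calibration_table):
        with pytest.raises(ValueError, match="3 distinct"):
            calibrate(calibration_table, {"C5-C18": 1.4, "C12-C20": 2.4,
                                          "C8-C19": 2.4})

    def test_unnormalized_table_rejected(self, params):
        table = generate_buildup_dataset(calibration_geometry(), params)
        with pytest.raises(ValueError, match="normalized"):
            calibrate(table, CALIBRATION_DISTANCES)

    def test_mislabeled_distance_flagged_as_outlier(self, params):
        """A calibration pair whose nominal distance is off by 2 Å stands out
        in the per-pair residuals."""
        table = generate_buildup_dataset(calibration_geometry(), params)
        norm = normalize_to_control(table, "C12-C20")
        wrong = dict(CALIBRATION_DISTANCES)
        wrong["Cys187CB-Gly188CA"] = 2.6  # truly 4.6
        cal = calibrate(norm, wrong)
        assert max(cal.per_pair_rmsd, key=cal.per_pair_rmsd.get) == \
            "Cys187CB-Gly188CA"
        assert cal.outliers == ["Cys187CB-Gly188CA"]


class TestInversion:
    @pytest.mark.parametrize("r", [1.5, 2.0, 2.4, 3.6, 4.6, 5.3, 5.6, 6.0])
    def test_noiseless_round_trip(self, r, calibrated, grid):
        curve = make_curve(r, calibrated.params, grid)
        r_hat, _ = fit_distance(curve, calibrated.params)
        assert r_hat == pytest.approx(r, abs=1e-3)

    def test_agrees_with_fine_grid_search_oracle(self, calibrated, grid):
        """Brute-force 1-D scan at 0.001 Å resolution is the independent
        inversion oracle."""
        params = calibrated.params
        for r in (2.1, 3.3, 4.9, 5.8):
            curve = make_curve(r, params, grid)
            rs = np.arange(1.0, 8.0, 0.001)
            models = np.array([simulate_buildup(x, params, grid) for x in rs])
            sse = ((models - curve.intensity) ** 2).sum(axis=1)
            oracle = rs[int(np.argmin(sse))]
            r_hat, _ = fit_distance(curve, params)
            assert abs(r_hat - oracle) < 0.05

    def test_estimate_at_printed_calibration_distance(self, calibrated, grid):
        est = infer_distance(make_curve(4.6, calibrated.params, grid),
                             calibrated.params, n_mc=0)
        assert est.status == "estimated"
        assert est.r_hat == pytest.approx(4.6, abs=1e-3)

    def test_pure_noise_curve_is_absent(self, params, grid):
        rng = np.random.default_rng(0)
        curve = Curve(grid, rng.normal(0, 1e-3, grid.shape), noise_rms=1e-3)
        est = infer_distance(curve, params)
        assert est.status == "absent"
        assert est.r_hat is None
        assert 6.0 <= est.detection_limit <= 6.5

    def test_all_zero_noiseless_curve_is_absent(self, params, grid):
        est = infer_distance(Curve(grid, np.zeros_like(grid)), params)
        assert est.status == "absent"

    def test_sigma_shrinks_with_noise(self, calibrated, grid):
        """Monte-Carlo uncertainty decreases monotonically with the noise RMS."""
        sigmas = []
        for i, noise in enumerate([0.004, 0.002, 0.001]):
            curve = make_curve(5.0, calibrated.params, grid, noise_rms=noise)
            est = infer_distance(curve, calibrated.params, n_mc=120, seed=5 + i)
            sigmas.append(est.sigma)
        assert sigmas[0] > sigmas[1] > sigmas[2]

    def test_noisy_recovery_near_truth(self, calibrated, grid):
        """Replicate-averaged 5.6 Å curves invert close to truth with the
        spread the noise level supports."""
        rng = np.random.default_rng(11)
        r_hats = [
            fit_distance(make_curve(5.6, calibrated.params, grid,
                                    noise_rms=DEFAULT_NOISE_RMS, rng=rng),
                         calibrated.params)[0]
            for _ in range(100)
        ]
        assert np.mean(r_hats) == pytest.approx(5.6, abs=0.15)
        assert 0.1 < np.std(r_hats) < 0.45


class TestDetection:
    def test_strong_peak_present(self, grid):
        curve = Curve(grid, np.full_like(grid, 0.01), noise_rms=0.001)
        assert detect_crosspeak(curve)

    def test_subthreshold_peak_absent(self, grid):
        curve = Curve(grid, np.full_like(grid, 0.0009), noise_rms=0.001)
        assert not detect_crosspeak(curve)

    def test_seven_angstrom_pair_mostly_absent(self, params, grid):
        """At the default SNR a 7 Å pair falls below the 3x-RMS threshold in
        at least 95% of noise replicates, matching the 6-6.5 Å
        observability limit."""
        rng = np.random.default_rng(42)
        clean = simulate_buildup(7.0, params, grid)
        absent = 0
        for _ in range(200):
            y = clean + rng.normal(0, DEFAULT_NOISE_RMS, grid.shape)
            absent += not detect_crosspeak(Curve(grid, y, noise_rms=DEFAULT_NOISE_RMS))
        assert absent >= 190


class TestGenerator:
    def test_noiseless_table_matches_closed_form(self, params, grid):
        geom = GroundTruthGeometry(pairs={"C12-C20": 2.4})
        table = generate_buildup_dataset(geom, params, grid)
        np.testing.assert_array_equal(
            table.curve("C12-C20").intensity, simulate_buildup(2.4, params, grid))

    def test_calibration_curves_ordered_by_distance(self, params, grid):
        table = generate_buildup_dataset(calibration_geometry(), params, grid)
        curves = {p: table.curve(p).intensity
                  for p in CALIBRATION_DISTANCES}
        order = sorted(CALIBRATION_DISTANCES, key=CALIBRATION_DISTANCES.get)
        for near, far in zip(order, order[1:]):
            if CALIBRATION_DISTANCES[near] == CALIBRATION_DISTANCES[far]:
                np.testing.assert_array_equal(curves[near], curves[far])
            else:
                assert np.all(curves[near] > curves[far])

    def test_seeded_generation_is_bit_identical(self, params, grid):
        noise = NoiseModel(noise_rms=0.01, seed=7, replicate_count=3)
        a = generate_buildup_dataset(calibration_geometry(), params, grid, noise)
        b = generate_buildup_dataset(calibration_geometry(), params, grid, noise)
        assert a.df.equals(b.df)

    def test_rejects_bad_grid_and_empty_geometry(self, params):
        with pytest.raises(ValueError):
            generate_buildup_dataset(calibration_geometry(), params, grid=[])
        with pytest.raises(ValueError):
            generate_buildup_dataset(calibration_geometry(), params,
                                     grid=[-10.0, 50.0])
        with pytest.raises(ValueError):
            GroundTruthGeometry(pairs={})

    def test_tsv_round_trip(self, tmp_path, params, grid):
        from metaii.buildup import CrosspeakTable

        table = generate_buildup_dataset(
            calibration_geometry(), params, grid,
            NoiseModel(noise_rms=0.004, seed=3))
        path = tmp_path / "peaks.tsv"
        table.to_tsv(path)
        back = CrosspeakTable.from_tsv(path)
        assert back.normalized == table.normalized
        np.testing.assert_allclose(back.df["intensity"], table.df["intensity"],
                                   rtol=1e-12)
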