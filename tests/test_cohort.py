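"""Synthetic cohort: setup-error model, phantom, fraction delivery, container."""

import json

import numpy as np
import pytest

from igsched import (
    CohortConfig,
    ConfigError,
    GenerationError,
    build_phantom,
    compute_dvh,
    deliver_fraction,
    dvh_metric,
    generate_cohort,
    load_cohort,
    sample_setup_errors,
    simulate_cohort,
)


class TestSetupErrors:
    def test_degenerate_noise_gives_exact_zeros(self, zero_noise_config):
        series = sample_setup_errors(zero_noise_config, 1)
        assert np.all(series.pre_shift == 0.0)
        assert np.all(series.post_shift == 0.0)

    def test_pre_correction_spread_matches_mixture_sd(self):
        # per-axis pre-correction SD should be sqrt(3^2 + 3^2) = 4.243 mm;
        # the 25-fraction sample SD has SE ~ sigma/sqrt(2(n-1)), allow 3 SE
        config = CohortConfig(seed=7)
        series = sample_setup_errors(config, 1)
        sd = series.pre_shift.std(axis=0, ddof=1)
        expected = np.hypot(3.0, 3.0)
        se = expected / np.sqrt(2 * (config.n_fractions - 1))
        assert np.all(np.abs(sd - expected) < 3 * se + expected * 0.5)

    def test_pooled_variance_matches_systematic_plus_random(self):
        # pooled over >= 1e4 draws the per-axis variance estimator should
        # approach sigma_sys^2 + sigma_rand^2 = 18 mm^2
        config = CohortConfig(n_patients=400, seed=11)
        draws = np.concatenate(
            [sample_setup_errors(config, pid).pre_shift for pid in range(1, 401)]
        )
        assert draws.shape[0] == 400 * 25
        var = draws.var(axis=0)
        assert np.all(np.abs(var - 18.0) / 18.0 < 0.10)

    def test_same_seed_and_patient_reproduces_bitwise(self):
        config = CohortConfig(seed=42)
        a = sample_setup_errors(config, 3)
        b = sample_setup_errors(config, 3)
        assert np.array_equal(a.pre_shift, b.pre_shift)
        assert np.array_equal(a.post_shift, b.post_shift)

    def test_different_patients_differ(self):
        config = CohortConfig(seed=42)
        a = sample_setup_errors(config, 1)
        b = sample_setup_errors(config, 2)
        assert not np.array_equal(a.pre_shift, b.pre_shift)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(sigma_random=-1.0)


class TestPhantom:
    def test_plan_quality_gate_d95(self, tiny_config, tiny_phantom):
        planned, masks = tiny_phantom
        for name in ("PTVsc", "PTVcw"):
            d95 = dvh_metric(compute_dvh(planned, masks[name]), "D95")
            assert d95 >= 0.95 * tiny_config.prescription

    def test_oars_get_less_than_targets(self, tiny_phantom):
        planned, masks = tiny_phantom
        ptv_mean = dvh_metric(compute_dvh(planned, masks["PTVcw"]), "Dmean")
        heart_mean = dvh_metric(compute_dvh(planned, masks["heart"]), "Dmean")
        assert heart_mean < ptv_mean

    def test_targets_disjoint_and_all_nonempty(self, tiny_phantom):
        _, masks = tiny_phantom
        assert not (masks["PTVsc"].values & masks["PTVcw"].values).any()
        for mask in masks.values():
            assert mask.n_voxels > 0

    def test_zero_penumbra_gives_binary_field(self):
        config = CohortConfig(grid_shape=(20, 20, 20), penumbra_width=0.0)
        planned, masks = build_phantom(config)
        values = np.unique(planned.values)
        assert set(values) <= {0.0, config.prescription}
        ptv = masks["PTVsc"].values | masks["PTVcw"].values
        assert np.all(planned.values[ptv] == config.prescription)

    def test_too_small_grid_rejected(self):
        with pytest.raises(GenerationError):
            build_phantom(CohortConfig(grid_shape=(4, 4, 4)))


class TestDeliverFraction:
    def test_zero_shift_is_planned_over_n(self, tiny_config, tiny_phantom):
        planned, _ = tiny_phantom
        fx = deliver_fraction(planned, (0, 0, 0), tiny_config.n_fractions)
        np.testing.assert_allclose(
            fx.values, planned.values / tiny_config.n_fractions, rtol=1e-12
        )

    def test_integer_voxel_shift_is_index_shift(self, tiny_phantom):
        planned, _ = tiny_phantom
        fx = deliver_fraction(planned, (planned.spacing, 0, 0), 1)
        # patient moved +x by one voxel: dose pattern shifts one index down in x
        np.testing.assert_allclose(
            fx.values[:, :, :-1], planned.values[:, :, 1:], atol=1e-12
        )

    def test_large_lateral_shift_degrades_single_fraction_d95(self, tiny_phantom):
        planned, masks = tiny_phantom
        base = dvh_metric(
            compute_dvh(deliver_fraction(planned, (0, 0, 0), 25), masks["PTVcw"],
                        bin_width=0.01),
            "D95",
        )
        shifted = dvh_metric(
            compute_dvh(deliver_fraction(planned, (10, 0, 0), 25), masks["PTVcw"],
                        bin_width=0.01),
            "D95",
        )
        assert shifted < base

    def test_shift_beyond_extent_rejected(self, tiny_phantom):
        planned, _ = tiny_phantom
        extent = planned.shape[2] * planned.spacing
        with pytest.raises(ValueError):
            deliver_fraction(planned, (extent + 1, 0, 0), 25)


class TestContainer:
    def test_counts_and_roundtrip(self, tmp_path):
        config = CohortConfig(
            n_patients=2, n_fractions=3, grid_shape=(16, 16, 16), seed=9
        )
        out = generate_cohort(config, tmp_path / "cohort")
        grids = list(out.glob("patient_*/fx*_*.f32"))
        assert len(grids) == 2 * 3 * 2  # patients x fractions x (pre, post)

        loaded = load_cohort(out)
        sim = simulate_cohort(config)
        assert loaded.patient_ids == sim.patient_ids
        for pid in sim.patient_ids:
            for fa, fb in zip(loaded.fractions(pid), sim.fractions(pid)):
                np.testing.assert_allclose(
                    fa.dose_pre.values, fb.dose_pre.values, atol=1e-5
                )
                np.testing.assert_allclose(
                    fa.dose_post.values, fb.dose_post.values, atol=1e-5
                )

    def test_manifest_is_deterministic(self, tmp_path):
        config = CohortConfig(
            n_patients=2, n_fractions=2, grid_shape=(16, 16, 16), seed=4
        )
        a = generate_cohort(config, tmp_path / "a") / "manifest.json"
        b = generate_cohort(config, tmp_path / "b") / "manifest.json"
        assert a.read_bytes() == b.read_bytes()
        manifest = json.loads(a.read_text())
        assert manifest["config_sha256"] == config.digest()

    def test_missing_manifest_is_an_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_cohort(tmp_path)
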