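"""Preprocessing operators: frame dropping, cosine filter, erosion,
CompCor, nuisance regression, variance normalization, RMS motion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from restfc.core import RoiTimeSeries
from restfc.preprocess import (
    NuisanceSet,
    compcor_components,
    cosine_highpass_basis,
    drop_initial_frames,
    erode_mask,
    preprocess_subject,
    regress_nuisance,
    rms_head_motion,
    variance_normalize,
)


class TestDropFrames:
    def test_study_convention_137_minus_4(self, rng):
        ts = RoiTimeSeries(rng.standard_normal((137, 3)), 2.8, list("abc"))
        out = drop_initial_frames(ts, 4)
        assert out.n_frames == 133
        assert out.roi_labels == ts.roi_labels
        np.testing.assert_array_equal(out.data, ts.data[4:])

    def test_zero_drop_is_identity(self, small_series):
        np.testing.assert_array_equal(drop_initial_frames(small_series, 0).data, small_series.data)

    def test_empty_output_forbidden(self, rng):
        ts = RoiTimeSeries(rng.standard_normal((10, 2)), 2.8, ["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            drop_initial_frames(ts, 10)


class TestCosineBasis:
    def test_regressor_count_at_study_parameters(self):
        assert cosine_highpass_basis(133, 2.8, 0.008).shape == (133, 5)

    def test_cutoff_below_fundamental_gives_empty_basis(self):
        with pytest.warns(UserWarning, match="empty basis"):
            basis = cosine_highpass_basis(20, 2.8, 1 / (2 * 20 * 2.8) * 0.9)
        assert basis.shape == (20, 0)

    def test_columns_mutually_orthogonal(self):
        b = cosine_highpass_basis(133, 2.8, 0.02)
        gram = b.T @ b
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_in_band_drift_mostly_removed(self):
        """A 0.004 Hz cosine loses >95% of its variance on the basis."""
        n, tr = 133, 2.8
        t = np.arange(n) * tr
        drift = np.cos(2 * np.pi * 0.004 * t + 0.7)
        X = np.column_stack([np.ones(n), cosine_highpass_basis(n, tr, 0.008)])
        resid = drift - X @ np.linalg.lstsq(X, drift, rcond=None)[0]
        assert resid.var() < 0.05 * drift.var()

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            cosine_highpass_basis(100, 2.8, 0.2)


def _brute_force_erode(mask, iterations):
    out = mask.copy()
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for _ in range(iterations):
        nxt = np.zeros_like(out)
        for idx in np.argwhere(out):
            keep = True
            for off in offsets:
                nb = idx + off
                if np.any(nb < 0) or np.any(nb >= np.array(out.shape)) or not out[tuple(nb)]:
                    keep = False
                    break
            nxt[tuple(idx)] = keep
        out = nxt
    return out


class TestErodeMask:
    def test_solid_cube_erodes_to_center(self):
        cube = np.ones((5, 5, 5), dtype=bool)
        got = erode_mask(cube, 2)
        np.testing.assert_array_equal(got, _brute_force_erode(cube, 2))
        assert got.sum() == 1 and got[2, 2, 2]

    def test_zero_iterations_identity(self, rng):
        mask = rng.random((4, 4, 4)) > 0.3
        np.testing.assert_array_equal(erode_mask(mask, 0), mask)

    def test_erosion_to_empty_raises_with_compartment_name(self):
        with pytest.raises(ValueError, match="WM"):
            erode_mask(np.ones((3, 3, 3), dtype=bool), 2, compartment="WM")

    def test_random_mask_matches_brute_force(self, rng):
        mask = rng.random((6, 6, 6)) > 0.25
        want = _brute_force_erode(mask, 1)
        if want.any():
            np.testing.assert_array_equal(erode_mask(mask, 1), want)


class TestCompCor:
    def test_exact_low_rank_recovery(self):
        from restfc.validation import compcor_subspace_angle

        assert compcor_subspace_angle() < 1e-8

    def test_constant_voxels_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            compcor_components(np.ones((30, 10)), 3)

    def test_explained_variance_ordering(self, rng):
        X = rng.standard_normal((80, 30))
        comps = compcor_components(X, 5)
        Xc = X - X.mean(0)
        # components share the unit-variance scale, so the energy of the
        # voxel loadings decreases with component rank
        energy = np.array([np.sum((Xc.T @ comps[:, k]) ** 2) for k in range(5)])
        assert np.all(np.diff(energy) <= 1e-9)

    def test_unit_variance_and_rank_warning(self, rng):
        low = rng.standard_normal((40, 2)) @ rng.standard_normal((2, 8))
        with pytest.warns(UserWarning, match="rank"):
            comps = compcor_components(low, 5)
        assert comps.shape == (40, 2)
        np.testing.assert_allclose(comps.std(axis=0, ddof=1), 1.0, atol=1e-12)


class TestRegressNuisance:
    def test_signal_equal_to_regressor_vanishes(self, rng):
        mot = rng.standard_normal((50, 6))
        ts = RoiTimeSeries(mot[:, :2].copy(), 2.8, ["a", "b"])
        out = regress_nuisance(ts, NuisanceSet(motion_regressors=mot))
        assert np.abs(out.data).max() < 1e-10

    def test_empty_nuisance_is_demeaning(self, small_series):
        out = regress_nuisance(small_series, NuisanceSet())
        np.testing.assert_allclose(out.data, small_series.data - small_series.data.mean(0), atol=1e-12)

    def test_idempotent(self, small_series, rng):
        nuis = NuisanceSet(
            motion_regressors=rng.standard_normal((60, 6)),
            highpass_basis=cosine_highpass_basis(60, 2.8, 0.02),
        )
        once = regress_nuisance(small_series, nuis)
        twice = regress_nuisance(once, nuis)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self, small_series, rng):
        mot = rng.standard_normal((60, 6))
        nuis = NuisanceSet(motion_regressors=mot)
        out = regress_nuisance(small_series, nuis)
        dots = mot.T @ out.data / (np.linalg.norm(mot, axis=0)[:, None] * np.linalg.norm(out.data, axis=0))
        assert np.abs(dots).max() < 1e-8

    def test_rank_deficient_columns_dropped(self, small_series, rng):
        mot = rng.standard_normal((60, 3))
        dup = np.hstack([mot, mot * 2.0])
        out = regress_nuisance(small_series, NuisanceSet(motion_regressors=dup))
        assert out.data.shape == small_series.data.shape

    def test_frame_mismatch_rejected(self, small_series, rng):
        with pytest.raises(ValueError, match="frames"):
            regress_nuisance(small_series, NuisanceSet(motion_regressors=rng.standard_normal((59, 6))))


class TestVarianceNormalize:
    def test_unit_variance_zero_mean(self, small_series):
        out = variance_normalize(small_series)
        np.testing.assert_allclose(out.data.std(0, ddof=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(out.data.mean(0), 0.0, atol=1e-12)

    @given(scale=st.floats(0.1, 50), offset=st.floats(-100, 100))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance(self, scale, offset):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((40, 3))
        a = variance_normalize(RoiTimeSeries(x, 2.8, list("abc")))
        b = variance_normalize(RoiTimeSeries(scale * x + offset, 2.8, list("abc")))
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)

    def test_zero_variance_column_names_roi(self, rng):
        x = rng.standard_normal((30, 2))
        x[:, 1] = 4.0
        with pytest.raises(ValueError, match="ROI_b"):
            variance_normalize(RoiTimeSeries(x, 2.8, ["ROI_a", "ROI_b"]))


class TestRmsMotion:
    def test_motionless_input_rms_zero(self):
        s = rms_head_motion(np.zeros((20, 6)))
        assert s.rms_motion_mm == 0.0

    def test_rotation_step_projected_to_sphere(self):
        motion = np.zeros((3, 6))
        motion[1:, 3] = 0.02  # one 0.02 rad step, then hold
        s = rms_head_motion(motion, 50.0)
        assert s.framewise_displacements[0] == pytest.approx(1.0)
        assert s.framewise_displacements[1] == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self):
        from restfc.validation import rms_motion_oracle_dev

        assert rms_motion_oracle_dev(n_trials=10) < 1e-12

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            rms_head_motion(np.zeros((1, 6)))


class TestFullPipeline:
    def test_shapes_and_order(self, rng):
        ts = RoiTimeSeries(rng.standard_normal((137, 5)), 2.8, [f"r{k}" for k in range(5)])
        motion = rng.standard_normal((137, 6)) * 0.01
        wm = rng.standard_normal((137, 12))
        csf = rng.standard_normal((137, 12))
        out = preprocess_subject(ts, motion, wm, csf)
        assert out.n_frames == 133 and out.n_roi == 5
        np.testing.assert_allclose(out.data.std(0, ddof=1), 1.0, atol=1e-12)

    def test_nuisance_regression_recovers_clean_correlations(self):
        """Leaked compartment noise inflates spurious |r|; the pipeline
        brings it back down (paired over 20 seeds)."""
        from restfc.synthetic import CohortConfig, NoiseSpec, generate_cohort, generate_motion_and_compartments

        worse = 0
        for s in range(20):
            cfg = CohortConfig(
                n_per_group=(2, 2, 2), n_roi=8, n_frames=100,
                within_lobe_r=0.0, between_lobe_r=0.0,
                noise_spec=NoiseSpec(leak_fraction=0.5, drift_amplitude=0.0), seed=s,
            )
            _, series, _ = generate_cohort(cfg)
            motion, wm, csf, _ = generate_motion_and_compartments(cfg)
            raw = np.abs(np.corrcoef(series[0].data.T)[np.triu_indices(8, 1)]).mean()
            clean = preprocess_subject(series[0], motion[0], wm[0], csf[0])
            post = np.abs(np.corrcoef(clean.data.T)[np.triu_indices(8, 1)]).mean()
            worse += post >= raw
        assert worse <= 2
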