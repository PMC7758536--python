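"""Generator correctness: determinism, injected effects, noise structure."""

import numpy as np
import pytest

from restfc.connectome import static_fc
from restfc.core import edge_index_pairs
from restfc.synthetic import (
    CohortConfig,
    NoiseSpec,
    block_correlation,
    correlation_shift_for_d,
    default_lobe_assignment,
    generate_cohort,
    generate_motion_and_compartments,
    star_cluster_edges,
    synthesize_timeseries,
)


class TestDeterminism:
    def test_same_seed_identical_cohort(self, tiny_cohort_config):
        s1, t1, _ = generate_cohort(tiny_cohort_config)
        s2, t2, _ = generate_cohort(tiny_cohort_config)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.data, b.data)
        assert [vars(a) for a in s1] == [vars(b) for b in s2]

    def test_motion_stream_reproducible_standalone(self, tiny_cohort_config):
        m1, w1, c1, l1 = generate_motion_and_compartments(tiny_cohort_config)
        _ = generate_cohort(tiny_cohort_config)
        m2, *_ = generate_motion_and_compartments(tiny_cohort_config)
        np.testing.assert_array_equal(m1[0], m2[0])

    def test_different_seed_differs(self, tiny_cohort_config):
        import dataclasses

        other = dataclasses.replace(tiny_cohort_config, seed=8)
        _, t1, _ = generate_cohort(tiny_cohort_config)
        _, t2, _ = generate_cohort(other)
        assert not np.allclose(t1[0].data, t2[0].data)


class TestStaticEffects:
    def test_null_config_no_group_difference(self):
        """With delta 0 the group z difference is zero within Monte-Carlo error."""
        edges = ((0, 5), (1, 6))
        cfg = CohortConfig(
            n_per_group=(40, 40, 2), n_roi=8, n_frames=120, effect_edges=edges,
            static_effect_delta=0.0, dynamic_effect_amp=0.0,
            noise_spec=NoiseSpec(leak_fraction=0.0, drift_amplitude=0.0), seed=3,
        )
        subs, series, _ = generate_cohort(cfg)
        Z = np.vstack([static_fc(ts).edge_vector() for ts in series])
        g = np.array([s.group for s in subs])
        iu, ju = edge_index_pairs(8)
        idx = [k for k, (i, j) in enumerate(zip(iu, ju)) if (i, j) in set(edges)]
        diff = Z[g == "nc"][:, idx].mean() - Z[g == "non_impaired"][:, idx].mean()
        se = np.sqrt(Z[:, idx].var() * (1 / 40 + 1 / 40) / len(idx))
        assert abs(diff) < 3 * se

    def test_fisher_z_shift_recovers_closed_form(self):
        """Injected correlation shift recovers the analytic Fisher-z gap."""
        n_roi, delta = 20, 0.3
        hub = n_roi - 1
        edges = star_cluster_edges(hub, list(range(10)))
        base = block_correlation(default_lobe_assignment(n_roi))
        r = float(base[edges[0]])
        cfg = CohortConfig(
            n_per_group=(50, 25, 25), n_roi=n_roi, n_frames=137, effect_edges=edges,
            static_effect_delta=delta, dynamic_effect_amp=0.0, subject_sigma_z=0.0,
            noise_spec=NoiseSpec(leak_fraction=0.0, drift_amplitude=0.0), seed=11,
        )
        subs, series, _ = generate_cohort(cfg)
        Z = np.vstack([static_fc(ts).edge_vector() for ts in series])
        g = np.array([s.group for s in subs])
        iu, ju = edge_index_pairs(n_roi)
        idx = [k for k, (i, j) in enumerate(zip(iu, ju)) if (i, j) in set(edges)]
        per_subj = Z[:, idx].mean(axis=1)
        diff = per_subj[g == "nc"].mean() - per_subj[g != "nc"].mean()
        se = np.sqrt(per_subj[g == "nc"].var(ddof=1) / 50 + per_subj[g != "nc"].var(ddof=1) / 50)
        expected = np.arctanh(r + delta) - np.arctanh(r)
        assert abs(diff - expected) < 3 * se

    def test_effect_recovery_sign_and_magnitude(self):
        """An injected d=0.8 realizes within +-30% through the raw pipeline."""
        n_roi = 20
        edges = star_cluster_edges(n_roi - 1, list(range(10)))
        base = block_correlation(default_lobe_assignment(n_roi))
        r = float(base[edges[0]])
        sigma = CohortConfig.subject_sigma_z
        delta = correlation_shift_for_d(0.8, r, 137, subject_sd=sigma)
        cfg = CohortConfig(
            n_per_group=(50, 25, 25), n_roi=n_roi, n_frames=137, effect_edges=edges,
            static_effect_delta=delta, dynamic_effect_amp=0.0,
            noise_spec=NoiseSpec(leak_fraction=0.0, drift_amplitude=0.0), seed=21,
        )
        subs, series, _ = generate_cohort(cfg)
        Z = np.vstack([static_fc(ts).edge_vector() for ts in series])
        g = np.array([s.group for s in subs])
        iu, ju = edge_index_pairs(n_roi)
        idx = [k for k, (i, j) in enumerate(zip(iu, ju)) if (i, j) in set(edges)]
        dz = Z[g == "nc"][:, idx].mean(axis=0) - Z[g != "nc"][:, idx].mean(axis=0)
        sd = Z[g != "nc"][:, idx].std(axis=0, ddof=1)
        d_hat = (dz / sd).mean()
        assert 0.8 * 0.7 < d_hat < 0.8 * 1.3

    def test_delta_outside_unit_interval_rejected(self):
        cfg = dict(n_per_group=(4, 4, 4), n_roi=8, n_frames=30,
                   effect_edges=((0, 5),), static_effect_delta=0.9)
        with pytest.raises(ValueError, match="outside"):
            generate_cohort(CohortConfig(**cfg))

    def test_invalid_edges_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            CohortConfig(n_per_group=(4, 4, 4), n_roi=8, effect_edges=((5, 3),))


class TestSynthesizeTimeseries:
    def test_two_roi_large_sample_consistency(self, rng):
        cov = np.array([[1.0, 0.6], [0.6, 1.0]])
        ts = synthesize_timeseries(cov, (), n_frames=10_000, tr=2.8, seed=rng)
        r = np.corrcoef(ts.data.T)[0, 1]
        assert abs(r - 0.6) < 0.02

    def test_identity_cov_offdiag_shrinks_with_frames(self):
        out = []
        for n in (200, 5000):
            ts = synthesize_timeseries(np.eye(6), (), n_frames=n, tr=2.8, seed=0)
            r = np.corrcoef(ts.data.T)
            out.append(np.abs(r[np.triu_indices(6, 1)]).mean())
        assert out[1] < out[0] < 0.12

    def test_non_positive_definite_rejected_with_eigenvalue(self):
        cov = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            synthesize_timeseries(cov, (), 50, 2.8, 0)

    def test_modulation_outside_unit_interval_rejected(self):
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        with pytest.raises(ValueError, match="leaves"):
            synthesize_timeseries(cov, ((0, 1, 0.8, 0.01),), 100, 2.8, 0)

    def test_modulated_edge_dominates_windowed_sd(self):
        """At long series length a 0.4-amplitude modulated edge has larger
        windowed-correlation SD than every stationary edge (100 seeds)."""
        from restfc.connectome import dynamic_fc, window_lengths

        n_roi, n_frames = 5, 20_000
        cov = np.eye(n_roi)
        wins = 0
        for s in range(100):
            ts = synthesize_timeseries(cov, ((0, 1, 0.4, 0.02),), n_frames, 2.8, s)
            sd = dynamic_fc(ts, window_lengths(ts, "fixed")).edge_vector()
            wins += int(np.argmax(sd)) == 0  # edge (0,1) first in i<j order
        assert wins >= 95


class TestMotionAndCompartments:
    def test_zero_leak_keeps_rois_independent_of_latents(self, tiny_cohort_config):
        _, series, truth = generate_cohort(tiny_cohort_config)
        lat = truth.noise_components["sub-001"]
        r = np.corrcoef(np.hstack([series[0].data, lat]).T)
        cross = r[:8, 8:]
        assert np.abs(cross).max() < 0.5  # only chance-level correlation

    def test_zero_amplitude_motion_is_all_zero(self):
        cfg = CohortConfig(
            n_per_group=(2, 2, 2), n_roi=4, n_frames=20,
            noise_spec=NoiseSpec(motion_step_mm=0.0), seed=0,
        )
        motion, *_ = generate_motion_and_compartments(cfg)
        assert all(np.all(m == 0) for m in motion)
        subs, _, _ = generate_cohort(cfg)
        assert all(s.rms_motion_mm == 0 for s in subs)

    def test_default_motion_below_study_ceiling(self):
        cfg = CohortConfig(n_per_group=(10, 10, 10), n_roi=4, n_frames=137, seed=5)
        subs, _, _ = generate_cohort(cfg)
        rms = np.array([s.rms_motion_mm for s in subs])
        assert rms.max() < 0.8 and rms.min() > 0

    def test_regressing_true_latents_reduces_spurious_correlation(self):
        """Paired over 20 seeds: removing the leaked components lowers the
        mean |r| between otherwise-unconnected ROIs."""
        worse = 0
        for s in range(20):
            cfg = CohortConfig(
                n_per_group=(2, 2, 2), n_roi=8, n_frames=120,
                within_lobe_r=0.0, between_lobe_r=0.0,
                noise_spec=NoiseSpec(leak_fraction=0.5, drift_amplitude=0.0), seed=s,
            )
            _, series, truth = generate_cohort(cfg)
            x = series[0].data
            lat = truth.noise_components["sub-001"]
            before = np.abs(np.corrcoef(x.T)[np.triu_indices(8, 1)]).mean()
            resid = x - lat @ np.linalg.lstsq(lat, x, rcond=None)[0]
            after = np.abs(np.corrcoef(resid.T)[np.triu_indices(8, 1)]).mean()
            worse += after >= before
        assert worse <= 2

    def test_compartments_share_latents(self, tiny_cohort_config):
        _, wm, csf, lat = generate_motion_and_compartments(tiny_cohort_config)[0:4]
        # latent series explain most compartment variance (leak path exists)
        w = wm[0]
        resid = w - lat[0] @ np.linalg.lstsq(lat[0], w, rcond=None)[0]
        assert resid.var() < 0.5 * w.var()


class TestNullCalibration:
    def test_group_t_statistics_follow_student_t(self):
        """All effects zero: pooled edge-wise contrast t over 50 null
        cohorts is Student t with the model's residual df."""
        from scipy import stats

        from restfc.glm import build_group_design, contrast_nc_gt_fighters, contrast_map, fit_edgewise

        t_all, df = [], None
        for s in range(50):
            cfg = CohortConfig(
                n_per_group=(6, 6, 6), n_roi=10, n_frames=60,
                within_lobe_r=0.0, between_lobe_r=0.0,
                noise_spec=NoiseSpec(leak_fraction=0.0, drift_amplitude=0.0), seed=s,
            )
            subs, series, _ = generate_cohort(cfg)
            Z = np.vstack([static_fc(ts).edge_vector() for ts in series])
            design = build_group_design(subs)
            fit = fit_edgewise(Z, design, 10)
            stat = contrast_map(fit, contrast_nc_gt_fighters(design.p))
            t_all.append(stat.t)
            df = fit.df
        t = np.concatenate(t_all)
        assert stats.kstest(t, stats.t(df).cdf).pvalue > 0.01


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_per_group=(4, 4)),
            dict(n_per_group=(1, 4, 4)),
            dict(n_per_group=(0, 0, 4)),
            dict(n_roi=1),
            dict(static_effect_groups=("controls",)),
        ],
    )
    def test_bad_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**{"n_per_group": (4, 4, 4), "n_roi": 8, **kwargs})

    def test_lobe_map_covers_80_rois(self):
        lobes = default_lobe_assignment(80)
        assert len(lobes) == 80
        assert set(lobes.values()) == {
            "Frontal", "Temporal", "Parietal", "Occipital",
            "CingulateCortex", "Limbic", "Insula", "Sub-cortical",
        }
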