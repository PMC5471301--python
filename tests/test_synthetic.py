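import dataclasses

import numpy as np
import pytest

from hemidti import dti
from hemidti import synthetic as syn


class TestGradientScheme:
    def test_default_has_52_volumes(self):
        scheme = syn.make_gradient_scheme(48, 800.0, 4)
        assert scheme.n_volumes == 52
        assert np.count_nonzero(scheme.bvalues == 0) == 4
        assert np.all(scheme.bvalues[4:] == 800.0)

    def test_minimal_scheme(self):
        scheme = syn.make_gradient_scheme(6, 800.0, 1)
        assert scheme.n_volumes == 7
        norms = np.linalg.norm(scheme.directions[scheme.bvalues > 0], axis=1)
        assert np.allclose(norms, 1.0, atol=1e-6)

    @pytest.mark.parametrize("n", [6, 12, 48, 100])
    def test_no_duplicate_directions(self, n):
        scheme = syn.make_gradient_scheme(n)
        d = scheme.directions[scheme.bvalues > 0]
        dots = d @ d.T
        np.fill_diagonal(dots, -1.0)
        assert dots.max() < 1.0 - 1e-6

    def test_too_few_directions_rejected(self):
        with pytest.raises(ValueError, match="invalid scheme"):
            syn.make_gradient_scheme(5)

    def test_determinism(self):
        a = syn.make_gradient_scheme(20)
        b = syn.make_gradient_scheme(20)
        assert np.array_equal(a.directions, b.directions)


class TestPhantomSpecValidation:
    def test_bad_eigenvalues(self):
        with pytest.raises(ValueError, match="eigenvalues"):
            syn.PhantomSpec(wm_eigenvalues=(3e-4, 1.7e-3, 3e-4))

    def test_bad_reduction_factor(self):
        with pytest.raises(ValueError, match="fa_reduction_factor"):
            syn.PhantomSpec(fa_reduction_factor=1.5)

    def test_tumor_needs_radius(self):
        with pytest.raises(ValueError, match="tumor_radius"):
            syn.PhantomSpec(tumor_center=(5, 10, 5), tumor_hemisphere="left")


class TestBuildPhantom:
    def test_symmetric_phantom_zero_delta(self, small_phantom):
        assert small_phantom.true_global_delta_fa == pytest.approx(0.0, abs=1e-12)

    def test_tumor_fa_below_threshold(self, tumor_phantom):
        fa = tumor_phantom.true_fa_map()
        assert np.all(fa[tumor_phantom.tumor_mask] < 0.2)

    def test_hemisphere_masks_disjoint(self, tumor_phantom):
        left, right = tumor_phantom.hemisphere_masks
        assert not np.any(left & right)

    def test_tumor_across_midline_rejected(self):
        with pytest.raises(ValueError, match="midsagittal"):
            syn.build_phantom(syn.PhantomSpec(
                grid_shape=(24, 24, 12), tumor_center=(11.8, 12, 6),
                tumor_radius=8.0, tumor_hemisphere="left"))

    def test_wrong_hemisphere_label_rejected(self):
        with pytest.raises(ValueError, match="hemisphere"):
            syn.build_phantom(syn.PhantomSpec(
                grid_shape=(24, 24, 12), tumor_center=(6, 12, 6),
                tumor_radius=6.0, tumor_hemisphere="right"))

    def test_true_delta_matches_brute_force(self, tumor_phantom):
        """Independent voxel-loop recomputation from the stored tensor field."""
        ph = tumor_phantom
        fa = np.zeros(ph.tissue_mask.shape)
        for idx in np.argwhere(ph.brain_mask):
            i, j, k = idx
            lam = np.linalg.eigvalsh(ph.tensor_field[i, j, k])[::-1]
            l1, l2, l3 = lam
            num = (l1 - l2) ** 2 + (l1 - l3) ** 2 + (l3 - l2) ** 2
            den = 2 * (l1**2 + l2**2 + l3**2)
            fa[i, j, k] = np.sqrt(num / den) if den > 0 else 0.0
        left, right = ph.hemisphere_masks
        lv = fa[left & (fa > 0.2)]
        rv = fa[right & (fa > 0.2)]
        brute = rv.mean() - lv.mean()  # tumor on the left: healthy - tumor side
        assert ph.true_global_delta_fa == pytest.approx(brute, abs=1e-10)

    def test_reduction_monotonicity(self, tumor_spec):
        deltas = []
        for f in (0.0, 0.02, 0.05, 0.1, 0.2):
            ph = syn.build_phantom(dataclasses.replace(
                tumor_spec, fa_reduction_factor=f))
            deltas.append(ph.true_global_delta_fa)
        assert np.all(np.diff(deltas) > 0)

    def test_derived_delta_equals_thresholded_oracle(self, tumor_spec):
        """fa_reduction 0.1: generator value equals a brute-force mean diff."""
        ph = syn.build_phantom(dataclasses.replace(
            tumor_spec, fa_reduction_factor=0.1))
        fa = ph.true_fa_map()
        left, right = ph.hemisphere_masks
        oracle = fa[right & (fa > 0.2)].mean() - fa[left & (fa > 0.2)].mean()
        assert ph.true_global_delta_fa == pytest.approx(oracle, abs=1e-10)


class TestCalibration:
    @pytest.mark.parametrize("target", [0.021, 0.007, -0.004])
    def test_calibrated_phantom_hits_target(self, tumor_spec, target):
        spec = syn.calibrate_reduction(tumor_spec, target)
        ph = syn.build_phantom(spec)
        assert ph.true_global_delta_fa == pytest.approx(target, abs=1e-9)


class TestSimulateDWI:
    def test_b0_equals_s0_noiseless(self, small_phantom, small_scheme):
        dwi = syn.simulate_dwi(small_phantom, small_scheme, noise_sigma=0)
        b0 = dwi.data[..., 0]
        m = small_phantom.brain_mask
        assert np.allclose(b0[m], small_phantom.s0_map[m])

    def test_isotropic_voxel_closed_form(self, small_scheme):
        """Tumor voxels are isotropic: S = S0 exp(-b d) for every direction."""
        spec = syn.PhantomSpec(grid_shape=(24, 24, 12), voxel_size=(2, 2, 2.8),
                               tumor_center=(6, 12, 6), tumor_radius=6.0,
                               tumor_hemisphere="left")
        ph = syn.build_phantom(spec)
        dwi = syn.simulate_dwi(ph, small_scheme, noise_sigma=0)
        vox = tuple(np.argwhere(ph.tumor_mask)[0])
        d = np.mean(spec.wm_eigenvalues)
        expected = ph.s0_map[vox] * np.exp(-small_scheme.bvalues * d)
        assert np.allclose(dwi.data[vox], expected, rtol=1e-12)

    def test_signal_positivity(self, small_phantom, small_scheme):
        dwi = syn.simulate_dwi(small_phantom, small_scheme, noise_sigma=0)
        m = small_phantom.brain_mask
        sig = dwi.data[m]
        assert np.all(sig > 0)
        assert np.all(sig <= small_phantom.s0_map[m][:, None] + 1e-12)

    def test_seed_determinism(self, small_phantom, small_scheme):
        a = syn.simulate_dwi(small_phantom, small_scheme, seed=7)
        b = syn.simulate_dwi(small_phantom, small_scheme, seed=7)
        c = syn.simulate_dwi(small_phantom, small_scheme, seed=8)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_negative_sigma_rejected(self, small_phantom, small_scheme):
        with pytest.raises(ValueError, match="noise_sigma"):
            syn.simulate_dwi(small_phantom, small_scheme, noise_sigma=-1.0)

    def test_rician_bias_bounded_at_high_snr(self, small_phantom, small_scheme, rng):
        """At SNR > 10 the mean of repeated noisy b0 samples is within 2% of S0."""
        vox = tuple(np.argwhere(small_phantom.brain_mask)[50])
        s0 = small_phantom.s0_map[vox]
        sigma = s0 / 15.0
        n1 = rng.normal(0, sigma, 4000)
        n2 = rng.normal(0, sigma, 4000)
        samples = np.sqrt((s0 + n1) ** 2 + n2**2)
        assert abs(samples.mean() - s0) / s0 < 0.02


class TestCohort:
    def test_session_counts(self):
        spec = syn.CohortSpec(n_controls=3, n_pre_rt=2, n_post_rt=2, seed=5,
                              grid_shape=(20, 20, 10))
        sessions, truth, phantoms = syn.make_longitudinal_cohort(spec)
        assert len(sessions) == 7
        assert len(truth) == 7
        assert sum(s.rt_status == "none" for s in sessions) == 3

    def test_paper_scale_counts(self):
        spec = syn.CohortSpec(n_controls=13, n_pre_rt=12, n_post_rt=38, seed=5,
                              grid_shape=(20, 20, 10))
        # counting only; phantom calibration for 63 sessions is exercised at
        # reduced scale elsewhere
        n = spec.n_controls + spec.n_pre_rt + spec.n_post_rt
        assert n == 63

    def test_pre_rt_delta_t_zero(self):
        spec = syn.CohortSpec(n_controls=1, n_pre_rt=3, n_post_rt=1, seed=2,
                              grid_shape=(20, 20, 10))
        sessions, _, _ = syn.make_longitudinal_cohort(spec)
        for s in sessions:
            if s.rt_status in ("none", "pre"):
                assert s.delta_t_months == 0.0

    def test_truth_table_deterministic(self):
        spec = syn.CohortSpec(n_controls=1, n_pre_rt=1, n_post_rt=2, seed=11,
                              grid_shape=(20, 20, 10))
        _, t1, _ = syn.make_longitudinal_cohort(spec)
        _, t2, _ = syn.make_longitudinal_cohort(spec)
        assert t1 == t2

    def test_calibrated_targets_realized(self):
        spec = syn.CohortSpec(n_controls=0, n_pre_rt=2, n_post_rt=2, seed=3,
                              grid_shape=(24, 24, 12))
        _, truth, phantoms = syn.make_longitudinal_cohort(spec)
        for row, ph in zip(truth, phantoms):
            assert row["true_global_delta_fa"] == pytest.approx(
                row["target_delta_fa"], abs=1e-8)

    def test_session_invariant_validation(self):
        with pytest.raises(ValueError):
            syn.SubjectSession("s", "1", "control", "pre", 0.0, "none")
        with pytest.raises(ValueError):
            syn.SubjectSession("s", "1", "patient", "pre", 3.0, "left")


class TestLongitudinalScalars:
    def test_pre_sessions_at_zero(self, rng):
        dt, vals = syn.simulate_longitudinal_scalars(rng)
        assert len(dt) == 50
        assert np.count_nonzero(dt == 0) == 12
        assert np.all(dt[12:] > 0)

    def test_noiseless_positive_slope_monotone_in_expectation(self, rng):
        dt, vals = syn.simulate_longitudinal_scalars(
            rng, resid_sd=0.0, subject_sd=0.0, pre_sd=0.0, slope=1e-3)
        post = dt > 0
        order = np.argsort(dt[post])
        assert np.all(np.diff(vals[post][order]) >= 0)
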