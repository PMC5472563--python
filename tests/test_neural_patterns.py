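"""Design/GLM, flood-fill ROIs, LOPO MVPA, discrimination, noise ceilings."""

import numpy as np
import pytest
from scipy import ndimage

from scenersa.neural_patterns import (BetaMaps, FoldRdms, build_design,
                                      define_roi_floodfill, fit_glm, hrf,
                                      lopo_rdms, noise_ceiling,
                                      univariate_amplitude,
                                      within_between_discrimination)
from scenersa.synthetic_data import generate_timeseries, generate_voxel_dataset

RNG = np.random.default_rng(8)


class TestDesign:
    def test_40_blocks_under_study_parameters(self):
        design = build_design(n_conditions=10, reps=4)
        assert design.condition_order.size == 40
        assert np.all(np.bincount(design.condition_order) == 4)

    def test_hrf_peaks_near_6s(self):
        t = np.arange(0, 30, 0.01)
        assert t[np.argmax(hrf(t))] == pytest.approx(6.0, abs=0.05)

    def test_brief_event_response_peaks_6s_after_onset(self):
        # single-condition design; response to a block peaks within one TR
        # of onset + 6 s + half the block
        design = build_design(n_conditions=1, reps=1, order_seed=0)
        onset = design.block_onsets[0]
        peak_t = design.frame_times[np.argmax(design.task_matrix[:, 0])]
        assert abs(peak_t - (onset + 6.0)) <= 2 * design.tr + 3.0

    def test_zero_reps_rejected(self):
        with pytest.raises(ValueError):
            build_design(reps=0)

    def test_seeded_order_deterministic(self):
        a = build_design(order_seed=4)
        b = build_design(order_seed=4)
        np.testing.assert_array_equal(a.condition_order, b.condition_order)
        np.testing.assert_allclose(a.matrix, b.matrix)


class TestGlm:
    def test_noiseless_round_trip(self):
        design = build_design(n_conditions=3, reps=2)
        betas = BetaMaps(RNG.standard_normal((3, 4, 4, 2)), np.eye(4))
        series = generate_timeseries(design, betas, noise_sd=0.0)
        recovered = fit_glm(series, design)
        np.testing.assert_allclose(recovered.data, betas.data, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        design = build_design(n_conditions=2, reps=2)
        x = design.matrix
        y = RNG.standard_normal((x.shape[0], 5))
        ours = fit_glm(y, design).data.reshape(2, 5)
        oracle = (np.linalg.inv(x.T @ x) @ x.T @ y)[:2]
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_orthogonal_confound_leaves_task_betas(self):
        design = build_design(n_conditions=2, reps=2, order_seed=1)
        x = design.matrix
        y = RNG.standard_normal((x.shape[0], 4))
        base = fit_glm(y, design).data
        # Gram-Schmidt a confound against the task columns
        c = RNG.standard_normal(x.shape[0])
        c -= x @ np.linalg.lstsq(x, c, rcond=None)[0]
        design_c = build_design(n_conditions=2, reps=2, order_seed=1,
                                confounds=c[:, None])
        with_conf = fit_glm(y, design_c).data
        np.testing.assert_allclose(with_conf, base, atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        design = build_design(n_conditions=2, reps=2, order_seed=1)
        bad = build_design(n_conditions=2, reps=2, order_seed=1,
                           confounds=design.matrix[:, :1])
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(RNG.standard_normal((bad.n_timepoints, 3)), bad)

    def test_all_zero_betas_give_zero_series(self):
        design = build_design(n_conditions=2, reps=1)
        betas = BetaMaps(np.zeros((2, 3, 3, 3)), np.eye(4))
        series = generate_timeseries(design, betas, noise_sd=0.0)
        assert np.all(series == 0)


class TestFloodfillRoi:
    @pytest.fixture(scope="class")
    def blob_map(self):
        # anisotropic blob with a mild gradient so supra-threshold component
        # sizes are dense (a perfectly symmetric blob has whole shells of
        # tied values and attainable sizes jump in steps)
        grid = np.zeros((40, 40, 40))
        grid[20, 20, 20] = 1.0
        blob = ndimage.gaussian_filter(grid, sigma=(5.0, 6.0, 7.0))
        ramp = np.linspace(0, 1e-6, 40)[None, None, :]
        return blob * (1.0 + ramp)

    def test_target_size_achieved_on_smooth_blob(self, blob_map):
        roi = define_roi_floodfill(blob_map, (20, 20, 20), target_size=500)
        assert 498 <= roi.achieved_size <= 502

    def test_connected_and_contains_seed(self, blob_map):
        roi = define_roi_floodfill(blob_map, (20, 20, 20), target_size=300)
        vol = roi.as_volume()
        labels, n = ndimage.label(vol, ndimage.generate_binary_structure(3, 1))
        assert n == 1
        assert vol[20, 20, 20]

    def test_bilateral_volume_is_4000_mm3_per_roi(self, blob_map):
        # 500 voxels at 2 mm isotropic = 4000 mm^3; two hemispheres = 8000
        roi = define_roi_floodfill(blob_map, (20, 20, 20), target_size=500)
        voxel_vol = 2.0 ** 3
        assert roi.achieved_size * voxel_vol == pytest.approx(4000, abs=2 * voxel_vol)

    def test_seed_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            define_roi_floodfill(np.zeros((5, 5, 5)), (2, 2, 2))


class TestLopoRdms:
    def test_identical_subjects_unit_diagonal(self):
        pattern = RNG.standard_normal((5, 60))
        folds = lopo_rdms([], patterns=[pattern] * 4)
        for f in range(4):
            np.testing.assert_allclose(np.diag(folds.stack[f]), 1.0, atol=1e-9)

    def test_voxelwise_mean_normalisation_contract(self):
        patterns = [RNG.standard_normal((6, 40)) for _ in range(4)]
        arr = np.stack(patterns)
        total = arr.sum(axis=0)
        for f in range(4):
            group = (total - arr[f]) / 3
            group -= group.mean(axis=0, keepdims=True)
            assert np.max(np.abs(group.mean(axis=0))) < 1e-10

    def test_planted_model_recovered_at_low_noise(self, random_model_matrix):
        ds = generate_voxel_dataset(6, 10, 3000, random_model_matrix,
                                    signal_sd=1.0, noise_sd=0.3, seed=21)
        folds = lopo_rdms([], patterns=ds.subjects)
        from scenersa.rsa_stats import offdiag_vector
        got = offdiag_vector(folds.mean_symmetric()).values
        want = offdiag_vector(random_model_matrix).values
        assert np.corrcoef(got, want)[0, 1] > 0.8

    def test_per_voxel_offset_invariance(self):
        """Adding a condition-independent per-voxel offset is removed by the
        voxel-wise mean subtraction and leaves every fold unchanged."""
        patterns = [RNG.standard_normal((6, 40)) for _ in range(4)]
        base = lopo_rdms([], patterns=patterns).stack
        offset = RNG.standard_normal(40)
        shifted = [p + offset for p in patterns]
        np.testing.assert_allclose(lopo_rdms([], patterns=shifted).stack, base,
                                   atol=1e-10)

    def test_subject_order_permutes_folds(self):
        patterns = [RNG.standard_normal((5, 30)) for _ in range(5)]
        base = lopo_rdms([], patterns=patterns).stack
        perm = [3, 1, 4, 0, 2]
        permuted = lopo_rdms([], patterns=[patterns[i] for i in perm]).stack
        np.testing.assert_allclose(permuted, base[perm], atol=1e-12)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            lopo_rdms([], patterns=[RNG.standard_normal((4, 10))] * 2)


class TestDiscrimination:
    def test_null_when_within_equals_between(self):
        stack = np.full((5, 4, 4), 0.3)
        res = within_between_discrimination(FoldRdms(stack))
        assert res.t == 0.0 and res.d == 0.0

    def test_df_19_for_20_folds(self):
        stack = np.clip(RNG.standard_normal((20, 10, 10)) * 0.1, -0.9, 0.9)
        assert within_between_discrimination(FoldRdms(stack)).df == 19

    def test_positive_discrimination_with_identity_structure(self):
        """With identity model and strong signal, within > between is
        detected at p < 0.01 in at least 95 of 100 seeded runs."""
        hits = 0
        for seed in range(100):
            ds = generate_voxel_dataset(5, 6, 120, np.eye(6), signal_sd=1.0,
                                        noise_sd=1.0, seed=seed)
            res = within_between_discrimination(lopo_rdms([], patterns=ds.subjects))
            hits += (res.t > 0) and (res.p < 0.01)
        assert hits >= 95


class TestUnivariate:
    def _roi(self):
        from scenersa.neural_patterns import RoiMask
        idx = np.unravel_index(np.arange(27), (3, 3, 3))
        return RoiMask(idx, (3, 3, 3), np.eye(4), 27, 0.0)

    def test_matches_direct_formula(self):
        roi = self._roi()
        betas = [BetaMaps(RNG.standard_normal((4, 3, 3, 3)), np.eye(4))
                 for _ in range(6)]
        res = univariate_amplitude(betas, roi)
        amp = np.stack([b.data.reshape(4, -1).mean(axis=1) for b in betas])
        t = amp.mean(0) / (amp.std(0, ddof=1) / np.sqrt(6))
        np.testing.assert_allclose(res.t, t, atol=1e-10)
        assert res.df == 5

    def test_degenerate_constant_betas_flagged(self):
        roi = self._roi()
        betas = [BetaMaps(np.full((2, 3, 3, 3), 3.0), np.eye(4)) for _ in range(4)]
        with pytest.warns(UserWarning):
            res = univariate_amplitude(betas, roi)
        np.testing.assert_allclose(res.condition_means, 3.0)
        assert np.all(res.undefined)


class TestNoiseCeiling:
    def test_identical_folds_give_unit_ceiling(self):
        m = np.clip(RNG.standard_normal((6, 6)) * 0.2, -0.9, 0.9)
        stack = np.tile(m, (4, 1, 1))
        nc = noise_ceiling(FoldRdms(stack))
        assert nc.lower == pytest.approx(1.0, abs=1e-9)
        assert nc.upper == pytest.approx(1.0, abs=1e-9)

    def test_lower_never_exceeds_upper(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            stack = np.clip(rng.standard_normal((4, 5, 5)) * 0.3, -0.95, 0.95)
            nc = noise_ceiling(FoldRdms(stack))
            assert nc.lower <= nc.upper + 1e-12

    def test_ceiling_decreases_with_noise(self, random_model_matrix):
        """Both bounds fall monotonically (within one standard error across
        seeds) as subject noise grows."""
        noise_grid = [0.3, 1.0, 3.0]
        lowers = np.empty((3, len(noise_grid)))
        for i, seed in enumerate((31, 32, 33)):
            for j, noise in enumerate(noise_grid):
                ds = generate_voxel_dataset(6, 10, 400, random_model_matrix,
                                            signal_sd=1.0, noise_sd=noise, seed=seed)
                lowers[i, j] = noise_ceiling(lopo_rdms([], patterns=ds.subjects)).lower
        mean = lowers.mean(axis=0)
        se = lowers.std(axis=0, ddof=1) / np.sqrt(3)
        assert mean[0] > mean[1] - (se[0] + se[1])
        assert mean[1] > mean[2] - (se[1] + se[2])
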