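"""Laminar fMRI stage: EPI detrending, Gaussian-mixture vein exclusion,
layer assignment, t-value voxel selection, leave-one-run-out decoding."""

import numpy as np
import pytest
from scipy import stats as sps

from fovflow import simulate
from fovflow.containers import LaminarVoxelTable
from fovflow.laminar import (
    assign_layer,
    decode_all_layers,
    decode_leave_one_run_out,
    detrend_epi,
    fit_two_gaussian_mixture,
    flag_vasculature,
    select_voxels_by_t,
)

from conftest import permute_block_labels


class TestDetrendEpi:
    def test_exact_linear_trend_removed(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, (50, 3))
        epi = 3.0 * coords[:, 0] + 100.0
        assert np.allclose(detrend_epi(epi, coords), 0.0, atol=1e-8)
        assert np.allclose(detrend_epi(np.full(50, 7.0), coords), 0.0,
                           atol=1e-8)

    def test_residuals_match_lstsq_oracle_and_shrink_variance(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 10, (200, 3))
        epi = coords @ [2.0, -1.0, 0.5] + rng.normal(0, 1, 200)
        resid = detrend_epi(epi, coords)
        design = np.column_stack([np.ones(200), coords])
        beta, *_ = np.linalg.lstsq(design, epi, rcond=None)
        assert np.allclose(resid, epi - design @ beta, atol=1e-10)
        assert resid.var() < epi.var()
        assert abs(resid.mean()) < 1e-8 * epi.std()

    def test_rank_deficient_coords_fall_back_to_centering(self, caplog):
        epi = np.arange(20.0)
        coords = np.ones((20, 3))  # all voxels at one point
        with caplog.at_level("WARNING"):
            resid = detrend_epi(epi, coords)
        assert np.allclose(resid, epi - epi.mean())
        assert any("rank-deficient" in r.message for r in caplog.records)

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError):
            detrend_epi(np.ones(5), np.ones((5, 3)))


class TestGaussianMixture:
    def test_recovers_planted_memberships(self):
        rng = np.random.default_rng(3)
        x = np.r_[rng.normal(0, 1, 500), rng.normal(10, 1, 50)]
        truth = np.r_[np.zeros(500, dtype=int), np.ones(50, dtype=int)]
        fit = fit_two_gaussian_mixture(x)
        assert fit.converged
        assert (fit.hard_assignment() == truth).mean() >= 0.99
        assert fit.separation > 2

    def test_negation_symmetry(self):
        rng = np.random.default_rng(4)
        x = np.r_[rng.normal(-2, 0.5, 300), rng.normal(3, 1.5, 200)]
        a = fit_two_gaussian_mixture(x)
        b = fit_two_gaussian_mixture(-x)
        assert np.allclose(np.sort(a.means), -np.sort(b.means)[::-1],
                           atol=1e-6)
        assert np.allclose(np.sort(a.sds), np.sort(b.sds), atol=1e-6)

    def test_unimodal_sample_stays_below_separation_gate(self):
        # the separation gate (2 pooled SDs) must suppress exclusions on
        # unimodal data across seeds
        seps = []
        for seed in range(20):
            x = np.random.default_rng(seed).normal(0, 1, 1000)
            seps.append(fit_two_gaussian_mixture(x).separation)
        assert max(seps) < 2

    def test_matches_sklearn_mixture_on_bimodal_sample(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(5)
        x = np.r_[rng.normal(0, 1, 400), rng.normal(6, 2, 200)]
        fit = fit_two_gaussian_mixture(x)
        gm = GaussianMixture(2, covariance_type="spherical", tol=1e-8,
                             n_init=3, random_state=0).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        assert np.allclose(fit.means, gm.means_.ravel()[order], atol=0.05)
        assert np.allclose(fit.weights, gm.weights_[order], atol=0.02)

    def test_invariants_and_errors(self):
        rng = np.random.default_rng(6)
        fit = fit_two_gaussian_mixture(rng.normal(0, 1, 100))
        assert np.isclose(fit.weights.sum(), 1.0)
        assert (fit.sds > 0).all()
        assert np.allclose(fit.responsibilities.sum(axis=1), 1.0)
        assert fit.means[0] <= fit.means[1]
        with pytest.raises(ValueError):
            fit_two_gaussian_mixture(np.arange(10.0))
        with pytest.raises(ValueError, match="degenerate"):
            fit_two_gaussian_mixture(np.full(30, 2.0))


class TestFlagVasculature:
    def test_recovers_planted_vein_mask(self, fmri_small):
        cfg, subjects, truth = fmri_small
        table = subjects[0]["V1_foveal"]
        mask, beta_fit, epi_fit = flag_vasculature(table)
        vein = truth.vein_mask["V1_foveal"][0]
        sens = (mask & vein).sum() / vein.sum()
        frac = mask.mean()
        assert 0.05 <= frac <= 0.15
        assert sens >= 0.9
        assert mask.mean() <= 0.5

    def test_no_veins_and_no_shifts_give_zero_exclusions(self):
        # unimodal betas/EPI: the separation gate must suppress both
        # mixture criteria (ROI at a realistic size; the gate is less
        # reliable on very small voxel samples)
        base = simulate.FmriSimConfig(
            n_subjects=1, rois=(("LOC", 450),), info_profile={}, seed=0)
        masks = []
        for changes in ({"vein_fraction": 0.0},
                        {"vein_beta_shift": 0.0, "vein_epi_shift": 0.0}):
            cfg = simulate.variant(base, **changes)
            subjects, _ = simulate.generate_laminar_fmri(cfg)
            mask, bf, ef = flag_vasculature(subjects[0]["LOC"])
            assert bf.separation < 2 and ef.separation < 2
            assert mask.sum() == 0
            masks.append(mask)
        # shift-free veins are indistinguishable from the no-vein case
        assert np.array_equal(masks[0], masks[1])


class TestAssignLayer:
    @pytest.mark.parametrize("fractions,expected", [
        ((0.05, 0.05, 0.80, 0.05, 0.05), "deep"),
        ((0.60, 0.00, 0.20, 0.10, 0.10), "excluded"),
        ((0.00, 0.70, 0.10, 0.10, 0.10), "excluded"),
        ((0.05, 0.05, 0.45, 0.45, 0.00), "deep"),      # tie: priority
        ((0.05, 0.05, 0.10, 0.40, 0.40), "middle"),    # tie: priority
        ((0.02, 0.03, 0.15, 0.20, 0.60), "superficial"),
    ])
    def test_dominant_fraction_rule(self, fractions, expected):
        assert assign_layer(np.array([fractions]))[0] == expected

    def test_negative_fractions_rejected(self):
        with pytest.raises(ValueError):
            assign_layer(np.array([[0.5, 0.6, -0.1, 0.0, 0.0]]))


class TestSelectVoxelsByT:
    def test_planted_effect_ranked_first_and_matches_oracle(self):
        rng = np.random.default_rng(9)
        betas = rng.normal(0, 1, (40, 24))
        labels = np.r_[np.zeros(12), np.ones(12)]
        betas[17, labels == 1] += 10.0
        sel = select_voxels_by_t(betas, labels, 5)
        assert sel[0] == 17
        t_oracle, _ = sps.ttest_ind(betas[:, labels == 0],
                                    betas[:, labels == 1], axis=1)
        expected = np.argsort(-np.abs(t_oracle), kind="stable")[:5]
        assert np.array_equal(sel, expected)

    def test_saturation_returns_all_voxels_ranked(self):
        rng = np.random.default_rng(10)
        betas = rng.normal(0, 1, (10, 20))
        labels = np.r_[np.zeros(10), np.ones(10)]
        sel = select_voxels_by_t(betas, labels, 300)
        assert sorted(sel) == list(range(10))

    def test_shuffled_labels_change_selection(self):
        rng = np.random.default_rng(11)
        betas = rng.normal(0, 1, (60, 24))
        labels = np.r_[np.zeros(12), np.ones(12)]
        betas[:10, labels == 1] += 3.0
        sel_signal = set(select_voxels_by_t(betas, labels, 10))
        sel_shuffled = set(select_voxels_by_t(
            betas, rng.permutation(labels), 10))
        assert sel_signal != sel_shuffled
        with pytest.raises(ValueError):
            select_voxels_by_t(betas, labels, 0)


class TestDecodeLeaveOneRunOut:
    def test_fold_count_and_accuracy_grid(self, fmri_small):
        cfg, subjects, _ = fmri_small
        res = decode_leave_one_run_out(subjects[0]["V1_foveal"],
                                       "category", "peripheral", k=150)
        assert res.n_folds == cfg.n_runs == 12
        # accuracy is a multiple of 1/(n_folds * per-fold test samples)
        steps = res.accuracy * res.n_folds * 4
        assert abs(steps - round(steps)) < 1e-9

    def test_planted_dissociation_foveal_task(self):
        # foveal-task profile: orientation in every foveal-V1 layer,
        # category absent — orientation decodes, category stays at chance
        cfg = simulate.variant(simulate.default_paper_config("fmri"),
                               n_subjects=1, rois=(("V1_foveal", 150),),
                               seed=13)
        subjects, _ = simulate.generate_laminar_fmri(cfg)
        table = subjects[0]["V1_foveal"]
        ori = decode_leave_one_run_out(table, "orientation", "foveal",
                                       k=150)
        cat = decode_leave_one_run_out(table, "category", "foveal", k=150)
        assert ori.accuracy > 0.9
        assert abs(cat.accuracy - 0.5) <= 0.2

    def test_permuted_labels_decode_at_chance(self, fmri_small):
        _, subjects, _ = fmri_small
        table = subjects[1]["V1_peripheral"]
        mask, _, _ = flag_vasculature(table)
        rng = np.random.default_rng(1)
        accs = [decode_leave_one_run_out(
            permute_block_labels(table, rng), "orientation", "peripheral",
            k=150, vasc_mask=mask).accuracy for _ in range(15)]
        assert 0.40 <= np.mean(accs) <= 0.60

    def test_voxel_permutation_invariance(self, fmri_small):
        _, subjects, _ = fmri_small
        table = subjects[0]["V1_foveal"]
        rng = np.random.default_rng(2)
        perm = rng.permutation(table.n_voxels)
        permuted = LaminarVoxelTable(
            table.betas[perm], table.block_info,
            table.layer_fractions[perm], table.mean_epi[perm],
            table.coords[perm], table.roi)
        a = decode_leave_one_run_out(table, "category", "peripheral", k=80)
        b = decode_leave_one_run_out(permuted, "category", "peripheral",
                                     k=80)
        assert a.accuracy == b.accuracy

    def test_per_layer_decoding_reports_all_layers(self, fmri_small):
        _, subjects, _ = fmri_small
        res = decode_all_layers(subjects[0]["V1_foveal"], "category",
                                "peripheral", k_roi=150, k_layer=100)
        assert set(res.per_layer) == {"deep", "middle", "superficial"}
        assert all(0 <= a <= 1 for a in res.per_layer.values())

    def test_unknown_target_rejected(self, fmri_small):
        _, subjects, _ = fmri_small
        with pytest.raises(ValueError):
            decode_leave_one_run_out(subjects[0]["V1_foveal"], "colour",
                                     "peripheral")
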