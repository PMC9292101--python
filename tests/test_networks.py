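"""Group ICA, dual regression, screening, engagement betas, group maps."""

import numpy as np
import pandas as pd
import pytest

from syncsl import networks as nw
from syncsl import synthdata
from syncsl.networks import ICADecomposition
from syncsl.synthdata import BoldGenParams, NetworkSpec, simulate_bold


@pytest.fixture(scope="module")
def decomposition(small_bold):
    ds, truth = small_bold
    dec = nw.group_ica(ds, n_components=4, seed=3, subject_dim=10)
    return ds, truth, dec


def _matched_recovery(dec, ds, truth):
    true_maps = truth["true_maps"][:, dec.mask.ravel()]
    assignment, rs = nw.match_components(dec.group_maps, true_maps)
    tc_rs = []
    for j in range(len(assignment)):
        per_subj = []
        for s in range(ds.n_subjects):
            t_true = truth["true_timecourses"][s][j]
            if np.std(t_true) == 0:
                continue
            t_est = dec.subject_timecourses[s][assignment[j]]
            per_subj.append(abs(np.corrcoef(t_est, t_true)[0, 1]))
        tc_rs.append(np.mean(per_subj))
    return assignment, np.abs(rs), np.asarray(tc_rs)


class TestGroupIca:
    def test_planted_network_recovery(self, decomposition):
        ds, truth, dec = decomposition
        _, spatial_r, tc_r = _matched_recovery(dec, ds, truth)
        assert np.all(spatial_r > 0.95)
        assert np.all(tc_r > 0.9)

    def test_recovery_stable_across_seeds(self, small_bold):
        ds, truth = small_bold
        metrics = []
        for seed in (11, 12):
            dec = nw.group_ica(ds, n_components=4, seed=seed, subject_dim=10)
            _, spatial_r, _ = _matched_recovery(dec, ds, truth)
            metrics.append(np.round(spatial_r, 3))
        np.testing.assert_allclose(metrics[0], metrics[1], atol=2e-3)

    def test_noiseless_rank2_exact_factorization(self):
        ds, truth = simulate_bold(BoldGenParams(
            n_subjects=3, grid_shape=(8, 8, 6), noise_sd=0.0, motion_sd=0.0,
            seed=2,
        ))
        dec = nw.group_ica(ds, n_components=2, seed=1, subject_dim=4)
        for s in range(3):
            mat = nw._percent_normalize(ds.data[s][dec.mask].T)
            recon = dec.subject_timecourses[s].T @ dec.subject_maps[s]
            resid = np.linalg.norm(mat - recon) / np.linalg.norm(mat)
            assert resid < 1e-6

    def test_dual_regression_equals_ols_oracle(self, decomposition):
        ds, _, dec = decomposition
        s = 0
        mat = nw._percent_normalize(ds.data[s][dec.mask].T)
        # oracle: per-time-point least squares of data on group maps
        oracle = np.linalg.lstsq(dec.group_maps.T, mat.T, rcond=None)[0]
        np.testing.assert_allclose(dec.subject_timecourses[s], oracle, atol=1e-10)

    def test_too_few_subjects_rejected(self, small_bold):
        ds, _ = small_bold
        solo = type(ds)(data=ds.data[:1], tr_s=ds.tr_s,
                        block_timing=ds.block_timing, motion=ds.motion[:1],
                        mask=ds.mask)
        with pytest.raises(ValueError):
            nw.group_ica(solo, n_components=2)

    def test_component_count_above_rank_rejected(self, small_bold):
        ds, _ = small_bold
        with pytest.raises(ValueError, match="[Rr]ank|count|exceeds"):
            nw.group_ica(ds, n_components=10_000)


class TestScreening:
    def test_rim_component_discarded(self, decomposition):
        ds, _, dec = decomposition
        rim = nw.rim_mask(dec.grid_shape)[dec.mask].astype(float)
        doctored = ICADecomposition(
            group_maps=np.vstack([dec.group_maps, rim / np.linalg.norm(rim)]),
            subject_timecourses=[
                np.vstack([tc, np.zeros_like(tc[0])]) for tc in dec.subject_timecourses
            ],
            subject_maps=dec.subject_maps,
            n_components=dec.n_components + 1,
            grid_shape=dec.grid_shape,
            mask=dec.mask,
        )
        retained, report = nw.screen_components(doctored)
        assert dec.n_components not in retained
        assert report.iloc[-1]["edge_fraction"] > 0.5

    def test_motion_locked_component_discarded(self, decomposition):
        ds, _, dec = decomposition
        motion = [m.copy() for m in ds.motion]
        # plant a motion regressor equal to component 0's time course
        motion[0][:, 0] = dec.subject_timecourses[0][0]
        retained, report = nw.screen_components(dec, motion=motion)
        assert 0 not in retained
        assert report.iloc[0]["max_motion_r"] > 0.99

    def test_planted_task_networks_retained(self, decomposition):
        ds, truth, dec = decomposition
        assignment, _, _ = _matched_recovery(dec, ds, truth)
        retained, _ = nw.screen_components(dec, motion=ds.motion)
        for k in assignment:
            assert int(k) in retained


class TestEngagementBetas:
    def test_noiseless_amplitude_recovered_exactly(self):
        """A known time course of amplitude 2 in PL yields a PL-rest beta of 2."""
        timing = synthdata.default_block_design()
        n_trs = int(round((timing["onset_s"] + timing["duration_s"]).max() / 1.5))
        regs = synthdata.condition_regressors(timing, n_trs, 1.5)
        tc = 2.0 * regs["PL"].to_numpy()
        dec = ICADecomposition(
            group_maps=np.zeros((1, 8)), subject_timecourses=[tc[None, :]],
            subject_maps=[np.zeros((1, 8))], n_components=1,
            grid_shape=(2, 2, 2), mask=np.ones((2, 2, 2), bool),
        )
        eng = nw.engagement_betas(dec, timing, tr_s=1.5)
        assert eng.betas[0, 0, 0] == pytest.approx(2.0, abs=1e-6)  # PL - rest
        assert eng.contrast_names == ("PL-rest", "AS-baseline")

    def test_constant_shift_invariance(self, decomposition):
        ds, _, dec = decomposition
        eng1 = nw.engagement_betas(dec, ds.block_timing, motion=ds.motion, tr_s=ds.tr_s)
        shifted = ICADecomposition(
            group_maps=dec.group_maps,
            subject_timecourses=[tc + 7.5 for tc in dec.subject_timecourses],
            subject_maps=dec.subject_maps, n_components=dec.n_components,
            grid_shape=dec.grid_shape, mask=dec.mask,
        )
        eng2 = nw.engagement_betas(shifted, ds.block_timing, motion=ds.motion,
                                   tr_s=ds.tr_s)
        np.testing.assert_allclose(eng1.betas, eng2.betas, atol=1e-8)

    def test_absent_network_contrasts_near_zero(self):
        rng_betas = []
        for seed in range(20):
            net = NetworkSpec(name="idle", center=(4.0, 4.0, 3.0), radius=1.2,
                              amplitudes={"high": {}}, subject_amp_sd=0.0)
            ds, truth = simulate_bold(BoldGenParams(
                n_subjects=2, grid_shape=(8, 8, 6), networks=[net],
                group_labels=["high", "high"], noise_sd=0.5, motion_sd=0.0,
                seed=seed,
            ))
            m = truth["true_maps"][0]
            for s in range(2):
                mat = ds.data[s].reshape(-1, ds.data[s].shape[-1])
                tc = (m @ mat) / (m @ m)
                dec = ICADecomposition(
                    group_maps=np.zeros((1, 8)), subject_timecourses=[tc[None, :]],
                    subject_maps=[np.zeros((1, 8))], n_components=1,
                    grid_shape=(2, 2, 2), mask=np.ones((2, 2, 2), bool),
                )
                eng = nw.engagement_betas(dec, ds.block_timing, tr_s=ds.tr_s)
                rng_betas.append(eng.betas[0, 0, :])
        rng_betas = np.asarray(rng_betas)
        se = rng_betas.std(axis=0, ddof=1) / np.sqrt(len(rng_betas))
        assert np.all(np.abs(rng_betas.mean(axis=0)) < 3 * se + 1e-3)

    def test_outlier_flagged(self):
        """A subject far outside the cohort beta distribution is excluded."""
        timing = synthdata.default_block_design()
        n_trs = int(round((timing["onset_s"] + timing["duration_s"]).max() / 1.5))
        regs = synthdata.condition_regressors(timing, n_trs, 1.5)
        rng = np.random.default_rng(8)
        amps = np.concatenate([1.0 + 0.1 * rng.standard_normal(11), [20.0]])
        dec = ICADecomposition(
            group_maps=np.zeros((1, 8)),
            subject_timecourses=[(a * regs["PL"].to_numpy())[None, :] for a in amps],
            subject_maps=[np.zeros((1, 8))] * 12, n_components=1,
            grid_shape=(2, 2, 2), mask=np.ones((2, 2, 2), bool),
        )
        eng = nw.engagement_betas(dec, timing, tr_s=1.5)
        assert eng.excluded[11, 0, 0]
        assert not eng.excluded[:11, 0, 0].any()

    def test_singular_design_reported(self, decomposition):
        ds, _, dec = decomposition
        motion = [np.zeros_like(m) for m in ds.motion]  # constant columns
        with pytest.raises(ValueError, match="singular|constant"):
            nw.engagement_betas(dec, ds.block_timing, motion=motion, tr_s=ds.tr_s)


class TestGroupStats:
    def test_planted_group_difference_detected(self):
        rng = np.random.default_rng(0)
        n_hi, n_lo = 18, 20
        betas = 0.5 * rng.standard_normal((n_hi + n_lo, 2, 2))
        betas[:n_hi, 0, 0] += 1.5
        eng = nw.NetworkEngagement(
            betas=betas, contrast_names=("PL-rest", "AS-baseline"),
            excluded=np.zeros_like(betas, bool), condition_betas=np.zeros((1, 1, 5)),
        )
        labels = ["high"] * n_hi + ["low"] * n_lo
        out = nw.group_network_stats(eng, labels)
        row = out[(out["component"] == 0) & (out["contrast"] == "PL-rest")].iloc[0]
        assert row["p_between_fdr"] < 0.05

    def test_single_component_fdr_identity(self):
        rng = np.random.default_rng(1)
        betas = rng.standard_normal((12, 1, 2))
        eng = nw.NetworkEngagement(
            betas=betas, contrast_names=("PL-rest", "AS-baseline"),
            excluded=np.zeros_like(betas, bool), condition_betas=np.zeros((1, 1, 5)),
        )
        out = nw.group_network_stats(eng, ["high"] * 6 + ["low"] * 6)
        np.testing.assert_allclose(out["p_between"], out["p_between_fdr"])

    def test_small_group_rejected(self):
        betas = np.random.default_rng(2).standard_normal((6, 1, 2))
        eng = nw.NetworkEngagement(
            betas=betas, contrast_names=("PL-rest", "AS-baseline"),
            excluded=np.zeros_like(betas, bool), condition_betas=np.zeros((1, 1, 5)),
        )
        with pytest.raises(ValueError):
            nw.group_network_stats(eng, ["high"] * 3 + ["low"] * 3)


class TestGroupMap:
    def _subject_maps(self, blob_voxels, n_subj=8, n_vox=1000, signal=1.0,
                      noise=0.2, seed=0):
        rng = np.random.default_rng(seed)
        maps = []
        for _ in range(n_subj):
            m = noise * rng.standard_normal(n_vox)
            m[blob_voxels] += signal
            maps.append(m[None, :])
        return maps

    def test_planted_blob_survives_as_single_cluster(self):
        mask = np.ones((10, 10, 10), bool)
        blob = np.zeros((10, 10, 10), bool)
        blob[2:7, 2:7, 2:6] = True  # 100 voxels
        idx = np.where(blob.ravel())[0]
        maps = self._subject_maps(idx, signal=1.0, noise=0.15, seed=3)
        gm = nw.group_map(maps, 0, mask, voxel_p=0.001, extent=50)
        assert len(gm.clusters) == 1
        center = gm.clusters[0]["center"]
        blob_com = [float(np.mean(c)) for c in np.where(blob)]
        assert np.allclose(center, blob_com, atol=1.5)

    def test_undersized_cluster_removed(self):
        mask = np.ones((10, 10, 10), bool)
        blob = np.zeros((10, 10, 10), bool)
        blob[1:8, 1:8, 1] = True  # 49 voxels
        idx = np.where(blob.ravel())[0]
        maps = self._subject_maps(idx, signal=2.0, noise=0.1, seed=4)
        gm = nw.group_map(maps, 0, mask, voxel_p=0.001, extent=50)
        assert gm.clusters == []
        assert not gm.thresholded_mask.any()
        gm2 = nw.group_map(maps, 0, mask, voxel_p=0.001, extent=49)
        assert any(c["size"] >= 49 for c in gm2.clusters)

    def test_null_voxelwise_calibration(self):
        """Pure-noise maps exceed the voxel threshold at about the nominal rate."""
        rng = np.random.default_rng(5)
        frac = []
        mask = np.ones((10, 10, 10), bool)
        for _ in range(100):
            maps = [rng.standard_normal(1000)[None, :] for _ in range(12)]
            gm = nw.group_map(maps, 0, mask, voxel_p=0.001, extent=1)
            from scipy import stats as sps

            t_crit = sps.t.isf(0.001, df=11)
            frac.append(np.mean(gm.t_map[mask] > t_crit))
        assert abs(np.mean(frac) - 0.001) < 0.0008

    def test_permutation_pruning_runs(self):
        mask = np.ones((8, 8, 8), bool)
        blob = np.zeros((8, 8, 8), bool)
        blob[1:6, 1:6, 1:5] = True
        idx = np.where(blob.ravel())[0]
        maps = self._subject_maps(idx, n_vox=512, signal=1.5, noise=0.2, seed=6)
        gm = nw.group_map(maps, 0, mask, voxel_p=0.001, extent=50,
                          n_permutations=200, seed=1)
        assert len(gm.clusters) == 1
        assert gm.clusters[0]["fwe_p"] < 0.05

    def test_bad_extent_rejected(self):
        with pytest.raises(ValueError):
            nw.group_map([np.zeros((1, 10))] * 3, 0, np.ones((10, 1, 1), bool),
                         extent=0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            nw.group_map([np.zeros((1, 10))] * 2, 0, np.ones((10, 1, 1), bool))


class TestMatchComponents:
    def test_sign_and_order_resolution(self):
        rng = np.random.default_rng(7)
        true = rng.standard_normal((3, 500))
        shuffled = np.vstack([-true[2], true[0], -true[1]])
        assignment, rs = nw.match_components(shuffled, true)
        assert assignment.tolist() == [1, 2, 0]
        np.testing.assert_allclose(np.abs(rs), 1.0, atol=1e-12)
        assert rs[1] < 0 and rs[2] < 0  # sign information preserved
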