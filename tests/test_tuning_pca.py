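"""Non-centered PCA of tuning weights, jackknife component test, PC
matching and consistency, theoretical-dimension correlations."""

import numpy as np
import pytest

from affectencode import synthetic as syn
from affectencode.encoding import WeightTensor, loo_run_weights, select_lambda
from affectencode.feature_space import build_feature_space
from affectencode.preprocess import preprocess_pipeline
from affectencode.tuning_pca import (
    JACKKNIFE_MIN_P,
    build_theoretical_dimensions,
    dim_pc_correlation,
    jackknife_pc_test,
    loocv_consistency,
    match_pcs,
    noncentered_pca,
    peak_weights,
    stimulus_pca,
)


def _wt(bins, n_feat=5):
    """Weight tensor with a constant per-bin profile on every feature."""
    W = np.tile(np.asarray(bins, dtype=float), (2, n_feat, 1))
    return WeightTensor(W, [f"f{i}" for i in range(n_feat)], "toy", 0.0)


class TestPeakWeights:
    def test_peak_bin_average(self):
        M, _ = peak_weights(_wt([0, 2, 4, 0]))
        assert np.all(M == 3.0)
        M, _ = peak_weights(_wt([5, 5, 5, 5]))
        assert np.all(M == 5.0)

    def test_missing_bins_rejected(self):
        W = np.zeros((2, 5, 2))
        wt = WeightTensor(W, [f"f{i}" for i in range(5)], "toy", 0.0)
        with pytest.raises(ValueError):
            peak_weights(wt)

    def test_plants_vehicles_columns_dropped(self):
        space = build_feature_space("CSVA", include_plants_vehicles=True)
        W = np.zeros((3, len(space), 4))
        wt = WeightTensor(W, space.feature_names, "CSVA", 0.0)
        M, names = peak_weights(wt, space)
        assert M.shape[1] == 144
        assert not any("Plants" in n or "Vehicles" in n for n in names)


class TestNoncenteredPCA:
    def test_rank_one_exact(self, rng):
        u = rng.standard_normal(30)
        v = rng.standard_normal(8)
        M = np.outer(u, v)
        dec = noncentered_pca(M)
        assert dec.variance_fraction[0] == pytest.approx(1.0)
        recon = dec.scores[:, :1] @ dec.loadings[:, :1].T
        assert np.allclose(recon, M, atol=1e-10)

    def test_variance_fractions_conserve(self, rng):
        M = rng.standard_normal((40, 6))
        dec = noncentered_pca(M)
        assert dec.variance_fraction.sum() == pytest.approx(1.0)

    def test_reconstruction_error_equals_discarded_energy(self, rng):
        M = rng.standard_normal((50, 10))
        dec_full = noncentered_pca(M)
        k = 4
        dec = noncentered_pca(M, k=k)
        recon = dec.scores @ dec.loadings.T
        err = ((M - recon) ** 2).sum()
        discarded = (dec_full.singular_values[k:] ** 2).sum()
        assert abs(err - discarded) / discarded < 1e-10

    def test_no_centering(self):
        # a matrix with a large constant offset: the first non-centered PC
        # is the mean direction, unlike centered PCA
        M = np.ones((20, 4)) + 1e-3 * np.random.default_rng(0).standard_normal((20, 4))
        dec = noncentered_pca(M)
        assert dec.variance_fraction[0] > 0.99
        assert np.allclose(np.abs(dec.loadings[:, 0]), 0.5, atol=0.01)

    def test_planted_factors_recovered(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((12, 3)))
        scores = rng.standard_normal((300, 3)) * [3.0, 2.0, 1.0]
        M = scores @ Q.T + 0.02 * rng.standard_normal((300, 12))
        dec = noncentered_pca(M, k=3)
        C = np.abs(Q.T @ dec.loadings)  # planted x recovered
        matched = C.max(axis=1)
        assert np.all(matched >= 0.95)

    def test_sign_convention(self, rng):
        M = rng.standard_normal((30, 6))
        dec = noncentered_pca(M)
        for j in range(dec.n_components):
            col = dec.loadings[:, j]
            assert col[np.abs(col).argmax()] > 0

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            noncentered_pca(np.zeros((5, 3)))


class TestStimulusPCA:
    def test_one_hot_rows_align_with_axes(self):
        M = np.zeros((30, 5))
        M[:, 2] = 1.0
        dec = stimulus_pca([M])
        assert dec.variance_fraction[0] == pytest.approx(1.0)
        assert dec.loadings[2, 0] == pytest.approx(1.0)

    def test_duplicated_subjects_leave_loadings_unchanged(self, rng):
        M = rng.standard_normal((40, 6))
        d1 = stimulus_pca([M])
        d2 = stimulus_pca([M, M, M])
        assert np.allclose(np.abs(d1.loadings), np.abs(d2.loadings),
                           atol=1e-8)

    def test_variance_fractions_non_increasing(self, rng):
        dec = stimulus_pca([rng.standard_normal((50, 8))])
        assert np.all(np.diff(dec.variance_fraction) <= 1e-12)

    def test_column_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            stimulus_pca([rng.standard_normal((5, 3)),
                          rng.standard_normal((5, 4))])


def _stim_F(seed=0):
    stim = syn.gen_stimulus_set(syn.SimConfig(seed=seed))
    ids = sorted(stim.labels)
    F = np.array([stim.space.encode(stim.labels[i]) for i in ids])
    return stim, F


class TestJackknife:
    def test_null_with_stimulus_covariance_not_significant(self):
        """Replicate weight sets that are pure noise with the stimulus
        covariance carry no tuning structure beyond the stimuli."""
        stim, F = _stim_F(1)
        C = F.T @ F / len(F)
        L = np.linalg.cholesky(C + 1e-9 * np.eye(C.shape[0]))
        sdec = stimulus_pca([F], k=4)
        rng = np.random.default_rng(4)
        hits = 0
        n_sim = 5
        for _ in range(n_sim):
            mats = [rng.standard_normal((200, C.shape[0])) @ L.T
                    for _ in range(30)]
            ret, p = jackknife_pc_test(mats, sdec.loadings, max_k=4)
            hits += (ret == 0)
        assert hits >= n_sim - 1

    def test_planted_structure_retains_three(self):
        cfg = syn.SimConfig(seed=404, snr=2.0, n_est_runs=15, n_voxels=200)
        exp = syn.gen_experiment(cfg, with_raters=False)
        bold = preprocess_pipeline(exp.bold_est, exp.stim.events_est)
        Y = bold.data.T
        lam, _ = select_lambda(exp.design_est, Y)
        loo = loo_run_weights(exp.design_est, Y, lam)
        mats = [peak_weights(w, exp.stim.space)[0] for w in loo]
        ids = sorted(exp.stim.labels)
        F = np.array([exp.stim.space.encode(exp.stim.labels[i])
                      for i in ids])
        sdec = stimulus_pca([F], k=6)
        ret, p = jackknife_pc_test(mats, sdec.loadings, max_k=6)
        assert ret == 3
        assert np.all(p[:3] == JACKKNIFE_MIN_P)

    def test_minimum_reportable_p(self, rng):
        mats = [np.abs(rng.standard_normal((50, 6))) + 5 for _ in range(10)]
        sdec = noncentered_pca(rng.standard_normal((40, 6)))
        _, p = jackknife_pc_test(mats, sdec.loadings, max_k=2)
        assert np.all(p >= JACKKNIFE_MIN_P)

    def test_too_few_replicates_rejected(self, rng):
        with pytest.raises(ValueError):
            jackknife_pc_test([rng.standard_normal((5, 3))] * 2,
                              np.eye(3))


class TestMatchPCs:
    def test_identity(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((20, 3)))
        perm, corr = match_pcs(Q, Q)
        assert list(perm) == [0, 1, 2]
        assert np.allclose(corr, 1.0)

    def test_conflict_resolution_prefers_closest_ordering(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((20, 4)))
        G = Q[:, :3]
        # subject PCs 1 and 2 both resemble group PC 1
        S = np.column_stack([
            G[:, 0] + 0.05 * Q[:, 3],
            G[:, 0] + 0.10 * Q[:, 3],
            G[:, 2],
        ])
        S /= np.linalg.norm(S, axis=0)
        perm, _ = match_pcs(S, G)
        assert perm[0] == 0       # subject PC 1 keeps group PC 1
        assert perm[1] == 1       # subject PC 2 takes its next best
        assert perm[2] == 2

    def test_random_loadings_still_permutation(self, rng):
        for _ in range(10):
            S = rng.standard_normal((15, 3))
            G = rng.standard_normal((15, 3))
            perm, _ = match_pcs(S, G)
            assert sorted(perm) == [0, 1, 2]


class TestLoocvConsistency:
    def _subject_mats(self, rng, shared, n_sub=4, n_vox=150, noise=0.05):
        Q, _ = np.linalg.qr(rng.standard_normal((30, 3)))
        mats = []
        for _ in range(n_sub):
            if shared:
                scores = rng.standard_normal((n_vox, 3)) * [3.0, 2.0, 1.2]
                M = scores @ Q.T + noise * rng.standard_normal((n_vox, 30))
            else:
                M = rng.standard_normal((n_vox, 30))
            mats.append(M)
        return mats

    def test_shared_structure_high_consistency(self, rng):
        mats = self._subject_mats(rng, shared=True)
        df = loocv_consistency(mats, k=3, n_perm=200, seed=0)
        assert (df["r"] > 0.9).all()
        assert (df["p_perm"] == 1.0 / 201.0).all()

    def test_independent_weights_inconsistent(self, rng):
        mats = self._subject_mats(rng, shared=False)
        df = loocv_consistency(mats, k=3, n_perm=200, seed=0)
        assert df["r"].abs().median() < 0.4
        assert (df["p_perm"] > 0.05).mean() > 0.5

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            loocv_consistency(self._subject_mats(rng, True, n_sub=2))


class TestTheoreticalDimensions:
    def test_seven_dimensions_with_expected_codes(self, csva_space):
        dims = build_theoretical_dimensions(csva_space)
        assert len(dims) == 7
        names = csva_space.feature_names
        scale = dims["animacy_scale"]
        assert scale[names.index("Human-Face|neutral|low")] == 3
        assert scale[names.index("Household-Object|neutral|low")] == 0
        assert scale[names.index("Land-Mammal|neutral|low")] == 2
        assert scale[names.index("Insect|neutral|low")] == 1
        assert set(np.unique(scale)) <= {0.0, 1.0, 2.0, 3.0}
        assert set(np.unique(dims["animacy_binary"])) == {0.0, 1.0}

    def test_animate_mean_fill(self, csva_space):
        dims = build_theoretical_dimensions(csva_space)
        feats = csva_space.features
        animate = np.array([bool(f.animate) for f in feats])
        v = dims["valence_animate"]
        assert np.allclose(v[~animate], v[animate].mean())
        a = dims["arousal_animate"]
        assert set(np.unique(a[animate])) <= {0.0, 1.0}

    def test_missing_se_affect_rejected(self, csva_space):
        import copy
        space = copy.deepcopy(csva_space)
        from affectencode.feature_space import Feature
        feats = [Feature(f.name, f.kind, f.category, None, None, f.animate,
                         f.human, f.animacy) if f.kind == "se" else f
                 for f in space.features]
        space.features = feats
        with pytest.raises(ValueError):
            build_theoretical_dimensions(space)


class TestDimPCCorrelation:
    def test_identical_dimension_hits_floor(self, rng):
        load = rng.standard_normal((144, 2))
        dims = {"self": load[:, 0]}
        df = dim_pc_correlation(dims, load, n_boot=200, seed=0)
        row = df[(df.dimension == "self") & (df.pc == 1)].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.p == pytest.approx(1.0 / 201.0)
        assert row.significant

    def test_orthogonal_dimension_not_significant(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((144, 2)))
        dims = {"orth": Q[:, 1] - Q[:, 1].mean()}
        df = dim_pc_correlation(dims, Q[:, :1], n_boot=300, seed=1)
        row = df.iloc[0]
        assert abs(row.r) < 2.0 / np.sqrt(144)
        assert not row.significant

    def test_bootstrap_sd_shrinks_with_features(self, rng):
        sds = []
        for n_feat in (36, 144, 576):
            x = rng.standard_normal(n_feat)
            y = 0.5 * x + rng.standard_normal(n_feat)
            df = dim_pc_correlation({"d": x}, y[:, None], n_boot=300,
                                    seed=2)
            sds.append(df.iloc[0].sd)
        assert sds[0] > sds[1] > sds[2]

    def test_constant_dimension_rejected(self, rng):
        with pytest.raises(ValueError):
            dim_pc_correlation({"c": np.ones(10)},
                               rng.standard_normal((10, 1)))
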