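"""End-to-end validation protocols on synthetic studies.

Each function runs one self-contained study (or batch of studies) from a
seed and returns the summary quantities a user would check before trusting
the pipeline on real data: exactness of the ridge solver against the
normal-equations closed form, calibration of the permutation and FDR
machinery, recovery of planted tuning weights and tuning dimensions,
behavioral-prediction recovery against its inter-rater ceiling, and power /
type-I behavior of the bootstrap model comparison.

The problem sizes are reduced-scale study conditions chosen so the whole
battery runs on one CPU in a few minutes; the methods note records them.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import synthetic as syn
from .behavior import aggregate_responses, loocv_predict, project_images
from .encoding import (
    WeightTensor,
    fit_encoding_model,
    loo_run_weights,
    predict_series,
    ridge_beta,
    select_lambda,
)
from .inference import bootstrap_compare, fdr_bh, permutation_test
from .preprocess import preprocess_pipeline
from .tuning_pca import (
    jackknife_pc_test,
    match_pcs,
    noncentered_pca,
    peak_weights,
    stimulus_pca,
)

__all__ = [
    "ridge_oracle_gap",
    "permutation_null_uniformity",
    "fdr_empirical_rate",
    "parameter_recovery",
    "pc_recovery_and_jackknife",
    "behavior_recovery",
    "bootstrap_comparison_rates",
]


def _seed(base: int, k: int) -> int:
    return (base * 1009 + k) % (2 ** 31 - 1)


def ridge_oracle_gap(seed: int, n_systems: int = 12,
                     max_cols: int = 50) -> float:
    """Max absolute difference between the SVD ridge path and the
    normal-equations closed form over random systems of up to
    ``max_cols`` columns and the full lambda grid."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_systems):
        p = int(rng.integers(2, max_cols + 1))
        n = int(rng.integers(p + 5, 4 * p + 40))
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, 3))
        for lam in np.logspace(-9, 5, 10):
            oracle = np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ Y)
            gap = np.abs(ridge_beta(X, Y, lam) - oracle).max()
            worst = max(worst, float(gap))
    return worst


def permutation_null_uniformity(seed: int, n_voxels: int = 200,
                                n_perm: int = 1000):
    """Permutation p values for voxels whose validation series carry no
    stimulus signal; returns ``(ks_statistic, ks_pvalue)`` against
    Uniform(0, 1)."""
    cfg = syn.SimConfig(seed=_seed(seed, 1), snr=1.0, n_voxels=n_voxels,
                        frac_tuned=0.0, drift_amplitude=0.0, ar_frac=0.0)
    exp = syn.gen_experiment(cfg, with_raters=False)
    rng = np.random.default_rng(_seed(seed, 2))
    wt = exp.wt_true
    wt = WeightTensor(0.1 * rng.standard_normal(wt.weights.shape),
                      wt.feature_names, wt.model_name, 0.0)
    obs = exp.bold_val.data.T - exp.bold_val.data.T.mean(axis=0)
    p, _, _ = permutation_test(wt, exp.stim.events_val, exp.stim.labels,
                               exp.stim.space, obs,
                               exp.stim.run_lengths_val, n_perm=n_perm,
                               seed=_seed(seed, 3))
    ks = stats.kstest(p, "uniform")
    return float(ks.statistic), float(ks.pvalue)


def fdr_empirical_rate(seed: int, reps: int = 500, m_null: int = 80,
                       m_signal: int = 20, q: float = 0.05) -> float:
    """Mean false-discovery proportion of BH over mixed null/signal
    p-value batches (nulls uniform, signals far below threshold)."""
    rng = np.random.default_rng(_seed(seed, 4))
    fdps = []
    for _ in range(reps):
        p = np.concatenate([rng.uniform(size=m_null),
                            rng.uniform(size=m_signal) * 1e-4])
        flags = fdr_bh(p, q=q)
        fdps.append(flags[:m_null].sum() / max(flags.sum(), 1))
    return float(np.mean(fdps))


def _recovery_config(seed: int, n_voxels: int, snr: float = 1.0,
                     **kw) -> syn.SimConfig:
    """Scaled-down study with enough estimation volumes (~4000) to
    identify the 576 design columns."""
    return syn.SimConfig(seed=seed, snr=snr, n_est_runs=30,
                         images_per_est_run=28, n_voxels=n_voxels, **kw)


def parameter_recovery(seed: int, n_voxels: int = 500) -> float:
    """Median over tuned voxels of the correlation between true and
    estimated peak-bin feature weights, at SNR 1."""
    cfg = _recovery_config(_seed(seed, 5), n_voxels)
    exp = syn.gen_experiment(cfg, with_raters=False)
    bold = preprocess_pipeline(exp.bold_est, exp.stim.events_est)
    wt = fit_encoding_model(exp.design_est, bold.data.T, model_name="CSVA")
    Wt = exp.wt_true.weights[:, :, 1:3].mean(axis=2)
    We = wt.weights[:, :, 1:3].mean(axis=2)
    rs = [np.corrcoef(Wt[v], We[v])[0, 1]
          for v in np.flatnonzero(exp.planted.tuned)]
    return float(np.median(rs))


def pc_recovery_and_jackknife(seed: int, n_sims: int = 50,
                              n_runs: int = 20, images_per_run: int = 28,
                              n_voxels: int = 200,
                              snr: float = 2.0) -> dict:
    """Batch of reduced-scale studies: non-centered PCA recovery of the 3
    planted tuning dimensions, and the jackknife component test's retained
    count per study.

    Returns median (over studies) of the worst matched |r| across the 3
    dimensions, the fraction of studies retaining exactly 3 components,
    and the per-study retained counts.
    """
    min_rs, retained = [], []
    for s in range(n_sims):
        cfg = syn.SimConfig(seed=_seed(seed, 10 + s), snr=snr,
                            n_est_runs=n_runs,
                            images_per_est_run=images_per_run,
                            n_voxels=n_voxels)
        exp = syn.gen_experiment(cfg, with_raters=False)
        bold = preprocess_pipeline(exp.bold_est, exp.stim.events_est)
        Y = bold.data.T
        lam, _ = select_lambda(exp.design_est, Y)
        loo = loo_run_weights(exp.design_est, Y, lam)
        mats = [peak_weights(w, exp.stim.space)[0] for w in loo]
        full = np.mean(mats, axis=0)[exp.planted.tuned]
        dec = noncentered_pca(full, k=3)
        _, corrs = match_pcs(exp.planted.loadings, dec.loadings)
        min_rs.append(np.abs(corrs).min())
        ids = sorted(exp.stim.labels)
        F = np.array([exp.stim.space.encode(exp.stim.labels[i])
                      for i in ids])
        sdec = stimulus_pca([F], k=6)
        masked = [m[exp.planted.tuned] for m in mats]
        ret, _ = jackknife_pc_test(masked, sdec.loadings, max_k=6)
        retained.append(ret)
    retained = np.array(retained)
    return {
        "median_min_abs_r": float(np.median(min_rs)),
        "fraction_exactly_3": float((retained == 3).mean()),
        "retained_counts": retained.tolist(),
    }


def behavior_recovery(seed: int, n_voxels: int = 200) -> dict:
    """One study with rater tables linear in the planted dimensions:
    LOOCV scaled R-squared (percent of the analytic inter-rater ceiling)
    from tuning-PCA scores vs stimulus-feature-PCA scores."""
    cfg = _recovery_config(_seed(seed, 6), n_voxels, snr=2.0,
                           behavior_link="linear")
    exp = syn.gen_experiment(cfg)
    ceiling = syn.analytic_explainable_variance(exp.rater_probs,
                                                cfg.n_raters)
    table = aggregate_responses(exp.raters)
    bold = preprocess_pipeline(exp.bold_est, exp.stim.events_est)
    wt = fit_encoding_model(exp.design_est, bold.data.T, model_name="CSVA")
    M, _ = peak_weights(wt, exp.stim.space)
    dec = noncentered_pca(M[exp.planted.tuned], k=10)
    w_scores = project_images(exp.stim.space, exp.stim.labels, dec,
                              n_pcs=10)
    ids = sorted(exp.stim.labels)
    F = np.array([exp.stim.space.encode(exp.stim.labels[i]) for i in ids])
    sdec = stimulus_pca([F], k=10)
    s_scores = project_images(exp.stim.space, exp.stim.labels, sdec,
                              n_pcs=10)
    n_list = [1, 2, 3]
    w_curve = loocv_predict(table, w_scores, n_list, explainable=ceiling)
    s_curve = loocv_predict(table, s_scores, n_list, explainable=ceiling)
    return {
        "analytic_ceiling": float(ceiling),
        "weight_scaled_r2": dict(zip(n_list, w_curve["scaled_r2"])),
        "stimulus_scaled_r2": dict(zip(n_list, s_curve["scaled_r2"])),
    }


def bootstrap_comparison_rates(seed: int, n_power: int = 50,
                               n_null: int = 100,
                               n_boot: int = 500) -> dict:
    """Power of the bootstrap model comparison (true model vs a model
    missing half its features, SNR 1) and its type-I rate under an
    exchangeable null (both models pure noise)."""
    hits = 0
    for s in range(n_power):
        cfg = syn.SimConfig(seed=_seed(seed, 100 + s), snr=1.0, n_voxels=80)
        exp = syn.gen_experiment(cfg, with_raters=False)
        wt = exp.wt_true
        ablated = WeightTensor(wt.weights.copy(), wt.feature_names,
                               wt.model_name, 0.0)
        ablated.weights[:, ::2, :] = 0.0
        obs = exp.bold_val.data.T - exp.bold_val.data.T.mean(axis=0)
        pa = predict_series(wt, exp.design_val)
        pb = predict_series(ablated, exp.design_val)
        res = bootstrap_compare(pa, pb, obs, exp.bold_val.run_index,
                                n_boot=n_boot, seed=_seed(seed, 200 + s),
                                mask=exp.planted.tuned)
        hits += int(res.p < 0.05 and res.mean_proportion > 0.5)
    rng = np.random.default_rng(_seed(seed, 7))
    run_index = np.repeat(np.arange(6), 50)
    rejects = 0
    for i in range(n_null):
        obs = rng.standard_normal((300, 60))
        pa = rng.standard_normal((300, 60))
        pb = rng.standard_normal((300, 60))
        res = bootstrap_compare(pa, pb, obs, run_index, n_boot=n_boot,
                                seed=_seed(seed, 300 + i))
        rejects += int(res.p < 0.05)
    return {"power": hits / n_power, "type1": rejects / n_null}
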