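"""Significance of voxel-wise prediction and bootstrap model comparison.

Permutation tests shuffle validation image identities (not time points),
preserving the event grid and the autocorrelation of the regressor
structure; BH-FDR corrects across voxels; pairs of models are compared by
bootstrap-resampling the validation runs and counting the proportion of
voxels better predicted by one model than the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .feature_space import FeatureSpace, FIRSpec
from .encoding import WeightTensor, pearson_by_column

__all__ = [
    "permutation_test",
    "fdr_bh",
    "bootstrap_compare",
    "ComparisonResult",
]


def _onset_matrices(events: pd.DataFrame, image_ids: list,
                    run_lengths, spec: FIRSpec):
    """Per-FIR-bin (volumes x images) onset matrices for the validation
    events, concatenated across runs."""
    idx = {img: i for i, img in enumerate(image_ids)}
    runs = sorted(run_lengths)
    blocks = []
    for run in runs:
        n = int(run_lengths[run])
        O = np.zeros((n, len(image_ids)))
        sub = events[(events["run"] == run) & (~events["is_null"].astype(bool))]
        for _, ev in sub.iterrows():
            v = int(ev["onset_volume"])
            if v < n:
                O[v, idx[ev["image_id"]]] += 1.0
        blocks.append(O)
    O = np.vstack(blocks)
    out = []
    for b in range(1, spec.delay_bins + 1):
        Ob = np.zeros_like(O)
        Ob[b:] = O[:-b]
        out.append(Ob)
    return out


def permutation_test(wt: WeightTensor, events: pd.DataFrame,
                     labels, space: FeatureSpace, obs: np.ndarray,
                     run_lengths, n_perm: int = 5000, seed=0,
                     spec: FIRSpec | None = None):
    """One-tailed permutation p per voxel for validation prediction accuracy.

    Validation image identities are shuffled without replacement; the
    shuffled feature regressors are FIR-convolved on the fixed event grid,
    multiplied by the estimation weights, and correlated with the observed
    series, 5000 times by default.  p = (1 + #{null r >= observed r}) /
    (1 + n_perm).  Zero-weight (degenerate) voxels get p = NaN.

    Returns ``(p, observed_r, null_r)`` with ``null_r`` of shape
    (n_perm, n_voxels).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    spec = spec or FIRSpec()
    rng = np.random.default_rng(seed)
    image_ids = sorted({ev for ev in events.loc[~events["is_null"].astype(bool),
                                                "image_id"]})
    F = np.array([space.encode(labels[i]) for i in image_ids])
    O_bins = _onset_matrices(events, image_ids, run_lengths, spec)
    # M_b = F @ W_b^T : (images x voxels); prediction = sum_b O_b @ M_b[perm]
    M_bins = [F @ wt.weights[:, :, b].T for b in range(wt.n_bins)]
    obs_c = obs - obs.mean(axis=0)
    obs_ss = np.sqrt((obs_c ** 2).sum(axis=0))

    def corr(pred):
        pc = pred - pred.mean(axis=0)
        den = np.sqrt((pc ** 2).sum(axis=0)) * obs_ss
        with np.errstate(invalid="ignore", divide="ignore"):
            return (pc * obs_c).sum(axis=0) / den

    base = sum(O @ M for O, M in zip(O_bins, M_bins))
    observed_r = corr(base)
    null_r = np.empty((n_perm, obs.shape[1]))
    n_img = len(image_ids)
    for k in range(n_perm):
        perm = rng.permutation(n_img)
        pred = sum(O @ M[perm] for O, M in zip(O_bins, M_bins))
        null_r[k] = corr(pred)
    exceed = (null_r >= observed_r).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    degenerate = ~np.isfinite(observed_r)
    p = np.where(degenerate, np.nan, p)
    return p, observed_r, null_r


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR pass flags at level q.  NaN entries
    (degenerate voxels) never pass."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    ok = np.isfinite(p)
    flags = np.zeros(p.shape, dtype=bool)
    if ok.any():
        flags[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return flags


@dataclass
class ComparisonResult:
    """Bootstrap model comparison: per-draw proportion of voxels better
    predicted by model A, z = (mean - 0.5) / SE over draws, two-tailed p."""

    proportions: np.ndarray
    z: float
    p: float

    @property
    def mean_proportion(self) -> float:
        return float(self.proportions.mean())


def bootstrap_compare(pred_a: np.ndarray, pred_b: np.ndarray,
                      obs: np.ndarray, run_index: np.ndarray,
                      n_boot: int = 1000, seed=0,
                      mask: np.ndarray | None = None) -> ComparisonResult:
    """Compare two models' voxel-wise validation accuracy by resampling
    validation runs with replacement.

    Per draw, runs are resampled, per-voxel r recomputed on the concatenated
    resampled series for both models, and the proportion of masked voxels
    with r_A > r_B recorded (ties count 0.5).  z is the mean proportion
    minus 0.5 over its bootstrap SE; p is two-tailed normal.
    """
    if mask is not None:
        if not mask.any():
            raise ValueError("empty voxel mask")
        pred_a = pred_a[:, mask]
        pred_b = pred_b[:, mask]
        obs = obs[:, mask]
    rng = np.random.default_rng(seed)
    runs = sorted(np.unique(run_index).tolist())
    segs = {r: run_index == r for r in runs}
    props = np.empty(n_boot)
    for i in range(n_boot):
        draw = rng.choice(len(runs), size=len(runs), replace=True)
        rows = np.concatenate([np.flatnonzero(segs[runs[j]]) for j in draw])
        ra = pearson_by_column(pred_a[rows], obs[rows])
        rb = pearson_by_column(pred_b[rows], obs[rows])
        better = np.where(np.isnan(ra) | np.isnan(rb), 0.5,
                          np.where(ra > rb, 1.0,
                                   np.where(ra < rb, 0.0, 0.5)))
        props[i] = better.mean()
    # the bootstrap SD of the proportion IS the standard error of the
    # observed proportion estimate
    se = props.std(ddof=1)
    mean_excess = props.mean() - 0.5
    if se == 0:
        z = 0.0 if mean_excess == 0 else np.sign(mean_excess) * np.inf
    else:
        z = mean_excess / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ComparisonResult(props, float(z), p)
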