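"""Non-centered PCA of voxel tuning weights and its inference machinery.

The tuning of a voxel is its vector of feature weights (peak-HRF FIR bins
averaged).  Non-centered PCA across voxels - an SVD of the raw weight
matrix, preserving the mean tuning direction - finds feature dimensions
along which voxels co-vary.  Components are tested against the covariance
structure of the stimulus features themselves via a jackknife over
leave-one-run-out model fits; consistency across subjects is assessed by
leave-one-subject-out matching of loadings; and retained components are
interpreted by correlating their loadings with hand-built theoretical
dimensions (animacy scale, humanness, animate/inanimate valence and
arousal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feature_space import FeatureSpace
from .encoding import WeightTensor

__all__ = [
    "PCDecomposition",
    "peak_weights",
    "noncentered_pca",
    "stimulus_pca",
    "jackknife_pc_test",
    "match_pcs",
    "loocv_consistency",
    "build_theoretical_dimensions",
    "dim_pc_correlation",
    "JACKKNIFE_MIN_P",
]

#: Smallest reportable p for the jackknife component test.
JACKKNIFE_MIN_P = 0.03

#: FIR bins averaged as the HRF peak (4-6 s and 6-8 s; 0-based bins 1 and 2).
PEAK_BINS = (1, 2)


@dataclass
class PCDecomposition:
    """loadings: feature x component (orthonormal columns); scores: voxel (or
    image) x component; variance_fraction: squared singular values over the
    matrix's total sum of squares."""

    loadings: np.ndarray
    scores: np.ndarray
    variance_fraction: np.ndarray
    singular_values: np.ndarray
    feature_names: list | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def peak_weights(wt: WeightTensor, space: FeatureSpace | None = None,
                 drop_categories: tuple = ("Plants", "Vehicles")) -> tuple:
    """Average the two peak-HRF FIR bins per feature, dropping features of
    rarely-viewed categories when present.

    Returns ``(matrix, feature_names)`` with matrix voxel x feature.
    """
    if wt.n_bins < max(PEAK_BINS) + 1:
        raise ValueError("weight tensor lacks the peak FIR bins")
    M = wt.weights[:, :, list(PEAK_BINS)].mean(axis=2)
    names = list(wt.feature_names)
    if space is not None and drop_categories:
        keep = [i for i, f in enumerate(space.features)
                if f.category not in drop_categories]
        M = M[:, keep]
        names = [names[i] for i in keep]
    return M, names


def noncentered_pca(M: np.ndarray, k: int | None = None,
                    feature_names=None) -> PCDecomposition:
    """Non-centered PCA: SVD of the raw matrix without column centering.

    Loadings are the right singular vectors (sign-fixed so each component's
    largest-magnitude loading is positive); scores are the projections of
    the rows; variance fractions are squared singular values over the total
    sum of squares.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite weight matrix")
    total_ss = float((M ** 2).sum())
    if total_ss == 0:
        raise ValueError("all-zero matrix")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if k is not None:
        U, s, Vt = U[:, :k], s[:k], Vt[:k]
    loadings = Vt.T
    # sign convention: largest-|.| entry of each loading positive
    signs = np.sign(loadings[np.abs(loadings).argmax(axis=0),
                             np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    scores = M @ loadings
    varfrac = s ** 2 / total_ss
    return PCDecomposition(loadings, scores, varfrac, s,
                           list(feature_names) if feature_names is not None
                           else None)


def stimulus_pca(feature_matrices, k: int | None = None,
                 feature_names=None) -> PCDecomposition:
    """Non-centered PCA of stimulus features: the image x feature encoding
    matrices (one per subject) are stacked vertically and decomposed, giving
    the covariance structure of the stimuli themselves."""
    mats = [np.asarray(m, dtype=float) for m in feature_matrices]
    ncol = {m.shape[1] for m in mats}
    if len(ncol) != 1:
        raise ValueError("feature-matrix column counts differ")
    return noncentered_pca(np.vstack(mats), k, feature_names)


def explained_by_direction(M: np.ndarray, u: np.ndarray) -> float:
    """Fraction of the matrix's total sum of squares captured by projecting
    rows onto the unit vector ``u``."""
    u = np.asarray(u, dtype=float)
    u = u / np.linalg.norm(u)
    return float(((M @ u) ** 2).sum() / (M ** 2).sum())


def jackknife_pc_test(loo_weight_mats, stim_loadings: np.ndarray,
                      max_k: int = 10, alpha: float = 0.05,
                      min_p: float = JACKKNIFE_MIN_P):
    """Jackknife test of tuning-PCA components against stimulus structure.

    ``loo_weight_mats`` holds one voxel x feature peak-weight matrix per
    leave-one-run-out model fit.  For each component k and each replicate,
    the variance fraction captured by the replicate's k-th weight PC is
    compared with the fraction of the same matrix's sum of squares captured
    by the k-th stimulus-feature PC loading; the jackknife SE of the
    difference gives a one-tailed t test (n - 1 df, p floored at ``min_p``).
    Testing stops at the first non-significant component.

    Returns ``(retained, pvals)``; ``pvals`` has one entry per tested
    component.
    """
    mats = [np.asarray(m, dtype=float) for m in loo_weight_mats]
    n = len(mats)
    if n < 3:
        raise ValueError("need at least 3 jackknife replicates")
    max_k = min(max_k, stim_loadings.shape[1])
    # per replicate: weight-PC variance fractions and stimulus-PC captures
    vfrac = np.empty((n, max_k))
    sfrac = np.empty((n, max_k))
    for j, M in enumerate(mats):
        dec = noncentered_pca(M, k=max_k)
        vfrac[j, : dec.n_components] = dec.variance_fraction[:max_k]
        if dec.n_components < max_k:
            vfrac[j, dec.n_components:] = 0.0
        for k in range(max_k):
            sfrac[j, k] = explained_by_direction(M, stim_loadings[:, k])
    diffs = vfrac - sfrac
    pvals = []
    retained = 0
    for k in range(max_k):
        d = diffs[:, k]
        dbar = d.mean()
        se = np.sqrt((n - 1) / n * ((d - dbar) ** 2).sum())
        t = np.inf if se == 0 and dbar > 0 else (0.0 if se == 0 else dbar / se)
        p = float(stats.t.sf(t, n - 1))
        p = max(p, min_p)
        pvals.append(p)
        if p > alpha:
            break
        retained += 1
    return retained, np.array(pvals)


def match_pcs(subject_loadings: np.ndarray, group_loadings: np.ndarray):
    """Match each subject PC to the group PC it correlates best with (in
    absolute value), resolving conflicts recursively in favor of the
    subject PC whose ordering is closest to the group PC's.

    Returns ``(assignment, correlations)``: ``assignment[i]`` is the group
    PC index matched to subject PC i, and ``correlations[i]`` the signed
    Pearson correlation of that pair.
    """
    S = np.asarray(subject_loadings, dtype=float)
    G = np.asarray(group_loadings, dtype=float)
    k = S.shape[1]
    C = np.corrcoef(S.T, G.T)[:k, k:]
    assignment = np.full(k, -1, dtype=int)
    unassigned = set(range(k))
    available = set(range(k))
    while unassigned:
        # each unassigned subject PC's best available group PC
        best = {i: max(available, key=lambda g: abs(C[i, g]))
                for i in unassigned}
        claimed: dict[int, list] = {}
        for i, g in best.items():
            claimed.setdefault(g, []).append(i)
        for g, claimants in claimed.items():
            # ordering-closest subject PC keeps the contested group PC
            winner = min(claimants, key=lambda i: (abs(i - g), i))
            assignment[winner] = g
            unassigned.discard(winner)
            available.discard(g)
    corrs = np.array([C[i, assignment[i]] for i in range(k)])
    return assignment, corrs


def loocv_consistency(subject_weight_mats, k: int = 3, n_perm: int = 10_000,
                      seed=0) -> pd.DataFrame:
    """Leave-one-subject-out consistency of tuning-PC loadings.

    For each subject, the top-k PCs of their own weight matrix are matched
    to the top-k PCs of a group PCA on the concatenated matrices of the
    remaining subjects; matched loading correlations (across features) are
    tested by permuting the left-out group's loading entries (p floored at
    1/(n_perm + 1)) and by the parametric t approximation.
    """
    mats = [np.asarray(m, dtype=float) for m in subject_weight_mats]
    if len(mats) < 3:
        raise ValueError("need at least 3 subjects")
    rng = np.random.default_rng(seed)
    n_feat = mats[0].shape[1]
    rows = []
    for si, own in enumerate(mats):
        others = np.vstack([m for j, m in enumerate(mats) if j != si])
        own_pcs = noncentered_pca(own, k=k)
        loo_pcs = noncentered_pca(others, k=k)
        assignment, corrs = match_pcs(own_pcs.loadings, loo_pcs.loadings)
        for i in range(k):
            g = assignment[i]
            r_obs = corrs[i]
            a = own_pcs.loadings[:, i]
            b = loo_pcs.loadings[:, g]
            null = np.empty(n_perm)
            for p_ in range(n_perm):
                null[p_] = _pearson(a, b[rng.permutation(n_feat)])
            p_perm = (1.0 + (null >= r_obs).sum()) / (1.0 + n_perm)
            t = r_obs * np.sqrt((n_feat - 2) / max(1e-300, 1 - r_obs ** 2))
            p_t = float(stats.t.sf(t, n_feat - 2))
            rows.append({"subject": si, "subject_pc": i + 1,
                         "group_pc": g + 1, "r": float(r_obs),
                         "p_perm": float(p_perm), "p_t": p_t})
    return pd.DataFrame(rows)


def _pearson(a, b) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    return float((a * b).sum() / den) if den > 0 else np.nan


# ---------------------------------------------------------------------------
# theoretical dimensions


def build_theoretical_dimensions(space: FeatureSpace) -> dict:
    """The seven hand-built feature-length hypothesis vectors.

    * ``animacy_scale``   - 0 (inanimate) .. 3 (human) per feature.
    * ``animacy_binary``  - animate 1 / inanimate 0.
    * ``human_presence``  - human 1 / non-human 0.
    * ``valence_animate`` / ``valence_inanimate`` - the -1/0/+1 valence of
      features in the covered partition; features of the other partition
      carry the covered partition's mean (excluding their influence on the
      correlation).
    * ``arousal_animate`` / ``arousal_inanimate`` - likewise with 0/1
      arousal codes.

    SE features contribute through their stored modal valence / arousal.
    """
    feats = space.features
    for f in feats:
        if f.kind == "se" and (f.valence is None or f.arousal is None):
            raise ValueError(f"SE feature {f.name!r} lacks affect metadata")
    animate = np.array([bool(f.animate) for f in feats])
    dims = {
        "animacy_scale": np.array([float(f.animacy or 0) for f in feats]),
        "animacy_binary": animate.astype(float),
        "human_presence": np.array([float(bool(f.human)) for f in feats]),
    }
    valence = np.array([float(f.valence if f.valence is not None else 0)
                        for f in feats])
    arousal = np.array([float(f.arousal if f.arousal is not None else 0)
                        for f in feats])
    for code, values in (("valence", valence), ("arousal", arousal)):
        for part, mask in (("animate", animate), ("inanimate", ~animate)):
            vec = np.empty(len(feats))
            vec[mask] = values[mask]
            vec[~mask] = values[mask].mean()
            dims[f"{code}_{part}"] = vec
    return dims


def dim_pc_correlation(dims: dict, loadings: np.ndarray,
                       n_boot: int = 5000, seed=0,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Correlate theoretical dimensions with PC loadings across features,
    with feature-resampling bootstrap sd, 95% CI and one-tailed p."""
    rng = np.random.default_rng(seed)
    n_feat = loadings.shape[0]
    boot_idx = rng.integers(0, n_feat, size=(n_boot, n_feat))
    rows = []
    for name, vec in dims.items():
        vec = np.asarray(vec, dtype=float)
        if np.std(vec) == 0:
            raise ValueError(f"constant theoretical dimension {name!r}")
        for pc in range(loadings.shape[1]):
            u = loadings[:, pc]
            r = _pearson(vec, u)
            boot = np.array([_pearson(vec[ix], u[ix]) for ix in boot_idx])
            boot = boot[np.isfinite(boot)]
            lo, hi = np.percentile(boot, [2.5, 97.5])
            if r >= 0:
                wrong = (boot <= 0).sum()
            else:
                wrong = (boot >= 0).sum()
            p = (1.0 + wrong) / (1.0 + len(boot))
            rows.append({"dimension": name, "pc": pc + 1, "r": r,
                         "sd": float(boot.std(ddof=1)),
                         "ci_lo": float(lo), "ci_hi": float(hi),
                         "p": float(p), "significant": p <= alpha})
    return pd.DataFrame(rows)
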