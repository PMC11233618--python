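"""Behavioral-affordance aggregation and prediction from tuning-space scores.

Raters viewing each image select the behaviors (from a 25-item taxonomy:
approach, avoidance and passive responses) appropriate to its content.  The
per-image selection proportions are predicted, image-held-out, from the
image's projections onto tuning-PCA (or stimulus-PCA) loadings; out-of-sample
R-squared is pooled over behaviors and scaled by the explainable variance
ceiling set by inter-rater consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_space import FeatureSpace

__all__ = [
    "BEHAVIOR_TAXONOMY",
    "DEFAULT_BEHAVIOR_PARTITION",
    "BehaviorTable",
    "aggregate_responses",
    "project_images",
    "loocv_predict",
    "explainable_variance",
    "bootstrap_ci",
    "filter_behaviors",
]

#: The 25 candidate behavioral responses shown to raters.
BEHAVIOR_TAXONOMY = [
    "Bond with",
    "Take Care of Young with",
    "Nurture/Raise",
    "Procreate with",
    "Be Affectionate with",
    "Have Sex with",
    "Play with",
    "Gain Social Support from",
    "Gain Nutrition from",
    "Gain Gustatory Satisfaction from",
    "Relieve Thirst with",
    "Use to Facilitate Activity",
    "Take Shelter in",
    "Warm Oneself with",
    "Empathic Response to Suffering",
    "Empathic Response to Joy",
    "Prolong Looking at",
    "Curtail Looking at",
    "Retreat from",
    "Defend Self from Aggressor",
    "Defend Self from Unwanted Sexual Attention",
    "Avoid Predation by Fleeing",
    "Avoid Predation by Freezing",
    "Avoid Disease by Not Touching",
    "Avoid Toxins by Not Consuming",
]

#: Default approach / avoidance / passive partition (configurable; the
#: passive set is the three responses requiring no explicit action, the
#: avoidance set the seven defend/avoid/retreat responses).
DEFAULT_BEHAVIOR_PARTITION = {
    "avoidance": [
        "Retreat from",
        "Defend Self from Aggressor",
        "Defend Self from Unwanted Sexual Attention",
        "Avoid Predation by Fleeing",
        "Avoid Predation by Freezing",
        "Avoid Disease by Not Touching",
        "Avoid Toxins by Not Consuming",
    ],
    "passive": [
        "Gain Social Support from",
        "Empathic Response to Suffering",
        "Empathic Response to Joy",
    ],
}
DEFAULT_BEHAVIOR_PARTITION["approach"] = [
    b for b in BEHAVIOR_TAXONOMY
    if b not in DEFAULT_BEHAVIOR_PARTITION["avoidance"]
    and b not in DEFAULT_BEHAVIOR_PARTITION["passive"]
]


@dataclass
class BehaviorTable:
    """Image x behavior selection-proportion matrix plus bookkeeping."""

    proportions: pd.DataFrame  # index: image_id, columns: behaviors
    counts: pd.Series  # total selections per behavior (pre-filter)
    retained: list = field(default_factory=list)
    n_responses: int = 0

    @property
    def image_ids(self) -> list:
        return list(self.proportions.index)


def aggregate_responses(raw: pd.DataFrame,
                        taxonomy=BEHAVIOR_TAXONOMY,
                        min_fraction: float = 0.01) -> BehaviorTable:
    """Aggregate worker-level selections into per-image proportions.

    ``raw`` has one row per selection with columns ``worker_id``,
    ``image_id``, ``behavior``.  A row with an empty behavior records a
    rater who selected nothing (counted in the denominator only).  The
    proportion is selections over distinct raters for that image.
    Behaviors with fewer than ``min_fraction`` of all responses (strict <)
    are dropped from the retained set.
    """
    raw = raw.assign(behavior=raw["behavior"].fillna(""))
    picks = raw[raw["behavior"] != ""]
    unknown = set(picks["behavior"]) - set(taxonomy)
    if unknown:
        raise ValueError(f"unknown behavior tokens: {sorted(unknown)}")
    n_total = len(picks)
    counts = picks["behavior"].value_counts().reindex(taxonomy, fill_value=0)
    raters = raw.groupby("image_id")["worker_id"].nunique()
    sel = (picks.groupby(["image_id", "behavior"]).size()
           .unstack(fill_value=0)
           .reindex(columns=taxonomy, fill_value=0)
           .reindex(index=raters.index, fill_value=0))
    props = sel.div(raters, axis=0)
    retained = [b for b in taxonomy if counts[b] >= min_fraction * n_total]
    return BehaviorTable(props[retained], counts, retained, n_total)


def project_images(space: FeatureSpace, labels, decomposition,
                   n_pcs: int | None = None) -> pd.DataFrame:
    """Image x component score matrix: inner product of each image's feature
    vector with each PC loading vector.  ``labels`` maps image_id ->
    :class:`ImageLabel` (affective codes should be across-subject modes)."""
    loadings = decomposition.loadings
    if n_pcs is not None:
        if n_pcs > loadings.shape[1]:
            raise ValueError("n_pcs exceeds available components")
        loadings = loadings[:, :n_pcs]
    ids = sorted(i for i, lab in labels.items() if not lab.excluded)
    F = np.array([space.encode(labels[i]) for i in ids])
    if F.shape[1] != loadings.shape[0]:
        raise ValueError("feature ordering mismatch between space and loadings")
    scores = F @ loadings
    cols = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return pd.DataFrame(scores, index=ids, columns=cols)


def _press_r2(X: np.ndarray, Y: np.ndarray) -> tuple[float, float]:
    """Pooled leave-one-out (PRESS) residual and total sums of squares for
    OLS of every column of Y on X (with intercept)."""
    n = X.shape[0]
    Xi = np.column_stack([np.ones(n), X])
    # hat diagonal via the economy QR; guards h ~ 1
    Q, _ = np.linalg.qr(Xi)
    h = np.minimum((Q ** 2).sum(axis=1), 1.0 - 1e-12)
    beta, *_ = np.linalg.lstsq(Xi, Y, rcond=None)
    resid = Y - Xi @ beta
    loo = resid / (1.0 - h)[:, None]
    ss_press = float((loo ** 2).sum())
    ss_tot = float(((Y - Y.mean(axis=0)) ** 2).sum())
    return ss_press, ss_tot


def loocv_predict(table: BehaviorTable, scores: pd.DataFrame,
                  n_pcs_list=None, explainable: float = 1.0) -> pd.DataFrame:
    """Image-held-out prediction of behavior proportions from PC scores.

    For each component count, every image is left out in turn; OLS on the
    remaining images' first n PC scores predicts its selection proportion
    for each behavior.  Out-of-sample R-squared is pooled across behaviors
    (summed squared errors over summed total variance) and scaled by the
    explainable-variance ceiling; values are percentages.
    """
    common = [i for i in table.image_ids if i in scores.index]
    Y = table.proportions.loc[common].to_numpy(dtype=float)
    S = scores.loc[common].to_numpy(dtype=float)
    max_pcs = S.shape[1]
    if n_pcs_list is None:
        n_pcs_list = range(1, max_pcs + 1)
    rows = []
    for n in n_pcs_list:
        if n > max_pcs:
            raise ValueError(f"n_pcs={n} exceeds available components")
        if n == 0:
            X = np.empty((len(common), 0))
        else:
            X = S[:, :n]
        ss_press, ss_tot = _press_r2(X, Y)
        r2 = 1.0 - ss_press / ss_tot
        rows.append({"n_pcs": int(n), "r2": 100.0 * r2,
                     "scaled_r2": 100.0 * r2 / explainable})
    return pd.DataFrame(rows)


def explainable_variance(raw: pd.DataFrame, behaviors=None,
                         n_splits: int = 100, seed=0) -> float:
    """Split-half inter-rater consistency ceiling on predictable variance.

    Raters of each image are split at random into halves; the two half-sets'
    proportion matrices are correlated over all image x behavior cells and
    Spearman-Brown corrected to the full rater count; the estimate is the
    average over ``n_splits`` random splits.
    """
    rng = np.random.default_rng(seed)
    raw = raw.assign(behavior=raw["behavior"].fillna(""))
    workers = raw.groupby("image_id")["worker_id"].unique()
    if (workers.map(len) < 2).any():
        raise ValueError("every image needs at least 2 raters")
    if behaviors is None:
        behaviors = sorted(raw["behavior"].unique())
    b_idx = {b: j for j, b in enumerate(behaviors)}
    images = list(workers.index)
    i_idx = {im: i for i, im in enumerate(images)}
    # per (image, worker): selection vector over behaviors
    sel: dict = {}
    for (im, w), grp in raw.groupby(["image_id", "worker_id"]):
        v = np.zeros(len(behaviors))
        for b in grp["behavior"]:
            if b in b_idx:
                v[b_idx[b]] = 1.0
        sel[(im, w)] = v
    rs = []
    for _ in range(n_splits):
        A = np.zeros((len(images), len(behaviors)))
        B = np.zeros_like(A)
        for im in images:
            ws = list(workers[im])
            rng.shuffle(ws)
            half = len(ws) // 2
            ga, gb = ws[:half], ws[half:]
            A[i_idx[im]] = np.mean(
                [sel.get((im, w), 0.0) for w in ga], axis=0)
            B[i_idx[im]] = np.mean(
                [sel.get((im, w), 0.0) for w in gb], axis=0)
        # center per behavior so the consistency matches the pooled,
        # per-behavior-centered R-squared definition
        a = (A - A.mean(axis=0)).ravel()
        b = (B - B.mean(axis=0)).ravel()
        den = np.sqrt((a ** 2).sum() * (b ** 2).sum())
        if den == 0:
            continue
        r_half = float((a * b).sum() / den)
        rs.append(2.0 * r_half / (1.0 + r_half))
    ev = float(np.mean(rs)) if rs else 0.0
    return min(max(ev, 1e-12), 1.0)


def bootstrap_ci(table: BehaviorTable, scores: pd.DataFrame,
                 n_pcs_list, explainable: float = 1.0,
                 n_boot: int = 1000, seed=0,
                 ci: tuple = (2.5, 97.5)) -> pd.DataFrame:
    """Percentile bootstrap CI of the scaled LOOCV R-squared curve, drawn by
    resampling images with replacement (used for one-tailed model-vs-model
    comparisons)."""
    common = [i for i in table.image_ids if i in scores.index]
    if len(common) < 50:
        raise ValueError("need at least 50 images for a stable bootstrap")
    Y = table.proportions.loc[common].to_numpy(dtype=float)
    S = scores.loc[common].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n_img = len(common)
    curves = {int(n): [] for n in n_pcs_list}
    for _ in range(n_boot):
        ix = rng.integers(0, n_img, size=n_img)
        Yb, Sb = Y[ix], S[ix]
        for n in n_pcs_list:
            ss_press, ss_tot = _press_r2(Sb[:, :n], Yb)
            if ss_tot == 0:
                continue
            curves[int(n)].append(100.0 * (1 - ss_press / ss_tot) / explainable)
    rows = []
    for n in n_pcs_list:
        vals = np.array(curves[int(n)])
        lo, hi = np.percentile(vals, list(ci))
        rows.append({"n_pcs": int(n), "ci_lo": float(lo), "ci_hi": float(hi),
                     "mean": float(vals.mean())})
    return pd.DataFrame(rows)


def filter_behaviors(table: BehaviorTable, subset: str,
                     partition=None) -> BehaviorTable:
    """Restrict the behavior columns to a configured subset: ``approach``,
    ``avoidance``, or ``exclude_passive`` (drops the passive set)."""
    partition = partition or DEFAULT_BEHAVIOR_PARTITION
    if subset == "exclude_passive":
        keep = [b for b in table.retained if b not in partition["passive"]]
    elif subset in partition:
        keep = [b for b in table.retained if b in partition[subset]]
    else:
        raise ValueError(f"unknown behavior subset {subset!r}")
    if not keep:
        raise ValueError(f"behavior subset {subset!r} is empty")
    return BehaviorTable(table.proportions[keep], table.counts, keep,
                         table.n_responses)
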