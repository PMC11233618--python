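"""Ridge estimation of voxel-wise encoding models and validation scoring.

Feature weights map FIR-expanded stimulus regressors onto each voxel's BOLD
series.  A single L2 penalty (lambda) is shared across voxels - selected by
run-blocked cross-validation over a 10-value log grid spanning 1e-9..1e5 -
so weights stay on a common scale for the downstream tuning-space PCA.
Prediction accuracy is the Pearson correlation between predicted and
observed held-out validation series, convertible to t and z statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .feature_space import DesignMatrix

__all__ = [
    "default_lambda_grid",
    "WeightTensor",
    "ridge_fit",
    "select_lambda",
    "predict_series",
    "accuracy",
    "pearson_by_column",
    "r_to_z",
    "gabor_control_residualize",
]


def default_lambda_grid(n: int = 10, low: float = -9.0,
                        high: float = 5.0) -> np.ndarray:
    """The 10-value log-spaced ridge-penalty grid, 1e-9 .. 1e5."""
    return np.logspace(low, high, n)


@dataclass
class WeightTensor:
    """voxel x feature x FIR-bin ridge coefficients for one model.

    Nuisance-column coefficients are fitted during estimation but kept
    outside the feature tensor (they are never used for validation
    prediction or PCA).
    """

    weights: np.ndarray  # (n_voxels, n_features, n_bins)
    feature_names: list
    model_name: str = ""
    lambda_: float = 0.0
    nuisance_weights: np.ndarray | None = None  # (n_nuisance, n_voxels)
    nuisance_names: list = field(default_factory=list)

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]

    @property
    def n_bins(self) -> int:
        return self.weights.shape[2]

    def flat(self) -> np.ndarray:
        """(n_features * n_bins, n_voxels) column-stacked weights matching
        design-matrix feature-column ordering."""
        return self.weights.reshape(self.n_voxels, -1).T


def _ridge_beta_svd(U, s, Vt, UtY, lam: float) -> np.ndarray:
    shrink = s / (s ** 2 + lam)
    return (Vt.T * shrink) @ UtY


def ridge_beta(X: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Ridge coefficients minimizing ||Y - X b||^2 + lam ||b||^2 per column
    of Y, via the SVD of X (stable for the near-zero grid penalties)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in ridge inputs")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    return _ridge_beta_svd(U, s, Vt, U.T @ Y, lam)


def ridge_fit(design: DesignMatrix, Y: np.ndarray, lam: float,
              model_name: str = "") -> WeightTensor:
    """Fit the ridge encoding model on a full design (feature + nuisance
    columns).  ``Y`` is volumes x voxels."""
    if design.values.shape[0] != Y.shape[0]:
        raise ValueError("design rows must match BOLD volumes")
    beta = ridge_beta(design.values, Y, lam)
    nf = design.n_feature_cols
    n_vox = Y.shape[1]
    W = beta[:nf].T.reshape(n_vox, len(design.feature_names), design.n_bins)
    nuis = beta[nf:] if beta.shape[0] > nf else None
    return WeightTensor(W, list(design.feature_names), model_name, lam,
                        nuis, list(design.nuisance_names))


def _fold_runs(run_index: np.ndarray, n_folds: int) -> list[np.ndarray]:
    """Partition the sorted unique run ids into ``n_folds`` contiguous
    groups (run-ordering invariant)."""
    runs = np.array(sorted(np.unique(run_index).tolist()))
    if len(runs) < n_folds:
        n_folds = len(runs)
    return [g for g in np.array_split(runs, n_folds) if len(g)]


def select_lambda(design: DesignMatrix, Y: np.ndarray,
                  grid: np.ndarray | None = None, n_folds: int = 10):
    """Select the single shared ridge penalty by run-blocked K-fold CV.

    For each grid value, each fold's model is fit on the remaining runs and
    predicts the held-out runs; the 10 held-out predicted segments are
    concatenated into a full-series prediction, correlated per voxel with
    the observed series, and the lambda maximizing the mean correlation
    across voxels wins.  Returns ``(best_lambda, mean_r_per_lambda)``.
    """
    if grid is None:
        grid = default_lambda_grid()
    grid = np.asarray(grid, dtype=float)
    X = design.values
    folds = _fold_runs(design.run_index, n_folds)
    if len(folds) < 2:
        raise ValueError("need at least 2 folds of runs")
    preds = np.zeros((len(grid),) + Y.shape)
    for fold in folds:
        te = np.isin(design.run_index, fold)
        tr = ~te
        U, s, Vt = np.linalg.svd(X[tr], full_matrices=False)
        UtY = U.T @ Y[tr]
        for gi, lam in enumerate(grid):
            beta = _ridge_beta_svd(U, s, Vt, UtY, lam)
            preds[gi][te] = X[te] @ beta
    mean_r = np.array([
        np.nanmean(pearson_by_column(preds[gi], Y)) for gi in range(len(grid))
    ])
    return float(grid[int(np.argmax(mean_r))]), mean_r


def fit_encoding_model(design: DesignMatrix, Y: np.ndarray,
                       grid: np.ndarray | None = None, n_folds: int = 10,
                       model_name: str = "") -> WeightTensor:
    """Cross-validated lambda selection followed by a refit on all runs."""
    lam, _ = select_lambda(design, Y, grid, n_folds)
    return ridge_fit(design, Y, lam, model_name)


def predict_series(wt: WeightTensor, design: DesignMatrix) -> np.ndarray:
    """Linear prediction (volumes x voxels) from the feature weights only;
    nuisance columns never contribute to validation predictions."""
    if list(design.feature_names) != list(wt.feature_names):
        raise ValueError("feature ordering mismatch between weights and design")
    if design.n_bins != wt.n_bins:
        raise ValueError("FIR bin count mismatch")
    return design.feature_values @ wt.flat()


def pearson_by_column(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation; NaN for constant columns."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    num = (Ac * Bc).sum(axis=0)
    den = np.sqrt((Ac ** 2).sum(axis=0) * (Bc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r


@dataclass
class PredictionAccuracy:
    """Per-voxel validation accuracy: Pearson r over the validation series,
    t and z per the r-to-t conversion, with constant-prediction voxels
    recorded as r = 0 and flagged (excluded from significance)."""

    r: np.ndarray
    t: np.ndarray
    z: np.ndarray
    n_volumes: int
    degenerate: np.ndarray  # constant-prediction flag
    p: np.ndarray | None = None  # permutation p, filled by inference
    fdr_pass: np.ndarray | None = None


def accuracy(pred: np.ndarray, obs: np.ndarray) -> PredictionAccuracy:
    """Score validation predictions against observed series per voxel."""
    if pred.shape != obs.shape:
        raise ValueError("prediction/observation shape mismatch")
    r = pearson_by_column(pred, obs)
    degenerate = ~np.isfinite(r)
    r = np.where(degenerate, 0.0, r)
    t, z = r_to_z(r, pred.shape[0])
    return PredictionAccuracy(r, t, z, pred.shape[0], degenerate)


def r_to_z(r, n: int):
    """Convert a prediction correlation to (t, z).

    t = r * sqrt((n - 2) / (1 - r^2)); z is the standard-normal quantile of
    the Student-t cumulative probability of t at n - 2 df (log-space, so
    extreme correlations keep precision).  |r| = 1 maps to +/- inf.
    """
    r = np.asarray(r, dtype=float)
    if n <= 2:
        raise ValueError("need n > 2")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
        t = np.where(np.abs(r) >= 1.0, np.sign(r) * np.inf, t)
    df = n - 2
    # evaluate on |t| and restore the sign: keeps precision in both tails
    with np.errstate(invalid="ignore"):
        z = -np.sign(t) * special.ndtri_exp(stats.t.logsf(np.abs(t), df))
    z = np.where(np.isinf(t), t, z)
    if np.ndim(r) == 0:
        return float(t), float(z)
    return t, z


def loo_run_weights(design: DesignMatrix, Y: np.ndarray, lam: float,
                    model_name: str = "") -> list[WeightTensor]:
    """Leave-one-run-out refits at a fixed penalty, one per estimation run.

    Uses per-run Gram-matrix accumulation, so each refit is a single solve
    of (X'X - X_r'X_r + lam I) b = (X'Y - X_r'Y_r) rather than a fresh
    decomposition; feeds the jackknife component test.
    """
    X = design.values
    runs = sorted(np.unique(design.run_index).tolist())
    G = X.T @ X
    H = X.T @ Y
    per_run = {}
    for r in runs:
        m = design.run_index == r
        per_run[r] = (X[m].T @ X[m], X[m].T @ Y[m])
    eye = lam * np.eye(G.shape[0])
    out = []
    nf = design.n_feature_cols
    for r in runs:
        Gr, Hr = per_run[r]
        beta = np.linalg.solve(G - Gr + eye, H - Hr)
        n_vox = Y.shape[1]
        W = beta[:nf].T.reshape(n_vox, len(design.feature_names),
                                design.n_bins)
        nuis = beta[nf:] if beta.shape[0] > nf else None
        out.append(WeightTensor(W, list(design.feature_names), model_name,
                                lam, nuis, list(design.nuisance_names)))
    return out


def gabor_control_residualize(bold_Y: np.ndarray, gabor_design: DesignMatrix,
                              n_folds: int = 10,
                              grid: np.ndarray | None = None,
                              lam: float | None = None) -> np.ndarray:
    """Remove out-of-sample variance explained by a low-level (Gabor) model.

    Per run-blocked fold, the Gabor model fit on the training folds predicts
    the held-out fold; the concatenated out-of-sample prediction is
    subtracted from the estimation BOLD (volumes x voxels).  The refit of a
    semantic/affective model on these residuals asks what it explains beyond
    low-level image structure.  ``lam`` fixes the ridge penalty; by default
    a single penalty is first selected on the full estimation set.
    """
    X = gabor_design.values
    if X.shape[0] != bold_Y.shape[0]:
        raise ValueError("design not aligned with BOLD")
    if lam is None:
        lam, _ = select_lambda(gabor_design, bold_Y, grid, n_folds)
    folds = _fold_runs(gabor_design.run_index, n_folds)
    if len(folds) < 2:
        raise ValueError("need at least 2 folds of runs")
    pred = np.zeros_like(bold_Y, dtype=float)
    for fold in folds:
        te = np.isin(gabor_design.run_index, fold)
        beta = ridge_beta(X[~te], bold_Y[~te], lam)
        pred[te] = X[te] @ beta
    return bold_Y - pred
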