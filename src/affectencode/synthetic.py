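"""Synthetic experiments with the statistical structure the analysis assumes.

Generates complete studies - labeled stimuli, run-structured event tables,
voxel tuning planted on a low-dimensional subspace of the feature space,
BOLD forward-modeled through the FIR design, and rater tables whose
selection probabilities derive from the planted dimensions - so every
analysis stage is testable without downloaded data.

The desk-scale defaults shrink the experiment (6 estimation runs of 21
images shown twice plus null trials every 8th slot, 2 validation runs of 9
images x 9 presentations in a Type-1 Index-1 sequence) while preserving its
structure; ``full_scale()`` mirrors the study's 30 estimation / 20
validation runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import behavior as bhv
from .feature_space import (
    FIRSpec,
    FeatureSpace,
    ImageLabel,
    build_design,
    build_feature_space,
    type1_index1_sequence,
)
from .encoding import WeightTensor, predict_series
from .preprocess import BoldRuns
from .tuning_pca import build_theoretical_dimensions

__all__ = [
    "SimConfig",
    "StimulusSet",
    "PlantedTuning",
    "Experiment",
    "gen_stimulus_set",
    "gen_tuning",
    "gen_bold",
    "gen_raters",
    "gen_experiment",
    "planted_loadings",
    "analytic_explainable_variance",
]

#: FIR-bin profile of the planted hemodynamic response (peaks at bins 2-3).
BIN_PROFILE = (0.5, 1.0, 1.0, 0.3)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic subject.

    Trial grid: trials last 2 TRs (1 s image + 3 s ISI at TR = 2 s); null
    trials occupy every 8th estimation slot, so ``images_per_est_run x
    est_reps`` must be divisible by 7.  SNR is the per-voxel ratio of signal
    variance to (white + AR) noise variance; drift rides on top and is the
    business of the detrending stage.
    """

    seed: int = 0
    # stimulus / run structure
    n_est_runs: int = 6
    images_per_est_run: int = 21
    est_reps: int = 2
    n_val_runs: int = 2
    val_images_per_run: int = 9
    trial_volumes: int = 2
    tail_volumes: int = 5
    null_every: int = 8
    tr_seconds: float = 2.0
    include_plants_vehicles: bool = False
    # label distributions
    p_valence: tuple = (0.3, 0.4, 0.3)  # negative, neutral, positive
    p_high_arousal: float = 0.5
    se_prob: float = 0.25
    # voxels and tuning
    n_voxels: int = 120
    frac_tuned: float = 0.8
    planted_strengths: tuple = (1.0, 0.7, 0.5)
    tuning_noise_sd: float = 0.05
    # noise model
    snr: float = 1.0
    ar_coef: float = 0.3
    ar_frac: float = 0.3  # fraction of noise variance that is AR(1)
    drift_amplitude: float = 1.0  # drift SD in units of noise SD
    drift_periods: tuple = (160.0, 288.0)  # seconds, beyond the SG window
    baseline: float = 100.0
    spike_prob: float = 0.0
    spike_amplitude: float = 50.0
    # raters
    n_raters: int = 9
    n_workers: int = 49
    n_behaviors: int = 25
    mean_selections: float = 2.0
    behavior_link: str = "logistic"  # or "linear"
    behavior_beta_scale: float = 1.2

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        if (self.images_per_est_run * self.est_reps) % (self.null_every - 1):
            raise ValueError(
                "stimulus trials per run must divide into blocks of "
                f"{self.null_every - 1} to place a null every "
                f"{self.null_every}th slot exactly")
        if abs(sum(self.p_valence) - 1.0) > 1e-9:
            raise ValueError("valence probabilities must sum to 1")


def full_scale(cfg: SimConfig | None = None) -> SimConfig:
    """The study-sized run structure (30 estimation / 20 validation runs)."""
    cfg = cfg or SimConfig()
    return replace(cfg, n_est_runs=30, images_per_est_run=49, n_val_runs=20)


@dataclass
class StimulusSet:
    space: FeatureSpace
    labels: dict  # image_id -> ImageLabel
    events_est: pd.DataFrame
    events_val: pd.DataFrame
    run_lengths_est: dict
    run_lengths_val: dict

    @property
    def est_image_ids(self):
        ev = self.events_est
        return sorted(set(ev.loc[~ev["is_null"].astype(bool), "image_id"]))

    @property
    def val_image_ids(self):
        ev = self.events_val
        return sorted(set(ev.loc[~ev["is_null"].astype(bool), "image_id"]))


@dataclass
class PlantedTuning:
    loadings: np.ndarray  # feature x 3, orthonormal
    scores: np.ndarray  # voxel x 3
    tuned: np.ndarray  # boolean voxel mask ("OTC" stand-in)


_SE_BY_CONTEXT = {
    ("human", -1): ["Mutilated humans",
                    "Threat toward viewer human aggressor",
                    "Threat away from viewer human aggressor"],
    ("human", 1): ["Romantic couples portrait", "Human babies",
                   "Erotica single human",
                   "Human social interaction gatherings"],
    ("human", 0): ["Human social interaction single human",
                   "Human social interaction portrait"],
    ("animal", -1): ["Mutilated animals",
                     "Threat toward viewer animal aggressor",
                     "Threat away from viewer animal aggressor"],
    ("animal", 1): ["Animal babies"],
    ("food", -1): ["Rotten food"],
}


def _draw_label(image_id: str, space: FeatureSpace, cfg: SimConfig,
                rng: np.random.Generator) -> ImageLabel:
    cats = sorted({f.category for f in space.features if f.category})
    cat = cats[rng.integers(len(cats))]
    valence = int(rng.choice((-1, 0, 1), p=cfg.p_valence))
    arousal = int(rng.random() < cfg.p_high_arousal)
    feats = {f.category: f for f in space.features if f.category}
    meta = feats[cat]
    if meta.human:
        group = "human"
    elif meta.animate:
        group = "animal"
    elif "Food" in cat:
        group = "food"
    else:
        group = "other"
    flags = ()
    candidates = _SE_BY_CONTEXT.get((group, valence), [])
    if candidates and rng.random() < cfg.se_prob:
        flags = (candidates[rng.integers(len(candidates))],)
    return ImageLabel(image_id, cat, valence, arousal, flags)


def gen_stimulus_set(cfg: SimConfig, rng=None) -> StimulusSet:
    """Labeled images plus estimation and validation event tables."""
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    space = build_feature_space("CSVA", cfg.include_plants_vehicles)
    labels: dict = {}

    def new_images(n, prefix):
        out = []
        for i in range(n):
            img = f"{prefix}{len(labels):05d}"
            labels[img] = _draw_label(img, space, cfg, rng)
            out.append(img)
        return out

    est_rows = []
    run_lengths_est = {}
    for r in range(cfg.n_est_runs):
        run = f"est{r:02d}"
        imgs = new_images(cfg.images_per_est_run, "img")
        stims = list(imgs) * cfg.est_reps
        rng.shuffle(stims)
        n_slots = len(stims) * cfg.null_every // (cfg.null_every - 1)
        si = 0
        for slot in range(n_slots):
            is_null = (slot + 1) % cfg.null_every == 0
            img = "" if is_null else stims[si]
            est_rows.append({"run": run,
                             "onset_volume": slot * cfg.trial_volumes,
                             "image_id": img,
                             "is_null": is_null})
            if not is_null:
                si += 1
        run_lengths_est[run] = n_slots * cfg.trial_volumes + cfg.tail_volumes

    val_rows = []
    run_lengths_val = {}
    m = cfg.val_images_per_run
    for r in range(cfg.n_val_runs):
        run = f"val{r:02d}"
        imgs = new_images(m, "img")
        seq = type1_index1_sequence(m, int(rng.integers(2 ** 31)))
        for slot, cond in enumerate(seq):
            val_rows.append({"run": run,
                             "onset_volume": slot * cfg.trial_volumes,
                             "image_id": imgs[int(cond)],
                             "is_null": False})
        run_lengths_val[run] = len(seq) * cfg.trial_volumes + cfg.tail_volumes

    space.set_se_affect_from_labels([labels])
    return StimulusSet(space, labels, pd.DataFrame(est_rows),
                       pd.DataFrame(val_rows), run_lengths_est,
                       run_lengths_val)


def planted_loadings(space: FeatureSpace) -> np.ndarray:
    """Three orthonormal feature-space dimensions mimicking animacy,
    animate valence and animate arousal (QR-orthonormalized theoretical
    dimensions, sign-fixed)."""
    dims = build_theoretical_dimensions(space)
    D = np.column_stack([dims["animacy_scale"],
                         dims["valence_animate"],
                         dims["arousal_animate"]])
    D = D - D.mean(axis=0)
    Q, R = np.linalg.qr(D)
    Q = Q * np.sign(np.diag(R))
    return Q


def gen_tuning(cfg: SimConfig, space: FeatureSpace,
               rng=None) -> tuple[WeightTensor, PlantedTuning]:
    """Voxel weights = planted-dimension scores x loadings + tuning noise,
    with an HRF-like FIR-bin profile peaking at bins 2-3.  A ``tuned``
    voxel subset (the anatomical-ROI stand-in) carries the structure;
    remaining voxels are pure tuning noise."""
    rng = np.random.default_rng(cfg.seed + 1 if rng is None else rng)
    L = planted_loadings(space)
    n_vox = cfg.n_voxels
    n_tuned = int(round(cfg.frac_tuned * n_vox))
    tuned = np.zeros(n_vox, dtype=bool)
    tuned[:n_tuned] = True
    scores = np.zeros((n_vox, L.shape[1]))
    scores[tuned] = rng.standard_normal((n_tuned, L.shape[1])) \
        * np.asarray(cfg.planted_strengths)
    peak = scores @ L.T
    # tuning noise only on tuned voxels: untuned voxels are true zeros, so
    # their forward signal is empty and validation r centers on 0
    peak[tuned] += cfg.tuning_noise_sd * rng.standard_normal(
        (n_tuned, peak.shape[1]))
    W = peak[:, :, None] * np.asarray(BIN_PROFILE)[None, None, :]
    wt = WeightTensor(W, list(space.feature_names), "CSVA-true", 0.0)
    return wt, PlantedTuning(L, scores, tuned)


def _ar1_noise(shape, coef, rng):
    w = rng.standard_normal(shape)
    x = lfilter([1.0], [1.0, -coef], w, axis=-1)
    return x * np.sqrt(1.0 - coef ** 2)  # unit stationary variance


def gen_bold(design, wt_true: WeightTensor, cfg: SimConfig, rng=None,
             run_index=None) -> BoldRuns:
    """Forward model: BOLD = design x weights + AR(1) + white noise scaled
    to the target SNR, plus slow cosine drift and a constant baseline."""
    rng = np.random.default_rng(cfg.seed + 2 if rng is None else rng)
    signal = predict_series(wt_true, design)
    run_index = design.run_index if run_index is None else run_index
    n_vol, n_vox = signal.shape
    var_s = signal.var(axis=0)
    ref = np.median(var_s[var_s > 0]) if (var_s > 0).any() else 1.0
    target_sd = np.sqrt(np.where(var_s > 0, var_s, ref) / cfg.snr)

    white = rng.standard_normal((n_vox, n_vol))
    noise = np.sqrt(1.0 - cfg.ar_frac) * white
    if cfg.ar_frac > 0:
        noise = noise + np.sqrt(cfg.ar_frac) * _ar1_noise(
            (n_vox, n_vol), cfg.ar_coef, rng)
    noise = noise * target_sd[:, None]

    drift = np.zeros((n_vox, n_vol))
    if cfg.drift_amplitude > 0:
        for run in sorted(pd.unique(run_index).tolist()):
            mask = run_index == run
            t = np.arange(mask.sum()) * cfg.tr_seconds
            for period in cfg.drift_periods:
                phase = rng.uniform(0, 2 * np.pi, size=n_vox)
                amp = cfg.drift_amplitude * target_sd / np.sqrt(
                    2 * len(cfg.drift_periods))
                drift[:, mask] += amp[:, None] * np.cos(
                    2 * np.pi * t[None, :] / period + phase[:, None])

    data = signal.T + noise + drift + cfg.baseline
    if cfg.spike_prob > 0:
        spikes = rng.random(n_vol) < cfg.spike_prob
        data[:, spikes] += cfg.spike_amplitude
    return BoldRuns(data, np.asarray(run_index).copy(), cfg.tr_seconds)


def _behavior_model(cfg: SimConfig, rng):
    """Per-behavior baseline and planted-dimension coefficients."""
    base_p = cfg.mean_selections / cfg.n_behaviors
    beta = rng.standard_normal((cfg.n_behaviors, 3))
    beta *= cfg.behavior_beta_scale / np.sqrt(3)
    return base_p, beta


def rater_probabilities(stim: StimulusSet, planted: PlantedTuning,
                        cfg: SimConfig, rng=None):
    """Image x behavior selection probabilities implied by the planted
    dimensions, plus the image ids (sorted) they index."""
    rng = np.random.default_rng(cfg.seed + 3 if rng is None else rng)
    ids = sorted(i for i, lab in stim.labels.items() if not lab.excluded)
    F = np.array([stim.space.encode(stim.labels[i]) for i in ids])
    s = F @ planted.loadings
    s = (s - s.mean(axis=0)) / np.maximum(s.std(axis=0), 1e-12)
    base_p, beta = _behavior_model(cfg, rng)
    lin = s @ beta.T
    if cfg.behavior_link == "logistic":
        # calibrate the intercept so the mean selection probability hits
        # the target despite the spread of the linear predictor
        logit0 = np.log(base_p / (1 - base_p))
        for _ in range(4):
            P = 1.0 / (1.0 + np.exp(-(logit0 + lin)))
            logit0 += np.log(base_p) - np.log(P.mean())
        P = 1.0 / (1.0 + np.exp(-(logit0 + lin)))
    elif cfg.behavior_link == "linear":
        # truly linear probabilities: base rate and slope sized so the
        # clip almost never engages (selection rate is higher than the
        # logistic default - linearity, not realism, is the point here)
        P = np.clip(0.3 + 0.1 * lin, 0.02, 0.98)
    else:
        raise ValueError(f"unknown behavior link {cfg.behavior_link!r}")
    return ids, P


def gen_raters(stim: StimulusSet, planted: PlantedTuning, cfg: SimConfig,
               rng=None):
    """Worker x image x behavior selection table: 9 raters per image, each
    selecting behaviors by independent Bernoulli draws on the planted-
    dimension probabilities (~2 selections per rater on average).

    Returns ``(raw_table, probabilities_dataframe)``.
    """
    rng = np.random.default_rng(cfg.seed + 3 if rng is None else rng)
    ids, P = rater_probabilities(stim, planted, cfg, rng)
    behaviors = bhv.BEHAVIOR_TAXONOMY[: cfg.n_behaviors]
    workers = [f"w{k:03d}" for k in range(cfg.n_workers)]
    rows = []
    for ii, img in enumerate(ids):
        chosen = rng.choice(cfg.n_workers, size=cfg.n_raters, replace=False)
        # independent Bernoulli selections; a rater may select nothing,
        # which keeps proportions unbiased for P and the binomial
        # explainable-variance ceiling exact
        draws = rng.random((cfg.n_raters, len(behaviors))) < P[ii]
        for rix, w in enumerate(chosen):
            picked = np.flatnonzero(draws[rix])
            if picked.size == 0:
                # record participation with an empty selection so the
                # proportion denominator still counts this rater
                rows.append({"worker_id": workers[int(w)],
                             "image_id": img, "behavior": ""})
            for b in picked:
                rows.append({"worker_id": workers[int(w)], "image_id": img,
                             "behavior": behaviors[int(b)]})
    raw = pd.DataFrame(rows)
    probs = pd.DataFrame(P, index=ids, columns=behaviors)
    return raw, probs


def analytic_explainable_variance(probs: pd.DataFrame,
                                  n_raters: int) -> float:
    """Closed-form inter-rater explainable-variance ceiling implied by the
    generating probabilities: pooled per-behavior-centered true variance
    over itself plus the binomial rater noise."""
    P = probs.to_numpy(dtype=float)
    true_var = (P.var(axis=0)).sum()
    noise_var = (P * (1 - P)).mean(axis=0).sum() / n_raters
    return float(true_var / (true_var + noise_var))


@dataclass
class Experiment:
    """A complete synthetic study for one subject."""

    cfg: SimConfig
    stim: StimulusSet
    wt_true: WeightTensor
    planted: PlantedTuning
    design_est: object
    design_val: object
    bold_est: BoldRuns
    bold_val: BoldRuns
    raters: pd.DataFrame | None = None
    rater_probs: pd.DataFrame | None = None


def gen_experiment(cfg: SimConfig, with_raters: bool = True,
                   stim: StimulusSet | None = None) -> Experiment:
    """Generate a full synthetic subject from the config's seed.

    Passing a shared ``stim`` creates additional subjects of a common
    study: same stimuli and planted loading basis (the basis is a
    deterministic function of the feature space), independent voxel scores
    and noise.
    """
    seq = np.random.SeedSequence(cfg.seed)
    r_stim, r_tune, r_bold_e, r_bold_v, r_raters = [
        np.random.default_rng(s) for s in seq.spawn(5)]
    if stim is None:
        stim = gen_stimulus_set(cfg, r_stim)
    wt_true, planted_out = gen_tuning(cfg, stim.space, r_tune)
    spec = FIRSpec(tr_seconds=cfg.tr_seconds)
    design_est = build_design(stim.events_est, stim.labels, stim.space,
                              stim.run_lengths_est, spec)
    design_val = build_design(stim.events_val, stim.labels, stim.space,
                              stim.run_lengths_val, spec)
    bold_est = gen_bold(design_est, wt_true, cfg, r_bold_e)
    bold_val = gen_bold(design_val, wt_true, cfg, r_bold_v)
    raters = probs = None
    if with_raters:
        raters, probs = gen_raters(stim, planted_out, cfg, r_raters)
    return Experiment(cfg, stim, wt_true, planted_out, design_est,
                      design_val, bold_est, bold_val, raters, probs)
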