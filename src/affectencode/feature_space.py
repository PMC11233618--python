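"""Model feature spaces, stimulus encoding, and FIR design-matrix construction.

The experiment presents natural images while BOLD data are recorded; each
image carries a semantic category, a subject-specific valence categorization
(negative / neutral / positive), a subject-specific arousal level (low / high
from a median split of 1-9 ratings), and optional semantic-emotion (SE) flags
such as "Mutilated humans" or "Erotica couples".

Five label-driven feature spaces are supported:

* ``CSVA``           - category x valence x arousal compound features
                       (21 x 3 x 2 = 126) plus 18 SE features = 144.
* ``SemanticOnly``   - the 21 mutually exclusive categories.
* ``ValenceArousal`` - the 6 valence x arousal compounds.
* ``SVAA``           - compounds for the 12 animate categories only,
                       plain category features for the 9 inanimate ones.
* ``SVAI``           - the mirror image (compounds for inanimate only).

A sixth, image-computed space (Gabor wavelet energies) is provided by
:class:`GaborBank` / :func:`gabor_features`.

Design matrices expand every feature regressor with a 4-bin finite impulse
response (FIR) filter covering 2-4, 4-6, 6-8 and 8-10 s post stimulus onset
(one bin per TR at TR = 2 s), so the hemodynamic response shape is estimated
per feature rather than assumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EXCLUDED",
    "CATEGORIES",
    "ANIMATE_CATEGORIES",
    "INANIMATE_CATEGORIES",
    "SE_FEATURES",
    "VALENCE_LEVELS",
    "AROUSAL_LEVELS",
    "ImageLabel",
    "Feature",
    "FeatureSpace",
    "FIRSpec",
    "DesignMatrix",
    "GaborBank",
    "build_feature_space",
    "resolve_valence",
    "median_split_arousal",
    "fir_expand",
    "build_design",
    "gabor_features",
    "gabor_feature_matrix",
    "type1_index1_sequence",
]

#: Sentinel for images with an unresolvable valence (tied negative/positive
#: categorizations with no neutral); such images never enter design matrices.
EXCLUDED = "EXCLUDED"

# (name, animate, human, animacy level 0-3).  Animacy scale: inanimate 0,
# invertebrates / non-mammalian vertebrates 1, non-human mammals 2, humans 3.
_CATEGORY_META = [
    ("Human-Face", True, True, 3),
    ("Human-Body", True, True, 3),
    ("Human-Body-Part", True, True, 3),
    ("Human-Couple", True, True, 3),
    ("Human-Gathering", True, True, 3),
    ("Human-Crowd", True, True, 3),
    ("Land-Mammal", True, False, 2),
    ("Water-Mammal", True, False, 2),
    ("Bird", True, False, 1),
    ("Fish", True, False, 1),
    ("Reptile", True, False, 1),
    ("Insect", True, False, 1),
    ("Savory-Food", False, False, 0),
    ("Dessert-Food", False, False, 0),
    ("Household-Object", False, False, 0),
    ("Other-Artifact", False, False, 0),
    ("Indoor-Building", False, False, 0),
    ("Outdoor-Building", False, False, 0),
    ("Water-Scenery", False, False, 0),
    ("Sky-Scenery", False, False, 0),
    ("Land-Scenery", False, False, 0),
]
# Rarely-shown categories, excluded from default spaces (behind a flag).
_EXTRA_CATEGORY_META = [
    ("Plants", False, False, 0),
    ("Vehicles", False, False, 0),
]

CATEGORIES = [c[0] for c in _CATEGORY_META]
ANIMATE_CATEGORIES = [c[0] for c in _CATEGORY_META if c[1]]
INANIMATE_CATEGORIES = [c[0] for c in _CATEGORY_META if not c[1]]

# SE feature metadata: (name, animate, human, animacy).  Modal valence /
# arousal are data-derived attributes (see FeatureSpace.se_affect); the
# defaults below are the synthetic-experiment convention.
_SE_META = [
    ("Mutilated humans", True, True, 3),
    ("Mutilated animals", True, False, 2),
    ("Rotten food", False, False, 0),
    ("Threat toward viewer human aggressor", True, True, 3),
    ("Threat toward viewer animal aggressor", True, False, 2),
    ("Threat away from viewer human aggressor", True, True, 3),
    ("Threat away from viewer animal aggressor", True, False, 2),
    ("Romantic couples portrait", True, True, 3),
    ("Romantic couples full bodies", True, True, 3),
    ("Human babies", True, True, 3),
    ("Animal babies", True, False, 2),
    ("Human social interaction portrait", True, True, 3),
    ("Human social interaction single human", True, True, 3),
    ("Human social interaction couples", True, True, 3),
    ("Human social interaction gatherings", True, True, 3),
    ("Erotica portrait", True, True, 3),
    ("Erotica single human", True, True, 3),
    ("Erotica couples", True, True, 3),
]
SE_FEATURES = [s[0] for s in _SE_META]

#: Default (valence, arousal) per SE feature, used when no rating data are
#: available to compute the across-subject mode.
DEFAULT_SE_AFFECT = {
    "Mutilated humans": (-1, 1),
    "Mutilated animals": (-1, 1),
    "Rotten food": (-1, 0),
    "Threat toward viewer human aggressor": (-1, 1),
    "Threat toward viewer animal aggressor": (-1, 1),
    "Threat away from viewer human aggressor": (-1, 1),
    "Threat away from viewer animal aggressor": (-1, 1),
    "Romantic couples portrait": (1, 1),
    "Romantic couples full bodies": (1, 1),
    "Human babies": (1, 0),
    "Animal babies": (1, 0),
    "Human social interaction portrait": (0, 0),
    "Human social interaction single human": (0, 0),
    "Human social interaction couples": (0, 0),
    "Human social interaction gatherings": (0, 0),
    "Erotica portrait": (1, 1),
    "Erotica single human": (1, 1),
    "Erotica couples": (1, 1),
}

VALENCE_LEVELS = (-1, 0, 1)  # negative, neutral, positive
AROUSAL_LEVELS = (0, 1)  # low, high
_VALENCE_NAMES = {-1: "negative", 0: "neutral", 1: "positive"}
_AROUSAL_NAMES = {0: "low", 1: "high"}


@dataclass(frozen=True)
class ImageLabel:
    """Per-image stimulus label.

    ``valence`` is -1/0/+1 or the string :data:`EXCLUDED`; ``arousal`` is
    0 (low) / 1 (high); ``se_flags`` holds names from :data:`SE_FEATURES`.
    """

    image_id: str
    category: str
    valence: object = 0
    arousal: int = 0
    se_flags: tuple = ()

    def __post_init__(self):
        if self.valence != EXCLUDED and self.valence not in VALENCE_LEVELS:
            raise ValueError(f"invalid valence {self.valence!r}")
        if self.arousal not in AROUSAL_LEVELS:
            raise ValueError(f"invalid arousal {self.arousal!r}")
        unknown = set(self.se_flags) - set(SE_FEATURES)
        if unknown:
            raise ValueError(f"unknown SE flags: {sorted(unknown)}")

    @property
    def excluded(self) -> bool:
        return self.valence == EXCLUDED


@dataclass(frozen=True)
class Feature:
    """One feature of a model space, with the metadata the tuning-space
    analyses need (animacy scale, humanness, affective codes)."""

    name: str
    kind: str  # "compound" | "semantic" | "va" | "se"
    category: str | None = None
    valence: int | None = None
    arousal: int | None = None
    animate: bool | None = None
    human: bool | None = None
    animacy: int | None = None


class FeatureSpace:
    """Ordered feature list plus the rule encoding an :class:`ImageLabel`
    into a binary vector.  Feature ordering is part of the contract: design
    matrices, weight tensors and PC loadings all share it."""

    def __init__(self, name: str, features: Sequence[Feature]):
        self.name = name
        self.features = list(features)
        self.feature_names = [f.name for f in self.features]
        self._index = {f.name: i for i, f in enumerate(self.features)}
        if len(self._index) != len(self.features):
            raise ValueError("duplicate feature names")

    def __len__(self) -> int:
        return len(self.features)

    def __repr__(self) -> str:
        return f"FeatureSpace({self.name!r}, {len(self)} features)"

    @property
    def n_compound(self) -> int:
        return sum(f.kind in ("compound", "semantic", "va") for f in self.features)

    @property
    def compound_slice(self) -> slice:
        """The mutually exclusive block (everything except SE features)."""
        return slice(0, self.n_compound)

    def index(self, name: str) -> int:
        return self._index[name]

    # -- encoding -----------------------------------------------------------

    def encode(self, label: ImageLabel) -> np.ndarray:
        """Binary feature vector for one image.

        Exactly one bit is set in the mutually exclusive compound block;
        SE bits are set independently.  Raises for EXCLUDED labels (they
        must be filtered before encoding) and unknown categories.
        """
        if label.excluded:
            raise ValueError(f"image {label.image_id} has EXCLUDED valence")
        vec = np.zeros(len(self.features), dtype=float)
        name = self._compound_name(label)
        if name not in self._index:
            raise KeyError(
                f"category {label.category!r} not representable in space {self.name!r}"
            )
        vec[self._index[name]] = 1.0
        for flag in label.se_flags:
            if flag in self._index:
                vec[self._index[flag]] = 1.0
        return vec

    def _compound_name(self, label: ImageLabel) -> str:
        kinds = {f.kind for f in self.features}
        v = _VALENCE_NAMES[label.valence]
        a = _AROUSAL_NAMES[label.arousal]
        if self.name == "ValenceArousal":
            return f"{v}|{a}"
        crossed = f"{label.category}|{v}|{a}"
        plain = label.category
        if crossed in self._index:
            return crossed
        if plain in self._index:
            return plain
        # fall through -> KeyError in encode()
        return crossed if "compound" in kinds else plain

    def encode_batch(self, labels: Iterable[ImageLabel]) -> np.ndarray:
        return np.array([self.encode(l) for l in labels])

    def decode_compound(self, vec: np.ndarray) -> Feature:
        """Recover the compound feature from an encoded vector (argmax of the
        mutually exclusive block)."""
        block = np.asarray(vec)[self.compound_slice]
        return self.features[int(np.argmax(block))]

    # -- SE affect metadata -------------------------------------------------

    def set_se_affect(self, affect: Mapping[str, tuple]) -> None:
        """Attach (modal valence, modal arousal) to each SE feature."""
        updated = []
        for f in self.features:
            if f.kind == "se" and f.name in affect:
                v, a = affect[f.name]
                f = Feature(f.name, f.kind, f.category, int(v), int(a),
                            f.animate, f.human, f.animacy)
            updated.append(f)
        self.features = updated
        self._index = {f.name: i for i, f in enumerate(self.features)}

    def set_se_affect_from_labels(
        self, label_sets: Sequence[Mapping[str, ImageLabel]]
    ) -> None:
        """Set SE affect as the across-subject mode of the valence / arousal
        of images carrying each flag.  ``label_sets`` holds one image_id ->
        label mapping per subject."""
        affect = {}
        for se in SE_FEATURES:
            vals, aros = [], []
            for labels in label_sets:
                for lab in labels.values():
                    if se in lab.se_flags and not lab.excluded:
                        vals.append(lab.valence)
                        aros.append(lab.arousal)
            if vals:
                affect[se] = (_mode(vals), _mode(aros))
        self.set_se_affect(affect)

    # -- (de)serialization --------------------------------------------------

    def to_manifest(self) -> dict:
        return {
            "name": self.name,
            "features": [
                {k: getattr(f, k) for k in
                 ("name", "kind", "category", "valence", "arousal",
                  "animate", "human", "animacy")}
                for f in self.features
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_manifest(), fh, indent=1)

    @classmethod
    def from_manifest(cls, manifest: Mapping) -> "FeatureSpace":
        feats = [Feature(**f) for f in manifest["features"]]
        return cls(manifest["name"], feats)

    @classmethod
    def from_json(cls, path) -> "FeatureSpace":
        with open(path) as fh:
            return cls.from_manifest(json.load(fh))


def _mode(values):
    vals, counts = np.unique(values, return_counts=True)
    return vals[int(np.argmax(counts))].item()


def _compound_features(categories) -> list[Feature]:
    feats = []
    for name, animate, human, animacy in categories:
        for v in VALENCE_LEVELS:
            for a in AROUSAL_LEVELS:
                feats.append(Feature(
                    f"{name}|{_VALENCE_NAMES[v]}|{_AROUSAL_NAMES[a]}",
                    "compound", name, v, a, animate, human, animacy))
    return feats


def _semantic_features(categories) -> list[Feature]:
    return [Feature(name, "semantic", name, None, None, animate, human, animacy)
            for name, animate, human, animacy in categories]


def _se_feature_list() -> list[Feature]:
    feats = []
    for name, animate, human, animacy in _SE_META:
        v, a = DEFAULT_SE_AFFECT[name]
        feats.append(Feature(name, "se", None, v, a, animate, human, animacy))
    return feats


def build_feature_space(model_name: str,
                        include_plants_vehicles: bool = False) -> FeatureSpace:
    """Construct one of the five label-driven model spaces.

    ``CSVA`` crosses all categories with valence and arousal and appends the
    18 SE features; ``SVAA`` / ``SVAI`` cross only the animate / inanimate
    categories respectively, keeping plain category features for the rest.
    """
    cats = list(_CATEGORY_META)
    if include_plants_vehicles:
        cats = cats + list(_EXTRA_CATEGORY_META)
    animate = [c for c in cats if c[1]]
    inanimate = [c for c in cats if not c[1]]
    if model_name == "CSVA":
        feats = _compound_features(cats) + _se_feature_list()
    elif model_name == "SemanticOnly":
        feats = _semantic_features(cats)
    elif model_name == "ValenceArousal":
        feats = [Feature(f"{_VALENCE_NAMES[v]}|{_AROUSAL_NAMES[a]}",
                         "va", None, v, a, None, None, None)
                 for v in VALENCE_LEVELS for a in AROUSAL_LEVELS]
    elif model_name == "SVAA":
        feats = _compound_features(animate) + _semantic_features(inanimate)
    elif model_name == "SVAI":
        feats = _compound_features(inanimate) + _semantic_features(animate)
    else:
        raise ValueError(f"unknown model name {model_name!r}")
    return FeatureSpace(model_name, feats)


# ---------------------------------------------------------------------------
# label construction from ratings


def resolve_valence(categorizations: Sequence[int]):
    """Collapse repeated valence categorizations of one image to a single
    code.  Modal value when unique; a tie containing neutral resolves to
    neutral; a negative/positive tie without neutral is EXCLUDED."""
    if len(categorizations) == 0:
        raise ValueError("empty categorization list")
    vals, counts = np.unique(np.asarray(categorizations, dtype=int),
                             return_counts=True)
    tied = vals[counts == counts.max()]
    if len(tied) == 1:
        return int(tied[0])
    if 0 in tied:
        return 0
    return EXCLUDED


def median_split_arousal(ratings: Mapping[str, float] | Sequence[float]):
    """Median-split one subject's 1-9 arousal ratings into low (0) / high (1).

    Ratings at or above the sample median are high; below are low.
    """
    if isinstance(ratings, Mapping):
        keys = list(ratings)
        values = np.asarray([ratings[k] for k in keys], dtype=float)
    else:
        keys = None
        values = np.asarray(ratings, dtype=float)
    if values.size == 0:
        raise ValueError("empty ratings")
    med = np.median(values)
    split = (values >= med).astype(int)
    if keys is not None:
        return dict(zip(keys, (int(s) for s in split)))
    return split


# ---------------------------------------------------------------------------
# FIR expansion and design matrices


@dataclass(frozen=True)
class FIRSpec:
    """Finite-impulse-response expansion: ``delay_bins`` delayed copies of
    each regressor, bin b placing an onset at volume v onto volume v + b
    (2-4 s ... 8-10 s post onset at TR = 2 s)."""

    tr_seconds: float = 2.0
    delay_bins: int = 4


@dataclass
class DesignMatrix:
    """Volumes x columns design with (feature, bin) column labels, optional
    nuisance columns at the right edge, and a per-row run index."""

    values: np.ndarray
    feature_names: list
    n_bins: int
    run_index: np.ndarray
    nuisance_names: list = field(default_factory=list)

    @property
    def n_feature_cols(self) -> int:
        return len(self.feature_names) * self.n_bins

    @property
    def feature_values(self) -> np.ndarray:
        return self.values[:, : self.n_feature_cols]

    def column_label(self, j: int):
        if j < self.n_feature_cols:
            return (self.feature_names[j // self.n_bins], j % self.n_bins + 1)
        return self.nuisance_names[j - self.n_feature_cols]


def fir_expand(indicator: np.ndarray, spec: FIRSpec = FIRSpec()) -> np.ndarray:
    """Expand a per-volume onset indicator into ``delay_bins`` shifted
    columns, truncating at the end of the series (one run)."""
    x = np.asarray(indicator, dtype=float)
    n = x.shape[0]
    out = np.zeros((n, spec.delay_bins))
    for b in range(1, spec.delay_bins + 1):
        out[b:, b - 1] = x[: n - b]
    return out


def build_design(
    events: pd.DataFrame,
    labels: Mapping[str, ImageLabel],
    space: FeatureSpace,
    run_lengths: Mapping,
    spec: FIRSpec = FIRSpec(),
    motion: np.ndarray | None = None,
) -> DesignMatrix:
    """Build the FIR-expanded design matrix for a run-structured event table.

    ``events`` needs columns ``run``, ``onset_volume``, ``image_id`` and
    ``is_null``; null trials and EXCLUDED images contribute all-zero rows.
    ``motion`` (optional) appends 6 nuisance columns as-is.
    """
    runs = sorted(run_lengths)
    n_feat = len(space)
    blocks, run_idx = [], []
    for run in runs:
        n_vol = int(run_lengths[run])
        onset = np.zeros((n_vol, n_feat))
        sub = events[events["run"] == run]
        prev = -1
        for _, ev in sub.iterrows():
            v = int(ev["onset_volume"])
            if v <= prev:
                raise ValueError(f"onsets not strictly increasing in run {run}")
            prev = v
            if bool(ev.get("is_null", False)):
                continue
            img = ev["image_id"]
            if img not in labels:
                raise KeyError(f"event references unlabeled image {img!r}")
            lab = labels[img]
            if lab.excluded:
                continue
            if v < n_vol:
                onset[v] += space.encode(lab)
        # expand: column ordering (feature, bin)
        block = np.zeros((n_vol, n_feat * spec.delay_bins))
        for b in range(1, spec.delay_bins + 1):
            block[b:, (b - 1):: spec.delay_bins] = onset[: n_vol - b]
        blocks.append(block)
        run_idx.append(np.full(n_vol, run))
    X = np.vstack(blocks) if blocks else np.zeros((0, n_feat * spec.delay_bins))
    run_index = np.concatenate(run_idx) if run_idx else np.array([])
    nuisance_names: list = []
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != X.shape[0]:
            raise ValueError("motion rows do not match design rows")
        X = np.hstack([X, motion])
        nuisance_names = [f"motion_{i + 1}" for i in range(motion.shape[1])]
    return DesignMatrix(X, list(space.feature_names), spec.delay_bins,
                        run_index, nuisance_names)


# ---------------------------------------------------------------------------
# Gabor wavelet image features


@dataclass(frozen=True)
class GaborBank:
    """Quadrature Gabor filter bank tiling the image.

    Per spatial frequency, the Gaussian envelope SD is
    ``sd_factor * image_size / frequency`` pixels (~1-octave bandwidth) and
    grid centers are ``spacing_sds`` SDs apart, covering the image.  The
    resulting filter count follows from this rule and the configuration.
    """

    image_size: int = 500
    orientations: tuple = (0.0, 45.0, 90.0, 135.0)
    frequencies: tuple = (1.5, 3.0, 6.0, 12.0, 24.0)
    sd_factor: float = 0.375
    spacing_sds: float = 3.0

    def grid(self, freq: float) -> tuple[float, np.ndarray]:
        sd = self.sd_factor * self.image_size / freq
        spacing = self.spacing_sds * sd
        n = max(1, int(np.ceil(self.image_size / spacing)))
        offset = (self.image_size - (n - 1) * spacing) / 2.0
        return sd, offset + spacing * np.arange(n)

    def filters(self):
        """Yield (frequency, orientation_deg, cy, cx, sd) for every filter."""
        for f in self.frequencies:
            sd, centers = self.grid(f)
            for cy in centers:
                for cx in centers:
                    for theta in self.orientations:
                        yield f, theta, cy, cx, sd

    @property
    def n_filters(self) -> int:
        return sum(1 for _ in self.filters())


def _gabor_kernel(freq_cpi, theta_deg, sd, size, truncate=3.0):
    """Quadrature pair on a truncated local support; returns (real, imag,
    y0, x0) where (y0, x0) is the top-left placement offset."""
    half = int(np.ceil(truncate * sd))
    ax = np.arange(-half, half + 1)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    theta = np.deg2rad(theta_deg)
    rot = xx * np.cos(theta) + yy * np.sin(theta)
    env = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sd ** 2))
    phase = 2.0 * np.pi * (freq_cpi / size) * rot
    return env * np.cos(phase), env * np.sin(phase)


def gabor_features(image: np.ndarray, bank: GaborBank = GaborBank(),
                   resample: bool = True) -> np.ndarray:
    """Per-filter Gabor energies of one grayscale image.

    The image is zero-meaned; each filter's energy is the quadrature-pair
    magnitude of the local inner product.  Images of the wrong size are
    resampled when ``resample`` is true, otherwise rejected.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:  # RGB -> luminance
        img = img.mean(axis=2)
    if not np.all(np.isfinite(img)):
        raise ValueError("non-finite image values")
    if img.shape != (bank.image_size, bank.image_size):
        if not resample:
            raise ValueError(
                f"image shape {img.shape} != {(bank.image_size,) * 2}")
        from scipy.ndimage import zoom
        zy = bank.image_size / img.shape[0]
        zx = bank.image_size / img.shape[1]
        img = zoom(img, (zy, zx), order=1)
        img = img[: bank.image_size, : bank.image_size]
    img = img - img.mean()

    energies = np.empty(bank.n_filters)
    kern_cache: dict = {}
    for i, (f, theta, cy, cx, sd) in enumerate(bank.filters()):
        key = (f, theta)
        if key not in kern_cache:
            kern_cache[key] = _gabor_kernel(f, theta, sd, bank.image_size)
        kre, kim = kern_cache[key]
        half = kre.shape[0] // 2
        y0, y1 = int(round(cy)) - half, int(round(cy)) + half + 1
        x0, x1 = int(round(cx)) - half, int(round(cx)) + half + 1
        ky0, kx0 = max(0, -y0), max(0, -x0)
        y0, x0 = max(0, y0), max(0, x0)
        y1, x1 = min(img.shape[0], y1), min(img.shape[1], x1)
        patch = img[y0:y1, x0:x1]
        kr = kre[ky0: ky0 + patch.shape[0], kx0: kx0 + patch.shape[1]]
        ki = kim[ky0: ky0 + patch.shape[0], kx0: kx0 + patch.shape[1]]
        energies[i] = np.hypot((patch * kr).sum(), (patch * ki).sum())
    return energies


def gabor_feature_matrix(images: Sequence[np.ndarray],
                         bank: GaborBank = GaborBank()) -> np.ndarray:
    """Stack per-image Gabor energies and z-score each feature across the
    image set (normalizing energy-magnitude differences across filter
    sizes).  Constant features map to zero."""
    M = np.array([gabor_features(im, bank) for im in images])
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    sd[sd == 0] = 1.0
    return (M - mu) / sd


# ---------------------------------------------------------------------------
# serially counterbalanced validation sequences


def type1_index1_sequence(m: int, seed) -> np.ndarray:
    """Type-1 Index-1 condition sequence: a closed walk of length m**2 + 1 on
    the complete directed graph with self-loops, in which every ordered pair
    of conditions (self-pairs included) occurs exactly once.

    Constructed as a random Eulerian circuit (Hierholzer's algorithm with a
    seeded RNG choosing among unused edges); the same seed reproduces the
    same sequence.
    """
    if m < 2:
        raise ValueError("need at least 2 conditions")
    rng = np.random.default_rng(seed)
    # unused[i] = list of targets j still available from i
    unused = [list(rng.permutation(m)) for _ in range(m)]
    start = int(rng.integers(m))
    stack, circuit = [start], []
    while stack:
        v = stack[-1]
        if unused[v]:
            stack.append(int(unused[v].pop()))
        else:
            circuit.append(stack.pop())
    seq = np.array(circuit[::-1], dtype=int)
    assert len(seq) == m * m + 1, "Eulerian circuit construction failed"
    return seq
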