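"""BOLD conditioning applied before model fitting.

Operates on run-structured voxel x time arrays.  The fixed stage order is:

1. bad-volume diagnostic (scaled mean-square successive difference) and
   replacement by good-neighbor averaging,
2. regression of an image-on/off nuisance FIR set (removing variance due
   simply to stimulus presence),
3. Savitzky-Golay low-frequency detrend (120 s window, cubic),
4. per-run per-voxel demeaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .feature_space import FIRSpec, fir_expand

__all__ = [
    "BoldRuns",
    "scaled_msd_diagnostic",
    "replace_bad_volumes",
    "regress_out_onoff",
    "sg_detrend",
    "demean_runs",
    "preprocess_pipeline",
]

DEFAULT_CUTOFF = 10.0


@dataclass
class BoldRuns:
    """Concatenated voxel x volume BOLD matrix with a per-volume run index."""

    data: np.ndarray  # (n_voxels, n_volumes)
    run_index: np.ndarray  # (n_volumes,)
    tr_seconds: float = 2.0
    voxel_meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.run_index = np.asarray(self.run_index)
        if self.data.shape[1] != self.run_index.shape[0]:
            raise ValueError("run_index length must match volume count")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    @property
    def runs(self):
        return sorted(pd.unique(self.run_index).tolist())

    def run_mask(self, run) -> np.ndarray:
        return self.run_index == run

    def run_data(self, run) -> np.ndarray:
        return self.data[:, self.run_mask(run)]

    def run_lengths(self) -> dict:
        return {r: int(self.run_mask(r).sum()) for r in self.runs}

    def copy(self) -> "BoldRuns":
        return BoldRuns(self.data.copy(), self.run_index.copy(),
                        self.tr_seconds, self.voxel_meta)


def scaled_msd_diagnostic(run_data: np.ndarray,
                          cutoff: float = DEFAULT_CUTOFF):
    """Volume-to-volume scaled mean-square-difference diagnostic for one run.

    The statistic for transition n is the voxel-mean squared intensity
    difference between volumes n and n-1, divided by the grand mean signal of
    the whole run.  Both volumes of a transition exceeding ``cutoff``
    (strictly) are flagged.

    Returns ``(stat, flags)`` where ``stat`` has one value per transition
    (length n_volumes - 1) and ``flags`` is a per-volume boolean vector.
    """
    x = np.asarray(run_data, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 volumes")
    grand = x.mean()
    if grand == 0:
        raise ValueError("zero whole-series mean signal")
    diff = np.diff(x, axis=1)
    stat = (diff ** 2).mean(axis=0) / grand
    flags = np.zeros(x.shape[1], dtype=bool)
    bad = stat > cutoff
    flags[1:][bad] = True
    flags[:-1][bad] = True
    return stat, flags


def replace_bad_volumes(run_data: np.ndarray, flags: np.ndarray) -> np.ndarray:
    """Replace flagged volumes by the average of the nearest unflagged
    volume on each side (or the single nearest good volume at run edges)."""
    x = np.asarray(run_data, dtype=float).copy()
    flags = np.asarray(flags, dtype=bool)
    good = np.flatnonzero(~flags)
    if good.size == 0:
        raise ValueError("all volumes flagged")
    for i in np.flatnonzero(flags):
        left = good[good < i]
        right = good[good > i]
        if left.size and right.size:
            x[:, i] = 0.5 * (x[:, left[-1]] + x[:, right[0]])
        elif left.size:
            x[:, i] = x[:, left[-1]]
        else:
            x[:, i] = x[:, right[0]]
    return x


def _onoff_design(bold: BoldRuns, events: pd.DataFrame,
                  spec: FIRSpec = FIRSpec()) -> np.ndarray:
    """FIR-expanded image-present indicator, concatenated across runs."""
    blocks = []
    for run in bold.runs:
        n = int(bold.run_mask(run).sum())
        ind = np.zeros(n)
        sub = events[(events["run"] == run) & (~events["is_null"].astype(bool))]
        for v in sub["onset_volume"].astype(int):
            if v < n:
                ind[v] = 1.0
        blocks.append(fir_expand(ind, spec))
    return np.vstack(blocks)


def regress_out_onoff(bold: BoldRuns, events: pd.DataFrame,
                      spec: FIRSpec = FIRSpec()) -> BoldRuns:
    """Remove the least-squares projection of every voxel series onto the
    4-bin image-on/off FIR columns (fit on concatenated runs)."""
    D = _onoff_design(bold, events, spec)
    if not D.any():
        raise ValueError("degenerate on/off design: no stimuli in events")
    # per-run intercepts fitted jointly so the signal baseline cannot leak
    # into the on/off coefficients
    runs = bold.runs
    C = np.column_stack([(bold.run_index == r).astype(float) for r in runs])
    Df = np.column_stack([C, D])
    Y = bold.data.T  # volumes x voxels
    beta, *_ = np.linalg.lstsq(Df, Y, rcond=None)
    resid = Y - Df @ beta
    return BoldRuns(resid.T, bold.run_index.copy(), bold.tr_seconds,
                    bold.voxel_meta)


def sg_detrend(bold: BoldRuns, window_seconds: float = 120.0,
               polyorder: int = 3) -> BoldRuns:
    """Subtract a Savitzky-Golay smoothed trend (default 120 s window, cubic)
    per voxel per run.  The window in samples is the nearest odd count."""
    window = int(round(window_seconds / bold.tr_seconds))
    if window % 2 == 0:
        window += 1
    out = bold.copy()
    for run in bold.runs:
        mask = bold.run_mask(run)
        seg = bold.data[:, mask]
        if seg.shape[1] < window:
            raise ValueError(
                f"run {run!r} shorter ({seg.shape[1]}) than SG window ({window})")
        trend = savgol_filter(seg, window, polyorder, axis=1)
        out.data[:, mask] = seg - trend
    return out


def demean_runs(bold: BoldRuns) -> BoldRuns:
    """Subtract each voxel's mean within each run."""
    out = bold.copy()
    for run in bold.runs:
        mask = bold.run_mask(run)
        out.data[:, mask] -= out.data[:, mask].mean(axis=1, keepdims=True)
    return out


def preprocess_pipeline(bold: BoldRuns, events: pd.DataFrame,
                        cutoff: float = DEFAULT_CUTOFF,
                        window_seconds: float = 120.0,
                        polyorder: int = 3,
                        spec: FIRSpec = FIRSpec()) -> BoldRuns:
    """Full conditioning pipeline in the fixed order:
    diagnostic/replace -> on/off regression -> SG detrend -> demean."""
    cleaned = bold.copy()
    for run in bold.runs:
        mask = bold.run_mask(run)
        seg = cleaned.data[:, mask]
        _, flags = scaled_msd_diagnostic(seg, cutoff)
        if flags.any():
            cleaned.data[:, mask] = replace_bad_volumes(seg, flags)
    cleaned = regress_out_onoff(cleaned, events, spec)
    cleaned = sg_detrend(cleaned, window_seconds, polyorder)
    return demean_runs(cleaned)
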