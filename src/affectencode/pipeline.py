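"""End-to-end orchestration: simulate -> preprocess -> fit -> test ->
compare -> pca -> behavior, with stage-level caching and a run manifest.

Each stage's cache key is the SHA-256 of its own parameters chained with its
upstream stage's key, so changing (say) the lambda grid invalidates the fit
and everything downstream but not the simulated data.  Outputs land in a
run directory with a ``manifest.json`` recording seeds, config hashes and
stage artifacts.
"""

from __future__ import annotations

import hashlib
import json
import pickle
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .behavior import (aggregate_responses, explainable_variance,
                       loocv_predict, project_images)
from .encoding import accuracy, fit_encoding_model, predict_series
from .feature_space import FIRSpec, build_design, build_feature_space
from .inference import bootstrap_compare, fdr_bh, permutation_test
from .preprocess import preprocess_pipeline
from .synthetic import SimConfig, full_scale, gen_experiment
from .tuning_pca import noncentered_pca, peak_weights, stimulus_pca

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "roi_mask", "load_config"]

DEFAULT_CONFIG = {
    "seed": 0,
    "scale": "desk",  # or "full"
    "sim": {},  # SimConfig overrides
    "models": ["CSVA", "SemanticOnly", "ValenceArousal"],
    "fit": {"n_folds": 10},
    "permtest": {"n_perm": 1000, "q": 0.05},
    "compare": {"n_boot": 1000},
    "pca": {"k": 10},
    "behavior": {"max_pcs": 10},
}


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _key(params, upstream: str = "") -> str:
    blob = json.dumps(params, sort_keys=True, default=str) + upstream
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class _Cache:
    def __init__(self, root: Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def path(self, stage: str, key: str) -> Path:
        return self.root / f"{stage}-{key}.pkl"

    def get(self, stage: str, key: str):
        p = self.path(stage, key)
        if p.exists():
            with open(p, "rb") as fh:
                return pickle.load(fh)
        return None

    def put(self, stage: str, key: str, value) -> Path:
        p = self.path(stage, key)
        with open(p, "wb") as fh:
            pickle.dump(value, fh)
        return p


def _stage(cache, manifest, stage, params, upstream_key, fn, log):
    key = _key(params, upstream_key)
    out = cache.get(stage, key)
    t0 = time.time()
    if out is None:
        out = fn()
        cache.put(stage, key, out)
        status = "computed"
    else:
        status = "cached"
    log(f"[{stage}] {status} key={key} elapsed={time.time() - t0:.1f}s")
    manifest["stages"][stage] = {"key": key, "params": params,
                                 "status": status}
    return out, key


def roi_mask(voxel_meta: pd.DataFrame, significant: np.ndarray,
             superior: np.ndarray | None = None,
             require_superiority: bool = False,
             roi_column: str = "roi") -> np.ndarray:
    """Voxel selection: ROI membership AND significant model fit AND
    (optionally) superiority over the comparison model."""
    mask = voxel_meta[roi_column].to_numpy(dtype=bool) & np.asarray(
        significant, dtype=bool)
    if require_superiority:
        if superior is None:
            raise ValueError("superiority flags required")
        mask = mask & np.asarray(superior, dtype=bool)
    if not mask.any():
        raise ValueError(
            f"empty voxel mask (roi={int(voxel_meta[roi_column].sum())}, "
            f"significant={int(np.asarray(significant).sum())})")
    return mask


def run_pipeline(config: dict, out_dir, log=print) -> dict:
    """Execute the full analysis on a synthetic study and write results plus
    a manifest under ``out_dir``.  Returns the manifest dict."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache = _Cache(out / "cache")
    manifest = {"config": cfg, "seed": cfg["seed"], "stages": {},
                "version": 1}

    sim_cfg = SimConfig(seed=cfg["seed"], **cfg["sim"])
    if cfg["scale"] == "full":
        sim_cfg = full_scale(sim_cfg)

    # -- simulate ----------------------------------------------------------
    def do_sim():
        return gen_experiment(sim_cfg)

    exp, k_sim = _stage(cache, manifest, "simulate", asdict(sim_cfg), "",
                        do_sim, log)
    aio.write_labels_tsv(exp.stim.labels, out / "labels.tsv")
    aio.write_events_tsv(exp.stim.events_est, out / "events_est.tsv")
    aio.write_events_tsv(exp.stim.events_val, out / "events_val.tsv")
    if exp.raters is not None:
        exp.raters.to_csv(out / "raters.csv", index=False)
    exp.stim.space.to_json(out / "feature_space.json")

    # -- preprocess --------------------------------------------------------
    def do_pre():
        est = preprocess_pipeline(exp.bold_est, exp.stim.events_est)
        val = preprocess_pipeline(exp.bold_val, exp.stim.events_val)
        return est, val

    (bold_est, bold_val), k_pre = _stage(cache, manifest, "preprocess", {},
                                         k_sim, do_pre, log)

    # -- fit + validate per model -----------------------------------------
    spaces = {m: (exp.stim.space if m == "CSVA" else build_feature_space(m))
              for m in cfg["models"]}
    fits = {}
    k_fit = k_pre
    for model in cfg["models"]:
        space = spaces[model]
        des_e = build_design(exp.stim.events_est, exp.stim.labels, space,
                             exp.stim.run_lengths_est,
                             FIRSpec(sim_cfg.tr_seconds))
        des_v = build_design(exp.stim.events_val, exp.stim.labels, space,
                             exp.stim.run_lengths_val,
                             FIRSpec(sim_cfg.tr_seconds))

        def do_fit(des_e=des_e, des_v=des_v, model=model):
            wt = fit_encoding_model(des_e, bold_est.data.T,
                                    n_folds=cfg["fit"]["n_folds"],
                                    model_name=model)
            pred = predict_series(wt, des_v)
            return wt, pred

        (wt, pred), k_fit_m = _stage(cache, manifest, f"fit-{model}",
                                     cfg["fit"], k_pre, do_fit, log)
        fits[model] = {"wt": wt, "pred": pred, "des_v": des_v}
        k_fit = _key({"m": model}, k_fit + k_fit_m)
        aio.write_weights_h5(wt, out / f"weights_{model}.h5")

    # -- permutation significance -----------------------------------------
    def do_perm():
        res = {}
        for model, d in fits.items():
            acc = accuracy(d["pred"], bold_val.data.T)
            p, _, _ = permutation_test(
                d["wt"], exp.stim.events_val, exp.stim.labels,
                spaces[model], bold_val.data.T, exp.stim.run_lengths_val,
                n_perm=cfg["permtest"]["n_perm"], seed=cfg["seed"])
            acc.p = p
            acc.fdr_pass = fdr_bh(p, cfg["permtest"]["q"])
            res[model] = acc
        return res

    accs, k_perm = _stage(cache, manifest, "permtest", cfg["permtest"],
                          k_fit, do_perm, log)
    for model, acc in accs.items():
        aio.write_accuracy_tsv(acc, out / f"accuracy_{model}.tsv")

    # -- model comparison --------------------------------------------------
    def do_compare():
        res = {}
        any_sig = np.zeros(sim_cfg.n_voxels, dtype=bool)
        for acc in accs.values():
            any_sig |= acc.fdr_pass
        base = "CSVA"
        for model in cfg["models"]:
            if model == base or not any_sig.any():
                continue
            comp = bootstrap_compare(
                fits[base]["pred"], fits[model]["pred"], bold_val.data.T,
                bold_val.run_index, n_boot=cfg["compare"]["n_boot"],
                seed=cfg["seed"], mask=any_sig)
            res[f"{base}_vs_{model}"] = {
                "proportion": comp.mean_proportion, "z": comp.z, "p": comp.p}
        return res, any_sig

    (comparisons, any_sig), k_cmp = _stage(
        cache, manifest, "compare", cfg["compare"], k_perm, do_compare, log)
    with open(out / "comparisons.json", "w") as fh:
        json.dump(comparisons, fh, indent=1)

    # -- tuning PCA --------------------------------------------------------
    def do_pca():
        voxel_meta = pd.DataFrame({"roi": exp.planted.tuned})
        csva_sig = accs["CSVA"].fdr_pass
        mask = roi_mask(voxel_meta, csva_sig)
        M, names = peak_weights(fits["CSVA"]["wt"], exp.stim.space)
        dec = noncentered_pca(M[mask], k=cfg["pca"]["k"],
                              feature_names=names)
        F = np.array([exp.stim.space.encode(exp.stim.labels[i])
                      for i in sorted(exp.stim.labels)
                      if not exp.stim.labels[i].excluded])
        stim_dec = stimulus_pca([F], k=cfg["pca"]["k"], feature_names=names)
        return dec, stim_dec, mask

    (dec, stim_dec, mask), k_pca = _stage(cache, manifest, "pca",
                                          cfg["pca"], k_perm, do_pca, log)
    pd.DataFrame(dec.loadings, index=dec.feature_names).to_csv(
        out / "pc_loadings.tsv", sep="\t")

    # -- behavior ----------------------------------------------------------
    def do_behavior():
        if exp.raters is None:
            return None
        table = aggregate_responses(exp.raters)
        ev = explainable_variance(exp.raters, behaviors=table.retained,
                                  seed=cfg["seed"])
        scores = project_images(exp.stim.space, exp.stim.labels, dec,
                                n_pcs=min(cfg["behavior"]["max_pcs"],
                                          dec.n_components))
        curve = loocv_predict(table, scores, explainable=ev)
        return {"explainable_variance": ev,
                "curve": curve.to_dict(orient="records")}

    behav, _ = _stage(cache, manifest, "behavior", cfg["behavior"],
                      k_pca, do_behavior, log)
    if behav is not None:
        with open(out / "behavior_curve.json", "w") as fh:
            json.dump(behav, fh, indent=1)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
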