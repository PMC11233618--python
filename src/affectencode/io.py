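"""Readers and writers for the pipeline's on-disk formats.

Tabular data travel as TSV/CSV (labels, events, rater selections, accuracy
tables); BOLD matrices and weight tensors as HDF5; feature-space manifests
as JSON (see :meth:`FeatureSpace.to_json`).  4D NIfTI volumes plus a mask
are accepted as an alternative BOLD source.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import h5py

from .feature_space import EXCLUDED, ImageLabel, SE_FEATURES
from .preprocess import BoldRuns
from .encoding import WeightTensor

__all__ = [
    "write_labels_tsv", "read_labels_tsv",
    "write_events_tsv", "read_events_tsv",
    "write_bold_h5", "read_bold_h5", "read_bold_nifti",
    "write_weights_h5", "read_weights_h5",
    "write_accuracy_tsv",
]


def write_labels_tsv(labels: dict, path) -> None:
    rows = []
    for img in sorted(labels):
        lab = labels[img]
        row = {"image_id": img, "category": lab.category,
               "valence": lab.valence, "arousal": lab.arousal}
        for se in SE_FEATURES:
            row[se] = int(se in lab.se_flags)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_labels_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    labels = {}
    for _, row in df.iterrows():
        val = row["valence"]
        val = EXCLUDED if str(val) == EXCLUDED else int(val)
        flags = tuple(se for se in SE_FEATURES if se in df.columns
                      and int(row[se]) == 1)
        labels[str(row["image_id"])] = ImageLabel(
            str(row["image_id"]), str(row["category"]), val,
            int(row["arousal"]), flags)
    return labels


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"run": str, "image_id": str})
    df["is_null"] = df["is_null"].astype(bool)
    df["image_id"] = df["image_id"].fillna("")
    return df


def write_bold_h5(bold: BoldRuns, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=bold.data, compression="gzip")
        runs = np.asarray([str(r) for r in bold.run_index], dtype="S")
        f.create_dataset("run_index", data=runs)
        f.attrs["tr_seconds"] = bold.tr_seconds


def read_bold_h5(path) -> BoldRuns:
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        runs = np.array([r.decode() for r in f["run_index"][...]])
        tr = float(f.attrs.get("tr_seconds", 2.0))
    return BoldRuns(data, runs, tr)


def read_bold_nifti(img_paths, mask_path, run_ids=None,
                    tr_seconds: float = 2.0) -> BoldRuns:
    """Load run-structured BOLD from 4D NIfTI files plus a 3D mask; voxels
    are the nonzero mask entries, concatenated across the per-run files."""
    import nibabel as nib

    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    mats, runs = [], []
    if run_ids is None:
        run_ids = [f"run{i:02d}" for i in range(len(img_paths))]
    for rid, p in zip(run_ids, img_paths):
        vol = np.asarray(nib.load(str(p)).dataobj)  # x,y,z,t
        mats.append(vol[mask].astype(float))
        runs.append(np.full(vol.shape[-1], rid))
    return BoldRuns(np.hstack(mats), np.concatenate(runs), tr_seconds)


def write_weights_h5(wt: WeightTensor, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=wt.weights, compression="gzip")
        f.create_dataset("feature_names",
                         data=np.asarray(wt.feature_names, dtype="S"))
        f.attrs["model_name"] = wt.model_name
        f.attrs["lambda"] = wt.lambda_
        if wt.nuisance_weights is not None:
            f.create_dataset("nuisance_weights", data=wt.nuisance_weights)
            f.create_dataset("nuisance_names",
                             data=np.asarray(wt.nuisance_names, dtype="S"))


def read_weights_h5(path) -> WeightTensor:
    with h5py.File(path, "r") as f:
        W = f["weights"][...]
        names = [n.decode() for n in f["feature_names"][...]]
        nuis = f["nuisance_weights"][...] if "nuisance_weights" in f else None
        nnames = ([n.decode() for n in f["nuisance_names"][...]]
                  if "nuisance_names" in f else [])
        return WeightTensor(W, names, str(f.attrs.get("model_name", "")),
                            float(f.attrs.get("lambda", 0.0)), nuis, nnames)


def write_accuracy_tsv(acc, path, voxel_ids=None) -> None:
    n = len(acc.r)
    df = pd.DataFrame({
        "voxel": voxel_ids if voxel_ids is not None else np.arange(n),
        "r": acc.r, "t": acc.t, "z": acc.z,
        "degenerate": acc.degenerate.astype(int),
    })
    if acc.p is not None:
        df["p"] = acc.p
    if acc.fdr_pass is not None:
        df["fdr_pass"] = acc.fdr_pass.astype(int)
    df.to_csv(path, sep="\t", index=False)
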