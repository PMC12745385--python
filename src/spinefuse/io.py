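"""Readers and writers: PNG / NIfTI slices, cohort manifests, features.

PNG is the native interchange format for single slices (8- or 16-bit
grayscale; RGB inputs are collapsed by channel mean with a warning).
Single-slice NIfTI volumes are supported for interoperability; the middle
slice along the first axis is taken and min-max rescaled to [0, 1].
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .features import BLOCK_SPANS
from .phantom import Cohort, SliceStack

logger = logging.getLogger(__name__)

__all__ = [
    "read_slice",
    "read_case",
    "write_slice_png",
    "write_slice_nifti",
    "write_cohort",
    "read_cohort",
    "write_features",
    "read_features",
]


def read_slice(path) -> np.ndarray:
    """Load one 2-D grayscale grid in [0, 1] from PNG or NIfTI."""
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        vol = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
        while vol.ndim > 2:
            vol = vol[vol.shape[0] // 2] if vol.shape[0] > 1 else vol[0]
        lo, hi = vol.min(), vol.max()
        return (vol - lo) / (hi - lo) if hi > lo else np.zeros_like(vol)
    img = Image.open(path)
    a = np.asarray(img, dtype=float)
    if a.ndim == 3:
        logger.warning("RGB input %s collapsed to grayscale by channel mean", path)
        a = a[..., :3].mean(axis=2)
    denom = 65535.0 if a.max() > 255 else 255.0
    return np.clip(a / denom, 0.0, 1.0)


def read_case(paths: dict, label: str = "unknown", case_id: str = "case",
              pixel_spacing: float = 0.5) -> SliceStack:
    """Assemble a SliceStack from per-modality files; shapes must agree."""
    channels, shape = {}, None
    for modality, p in paths.items():
        a = read_slice(p)
        if shape is None:
            shape = a.shape
        elif a.shape != shape:
            raise ValueError(
                f"shape mismatch: {p} is {a.shape}, expected {shape}")
        channels[modality] = a
    return SliceStack(channels=channels, label=label, case_id=case_id,
                      pixel_spacing=pixel_spacing)


def write_slice_png(img: np.ndarray, path) -> None:
    a = np.clip(np.asarray(img, dtype=float), 0, 1)
    Image.fromarray((a * 255).round().astype(np.uint8)).save(path)


def write_slice_nifti(img: np.ndarray, path, pixel_spacing: float = 0.5) -> None:
    """Single-slice NIfTI volume (1 x H x W) with the pixel spacing in the
    affine."""
    a = np.asarray(img, dtype=float)[None]
    affine = np.diag([1.0, pixel_spacing, pixel_spacing, 1.0])
    nib.save(nib.Nifti1Image(a, affine), str(path))


def write_cohort(cohort: Cohort, out_dir, fmt: str = "png",
                 params: dict | None = None) -> Path:
    """Write one image per modality per case plus a ``cohort.csv`` manifest
    and a JSON sidecar of generator parameters; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cohort.cases:
        row = {"case_id": case.case_id, "label": case.label,
               "seed": case.meta.get("rng_seed", ""),
               "pixel_spacing": case.pixel_spacing}
        for modality, img in case.channels.items():
            if fmt == "nifti":
                fname = f"{case.case_id}_{modality}.nii.gz"
                write_slice_nifti(img, out / fname, case.pixel_spacing)
            else:
                fname = f"{case.case_id}_{modality}.png"
                write_slice_png(img, out / fname)
            row[f"path_{modality}"] = fname
        rows.append(row)
    manifest = out / "cohort.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    sidecar = {"seed": cohort.seed, "class_counts": cohort.class_counts,
               "format": fmt}
    if params:
        sidecar["generator_params"] = params
    (out / "cohort_params.json").write_text(json.dumps(sidecar, indent=2))
    return manifest


def read_cohort(manifest_path) -> Cohort:
    """Rebuild a cohort from a manifest written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    cases = []
    for _, row in df.iterrows():
        paths = {c[len("path_"):]: base / row[c]
                 for c in df.columns if c.startswith("path_")}
        case = read_case(paths, label=row["label"], case_id=row["case_id"],
                         pixel_spacing=float(row.get("pixel_spacing", 0.5)))
        cases.append(case)
    counts = df["label"].value_counts().to_dict()
    params = {}
    sidecar = base / "cohort_params.json"
    if sidecar.exists():
        params = json.loads(sidecar.read_text())
    return Cohort(cases=cases, class_counts=counts,
                  seed=int(params.get("seed", 0)))


def write_features(X: np.ndarray, labels, case_ids, out_csv,
                   spans: dict | None = None) -> None:
    """Feature matrix as CSV (case_id, label, f0000..) plus a ``spans.json``
    manifest of the block column spans next to it."""
    X = np.asarray(X)
    cols = [f"f{j:04d}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "label", list(labels))
    df.insert(0, "case_id", list(case_ids))
    out_csv = Path(out_csv)
    df.to_csv(out_csv, index=False)
    spans = spans if spans is not None else dict(BLOCK_SPANS)
    (out_csv.parent / "spans.json").write_text(
        json.dumps({k: list(v) for k, v in spans.items()}, indent=2))


def read_features(csv_path):
    """-> (X, labels, case_ids, spans)."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    feature_cols = [c for c in df.columns if c.startswith("f")]
    X = df[feature_cols].to_numpy(dtype=float)
    spans_file = csv_path.parent / "spans.json"
    spans = ({k: tuple(v) for k, v in json.loads(spans_file.read_text()).items()}
             if spans_file.exists() else None)
    return X, df["label"].to_numpy(), df["case_id"].to_numpy(), spans
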