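"""End-to-end orchestration: simulate -> featurize -> split -> select ->
train -> evaluate -> ablate, with every artifact written under one run
directory together with the resolved configuration and seed.

A rerun from the same config produces identical metric artifacts; with
``resume=True`` stages whose artifacts already exist are skipped, and a
regenerated artifact is identical to the deleted one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import classify, io, lyrebird
from .config import RunConfig, save_config
from .features import BLOCK_SPANS, featurize_cohort
from .phantom import DEFAULT_PROFILES, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_all"]

ARTIFACTS = ("cohort.csv", "features.csv", "split.json", "mask.json",
             "model.json", "report.json", "ablation.json")


def _stage(name):
    def wrap(fn):
        def inner(ctx, *a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(ctx, *a, **kw)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_all(cfg: RunConfig, out_dir, resume: bool = False) -> Path:
    """Run the whole pipeline; returns the run directory.

    Refuses to overwrite an existing non-empty run directory unless
    ``resume`` is set, in which case stages with existing artifacts are
    skipped.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not resume:
        raise FileExistsError(
            f"run directory {out} already exists; pass resume=True (or pick "
            "a fresh directory) to continue into it")
    out.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out / "config.yaml")

    # -- simulate ----------------------------------------------------------
    cohort_csv = out / "cohort.csv"
    if resume and cohort_csv.exists():
        cohort = io.read_cohort(cohort_csv)
        logger.info("stage simulate   skipped (cohort.csv exists)")
    else:
        cohort = _simulate({"cfg": cfg})
        io.write_cohort(cohort, out, params={
            "counts": cfg.cohort.counts, "size": cfg.cohort.size,
            "noise_sigma": cfg.cohort.noise_sigma})

    # -- featurize ---------------------------------------------------------
    feat_csv = out / "features.csv"
    if resume and feat_csv.exists():
        X, y, case_ids, spans = io.read_features(feat_csv)
        logger.info("stage featurize  skipped (features.csv exists)")
    else:
        X, y = _featurize({"cfg": cfg, "cohort": cohort})
        case_ids = [c.case_id for c in cohort.cases]
        spans = dict(BLOCK_SPANS)
        io.write_features(X, y, case_ids, feat_csv, spans)

    # -- split -------------------------------------------------------------
    plan = classify.split_dataset(y, fractions=cfg.split_fractions,
                                  seed=cfg.seed)
    _write_json(out / "split.json", {
        "train": plan.train_idx.tolist(), "val": plan.val_idx.tolist(),
        "test": plan.test_idx.tolist(), "seed": cfg.seed,
        "fractions": list(cfg.split_fractions)})

    # -- select ------------------------------------------------------------
    dev = np.concatenate([plan.train_idx, plan.val_idx])
    best, history = _select({"cfg": cfg}, X[dev], y[dev])
    _write_json(out / "mask.json", {
        "bits": best.mask.bits.tolist(),
        "n_selected": best.mask.n_selected,
        "fitness": best.mean_accuracy,
        "cv_accuracies": best.cv_accuracies.tolist(),
        "history": history})

    # -- train -------------------------------------------------------------
    Xsel_dev = lyrebird.apply_mask(X[dev], best.mask)
    rf_cfg = dataclasses.replace(cfg.rf, seed=cfg.seed)
    model = _train({"cfg": cfg}, Xsel_dev, y[dev], rf_cfg)
    Xsel_test = lyrebird.apply_mask(X[plan.test_idx], best.mask)
    prob = model.predict_proba(Xsel_test)
    pred = model.classes_[np.argmax(prob, axis=1)]
    fingerprint = hashlib.sha256(
        np.ascontiguousarray(prob).tobytes()).hexdigest()
    _write_json(out / "model.json", {
        "rf": dataclasses.asdict(rf_cfg),
        "n_features_selected": best.mask.n_selected,
        "classes": [str(c) for c in model.classes_],
        "test_prediction_sha256": fingerprint})

    # -- evaluate ----------------------------------------------------------
    report = _evaluate({"cfg": cfg}, y[plan.test_idx], pred, prob,
                       list(model.classes_))
    _write_json(out / "report.json", report.as_dict())
    (out / "report.md").write_text(_markdown_report(report))
    np.savetxt(out / "confusion.csv", report.confusion, fmt="%d", delimiter=",")

    # -- ablate ------------------------------------------------------------
    ablation = _ablate({"cfg": cfg}, X, y, spans)
    _write_json(out / "ablation.json",
                {name: rep.as_dict() for name, rep in ablation.items()})
    return out


@_stage("simulate")
def _simulate(ctx):
    cfg = ctx["cfg"]
    profiles = {k: DEFAULT_PROFILES[k] for k in cfg.cohort.counts}
    return generate_cohort(profiles, cfg.cohort.counts, base_seed=cfg.seed,
                           size=cfg.cohort.size,
                           modalities=cfg.cohort.modalities,
                           noise_sigma=cfg.cohort.noise_sigma)


@_stage("featurize")
def _featurize(ctx):
    cfg = ctx["cfg"]
    return featurize_cohort(ctx["cohort"], modality=cfg.modality,
                            backbone=cfg.backbone, roi_cfg=cfg.roi)


@_stage("select")
def _select(ctx, X, y):
    cfg = ctx["cfg"]
    loa_cfg = dataclasses.replace(cfg.loa, seed=cfg.seed)
    rf_cfg = dataclasses.replace(cfg.rf, seed=cfg.seed)
    return lyrebird.loa_select(X, y, loa_cfg, rf_cfg, k=cfg.cv_folds)


@_stage("train")
def _train(ctx, X, y, rf_cfg):
    return classify.train_rf(X, y, rf_cfg)


@_stage("evaluate")
def _evaluate(ctx, y_true, pred, prob, classes):
    cfg = ctx["cfg"]
    return classify.evaluate_predictions(
        y_true, pred, prob, n_bootstrap=cfg.n_bootstrap, seed=cfg.seed,
        classes=classes)


@_stage("ablate")
def _ablate(ctx, X, y, spans):
    cfg = ctx["cfg"]
    loa_cfg = dataclasses.replace(cfg.loa, seed=cfg.seed)
    rf_cfg = dataclasses.replace(cfg.rf, seed=cfg.seed)
    return classify.run_ablation(
        X, y, spans, rf_cfg=rf_cfg, loa_cfg=loa_cfg, seed=cfg.seed,
        n_bootstrap=min(cfg.n_bootstrap, 200),
        fractions=cfg.split_fractions)


def _markdown_report(report) -> str:
    lines = ["# Evaluation report", "",
             "Class-wise metrics are macro one-vs-rest averages; CIs are "
             f"95% percentile bootstrap over {report.n_bootstrap} "
             "case-level resamples.", "",
             "| metric | estimate | 95% CI |", "|---|---|---|"]
    for m, v in report.estimates.items():
        lo, hi = report.cis[m]
        lines.append(f"| {m} | {v:.4f} | [{lo:.4f}, {hi:.4f}] |")
    lines += ["", "Confusion matrix (rows = true, cols = predicted; classes "
              f"{', '.join(map(str, report.classes))}):", ""]
    for row in report.confusion:
        lines.append("    " + "  ".join(f"{v:4d}" for v in row))
    return "\n".join(lines) + "\n"
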