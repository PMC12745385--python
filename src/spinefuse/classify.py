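"""Random-Forest classification, dataset splitting, metrics and ablations.

The final classifier is a Random Forest with 100 trees, maximum depth 20,
Gini impurity splits and balanced (inverse-frequency) class weights — a
configuration chosen for robustness and interpretability on small cohorts.

The cohort is split 70% / 15% / 15% (train / validation / held-out test),
stratified by class; model development may additionally use stratified
k-fold cross-validation inside the training portion.  The metric panel is
accuracy, sensitivity (macro recall), specificity (macro one-vs-rest true
negative rate), macro one-vs-rest AUC and macro F1, each with a 95%
percentile-bootstrap confidence interval over case-level resamples
(1,000 iterations by default).  For the 3-class problem all class-wise
metrics are macro one-vs-rest averages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "RFConfig",
    "SplitPlan",
    "EvalReport",
    "METRIC_NAMES",
    "split_dataset",
    "train_rf",
    "compute_metrics",
    "bootstrap_ci",
    "evaluate_predictions",
    "crossval",
    "run_ablation",
    "ABLATION_VARIANTS",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "auc", "f1")


@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 100
    max_depth: int = 20
    split_criterion: str = "gini"
    class_weighting: str = "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class SplitPlan:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    fractions: tuple = (0.70, 0.15, 0.15)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        parts = [np.asarray(p) for p in (self.train_idx, self.val_idx, self.test_idx)]
        n = sum(len(p) for p in parts)
        union = np.concatenate(parts)
        if len(np.unique(union)) != n:
            raise ValueError("split parts overlap")

    @property
    def sizes(self) -> tuple:
        return (len(self.train_idx), len(self.val_idx), len(self.test_idx))


@dataclass
class EvalReport:
    """Per-metric point estimates with 95% bootstrap CIs plus the raw
    confusion matrix; optionally a per-fold table."""

    estimates: dict
    cis: dict
    confusion: np.ndarray
    classes: list
    n_bootstrap: int = 1000
    folds: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "metrics": {
                m: {"estimate": self.estimates[m],
                    "ci_low": self.cis[m][0], "ci_high": self.cis[m][1]}
                for m in self.estimates
            },
            "confusion": self.confusion.tolist(),
            "classes": list(map(str, self.classes)),
            "n_bootstrap": self.n_bootstrap,
            "folds": self.folds,
        }


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing to ``total`` with floors + largest
    fractional remainders."""
    floors = np.floor(targets).astype(int)
    short = total - floors.sum()
    order = np.argsort(-(targets - floors), kind="stable")
    out = floors.copy()
    out[order[:short]] += 1
    return out


def split_dataset(labels, fractions=(0.70, 0.15, 0.15), seed: int = 0) -> SplitPlan:
    """Stratified train/validation/test split.

    Overall sizes are ``round(f_train * n)``, ``round(f_val * n)`` and the
    remainder, allocated across classes by largest remainder so per-class
    proportions stay within one case of the targets.  Deterministic per
    seed.
    """
    y = np.asarray(labels)
    n = len(y)
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 3).any():
        bad = classes[counts < 3][0]
        raise ValueError(f"class {bad!r} has fewer than 3 members")
    f_train, f_val, _ = fractions

    n_train = int(round(f_train * n))
    n_val = int(round(f_val * n))
    train_c = _largest_remainder(f_train * counts, n_train)
    val_c = _largest_remainder(f_val * counts, n_val)
    if ((train_c + val_c) > counts).any():
        raise ValueError("split fractions leave a class without test cases")

    rng = np.random.default_rng(seed)
    tr, va, te = [], [], []
    for cls, ntr, nva in zip(classes, train_c, val_c):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        tr.append(idx[:ntr])
        va.append(idx[ntr:ntr + nva])
        te.append(idx[ntr + nva:])
    return SplitPlan(np.sort(np.concatenate(tr)), np.sort(np.concatenate(va)),
                     np.sort(np.concatenate(te)), fractions=tuple(fractions),
                     seed=seed)


# ---------------------------------------------------------------------------
# forest
# ---------------------------------------------------------------------------

def train_rf(X, y, cfg: RFConfig = RFConfig()) -> RandomForestClassifier:
    """Fit the configured forest; requires at least two classes present."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        criterion=cfg.split_criterion,
        class_weight=cfg.class_weighting,
        random_state=cfg.seed,
        n_jobs=1,
    )
    model.fit(np.asarray(X), y)
    return model


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _confusion(y_true, y_pred, classes) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    return cm


def compute_metrics(y_true, y_pred, y_prob=None, classes=None) -> dict:
    """Metric panel from predictions.

    accuracy: fraction correct; sensitivity: macro-averaged per-class
    recall; specificity: macro-averaged per-class one-vs-rest TN/(TN+FP);
    f1: macro-averaged per-class F1; auc: macro one-vs-rest ROC AUC from
    ``y_prob`` (omitted when probabilities are not given).  Classes absent
    from ``y_true`` are excluded from the macro averages with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch between y_true and y_pred")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = list(classes)
    cm = _confusion(y_true, y_pred, classes)
    support = cm.sum(axis=1)
    present = support > 0
    if not present.all():
        missing = [c for c, p in zip(classes, present) if not p]
        logger.warning("classes absent from y_true excluded from macro "
                       "averages: %s", missing)

    n = cm.sum()
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = n - tp - fn - fp

    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        spec = np.where(tn + fp > 0, tn / (tn + fp), 0.0)
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        f1 = np.where(prec + recall > 0, 2 * prec * recall / (prec + recall), 0.0)

    out = {
        "accuracy": float(tp.sum() / n) if n else 0.0,
        "sensitivity": float(recall[present].mean()),
        "specificity": float(spec[present].mean()),
        "f1": float(f1[present].mean()),
    }
    if y_prob is not None:
        y_prob = np.asarray(y_prob, dtype=float)
        cols = [i for i, p in enumerate(present) if p]
        true_present = np.asarray(y_true)
        if len(cols) < 2:
            out["auc"] = 0.0
        elif len(cols) == 2:
            pos = classes[cols[1]]
            out["auc"] = float(roc_auc_score(
                (true_present == pos).astype(int), y_prob[:, cols[1]]))
        else:
            sub = y_prob[:, cols]
            sub = sub / sub.sum(axis=1, keepdims=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out["auc"] = float(roc_auc_score(
                    y_true, sub, multi_class="ovr", average="macro",
                    labels=[classes[i] for i in cols]))
    return out


def bootstrap_ci(metric: str, y_true, y_pred, y_prob=None, B: int = 1000,
                 seed: int = 0, classes=None) -> tuple:
    """95% percentile bootstrap interval over case-level resamples.

    Resamples are drawn with replacement at case level; a resample
    containing a single true class is redrawn (logged at debug level).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = list(np.unique(np.concatenate([y_true, y_pred])))
    rng = np.random.default_rng(seed)
    n = len(y_true)
    vals = np.empty(B)
    # inside resamples a class may legitimately drop out of y_true; that is
    # expected here, so silence the per-resample exclusion warnings
    level = logger.level
    logger.setLevel(logging.ERROR)
    try:
        for b in range(B):
            for _ in range(100):
                idx = rng.integers(0, n, n)
                if len(np.unique(y_true[idx])) > 1:
                    break
            prob = y_prob[idx] if y_prob is not None else None
            vals[b] = compute_metrics(y_true[idx], y_pred[idx], prob,
                                      classes=classes)[metric]
    finally:
        logger.setLevel(level)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def evaluate_predictions(y_true, y_pred, y_prob=None, n_bootstrap: int = 1000,
                         seed: int = 0, classes=None) -> EvalReport:
    """Full panel: point estimates, bootstrap CIs and the confusion matrix."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = list(np.unique(np.concatenate([y_true, y_pred])))
    est = compute_metrics(y_true, y_pred, y_prob, classes=classes)
    cis = {m: bootstrap_ci(m, y_true, y_pred, y_prob, B=n_bootstrap,
                           seed=seed, classes=classes)
           for m in est}
    return EvalReport(estimates=est, cis=cis,
                      confusion=_confusion(y_true, y_pred, classes),
                      classes=classes, n_bootstrap=n_bootstrap)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def crossval(X, y, rf_cfg: RFConfig = RFConfig(), k: int = 5, seed: int = 0,
             selector=None):
    """Stratified k-fold cross-validation of the forest.

    ``selector``, when given, is called as ``selector(X_train, y_train,
    fold_seed) -> mask`` inside each training fold only, and the returned
    boolean/0-1 column mask is applied to both the training and evaluation
    folds — selection never sees evaluation labels.  Returns (per-fold
    metric dicts, summary mean/sd dict).
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if k == len(y):  # leave-one-out boundary: stratification is impossible
        from sklearn.model_selection import KFold
        splitter = KFold(n_splits=k)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(splitter.split(X, y)):
        Xtr, Xte = X[tr], X[te]
        if selector is not None:
            bits = np.asarray(selector(Xtr, y[tr], seed * 1000 + fold)).astype(bool)
            if bits.sum() == 0:
                raise ValueError("selector returned an empty mask")
            Xtr, Xte = Xtr[:, bits], Xte[:, bits]
        model = train_rf(Xtr, y[tr], rf_cfg)
        prob = model.predict_proba(Xte)
        pred = model.classes_[np.argmax(prob, axis=1)]
        m = compute_metrics(y[te], pred, prob, classes=list(model.classes_))
        m["fold"] = fold
        rows.append(m)
    summary = {}
    for name in rows[0]:
        if name == "fold":
            continue
        vals = np.array([r[name] for r in rows])
        summary[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))
                         if len(vals) > 1 else 0.0}
    return rows, summary


# ---------------------------------------------------------------------------
# ablation
# ---------------------------------------------------------------------------

ABLATION_VARIANTS = (
    "sift->rf",
    "deep->rf",
    "sift+deep->rf",
    "deep->lo-rf",
    "sift+deep->lo-rf",
)


def run_ablation(X, y, block_spans, rf_cfg: RFConfig = RFConfig(),
                 loa_cfg=None, seed: int = 0, n_bootstrap: int = 200,
                 fractions=(0.70, 0.15, 0.15)):
    """Evaluate the five architecture variants under one shared split.

    Variants: handcrafted block only -> RF; deep block only -> RF; fused ->
    RF; deep -> wrapper-selected RF; fused -> wrapper-selected RF (the full
    pipeline).  Wrapper selection runs on the training portion only; every
    variant is scored on the shared held-out test portion with the full
    metric panel.  Returns an ordered mapping variant -> EvalReport.
    """
    from .lyrebird import LOAConfig, apply_mask, loa_select

    X = np.asarray(X)
    y = np.asarray(y)
    if not {"sift", "deep"} <= set(block_spans):
        raise ValueError("block_spans must define 'sift' and 'deep'")
    if loa_cfg is None:
        loa_cfg = LOAConfig(population_size=8, iterations=5, seed=seed)

    plan = split_dataset(y, fractions=fractions, seed=seed)
    tr = np.concatenate([plan.train_idx, plan.val_idx])  # selection + fitting
    te = plan.test_idx

    def cols(kinds):
        pieces = [np.arange(*block_spans[k]) for k in kinds]
        return np.concatenate(pieces)

    variants = {
        "sift->rf": (cols(["sift"]), False),
        "deep->rf": (cols(["deep"]), False),
        "sift+deep->rf": (cols(["sift", "deep"]), False),
        "deep->lo-rf": (cols(["deep"]), True),
        "sift+deep->lo-rf": (cols(["sift", "deep"]), True),
    }

    out = {}
    for name, (columns, use_selector) in variants.items():
        Xtr, Xte = X[np.ix_(tr, columns)], X[np.ix_(te, columns)]
        if use_selector:
            import dataclasses as _dc
            best, _ = loa_select(Xtr, y[tr], _dc.replace(loa_cfg, seed=loa_cfg.seed),
                                 rf_cfg)
            Xtr = apply_mask(Xtr, best.mask)
            Xte = apply_mask(Xte, best.mask)
        model = train_rf(Xtr, y[tr], rf_cfg)
        prob = model.predict_proba(Xte)
        pred = model.classes_[np.argmax(prob, axis=1)]
        out[name] = evaluate_predictions(y[te], pred, prob,
                                         n_bootstrap=n_bootstrap, seed=seed,
                                         classes=list(model.classes_))
    return out
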