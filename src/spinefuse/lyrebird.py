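"""Wrapper-based binary feature selection (lyrebird-style metaheuristic).

Each candidate solution is a binary mask over feature columns; its fitness
is the stratified 5-fold cross-validated accuracy of a Random Forest
trained on the selected columns only.  The search alternates two moves per
individual per iteration, echoing the lyrebird's escape/hide behaviour:

* ESCAPE (exploration): each bit is, with probability 1/2, copied from a
  fitter randomly chosen member of the population, then every bit is
  flipped independently with probability ``flip_rate``;
* HIDE (exploitation): a Binomial(D, flip_rate) number of the individual's
  own bits (at least one) is flipped.

Moves are accepted greedily (kept only if fitness does not decrease), the
escape probability decays linearly over iterations, and elitism keeps the
best masks, so the best-so-far fitness trace is monotone non-decreasing.
Fitness evaluations are cached by mask bits — caching changes no results,
it only avoids refitting forests.

``exhaustive_select`` enumerates every non-empty mask (D <= 12) and serves
as the independent optimum oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classify import RFConfig, train_rf

__all__ = [
    "SelectionMask",
    "LOAConfig",
    "FitnessRecord",
    "FitnessEvaluator",
    "fitness",
    "loa_select",
    "exhaustive_select",
    "apply_mask",
]


@dataclass
class SelectionMask:
    bits: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits).astype(np.int8)
        if self.bits.ndim != 1:
            raise ValueError("bits must be a 1-D binary vector")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")
        if self.fitness is not None and not 0 <= self.fitness <= 1:
            raise ValueError("fitness must be in [0, 1]")

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    def key(self) -> bytes:
        return self.bits.tobytes()


@dataclass(frozen=True)
class LOAConfig:
    """Search budget and operator settings.

    ``p_escape`` is the per-individual probability of the exploration phase
    at iteration 0, decaying linearly to ``p_escape_final``; ``flip_rate``
    defaults to 2/D (expected two bits perturbed), with a floor of one
    flipped bit in the exploitation move.
    """

    population_size: int = 30
    iterations: int = 50
    p_escape: float = 0.5
    p_escape_final: float = 0.1
    flip_rate: float | None = None   # None -> 2/D
    elitism: int = 1
    seed: int = 0
    empty_mask_fitness: float = 0.0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        for p in (self.p_escape, self.p_escape_final):
            if not 0 <= p <= 1:
                raise ValueError("escape probabilities must be in [0, 1]")
        if self.elitism < 0:
            raise ValueError("elitism must be >= 0")


@dataclass
class FitnessRecord:
    mask: SelectionMask
    cv_accuracies: np.ndarray
    mean_accuracy: float
    evaluations_used: int = 0

    def __post_init__(self) -> None:
        self.cv_accuracies = np.asarray(self.cv_accuracies, dtype=float)
        if not np.isclose(self.mean_accuracy, self.cv_accuracies.mean()):
            raise ValueError("mean_accuracy must equal mean(cv_accuracies)")


class FitnessEvaluator:
    """Cached stratified-CV fitness of selection masks.

    Deterministic: the fold assignment and forest seed are fixed at
    construction, so the same mask always scores identically within one
    evaluator.  ``evaluations`` counts distinct forests actually trained
    (cache hits and the empty mask cost nothing).
    """

    def __init__(self, X, y, rf_cfg: RFConfig = RFConfig(), k: int = 5,
                 seed: int = 0, empty_mask_fitness: float = 0.0):
        self.X = np.asarray(X)
        self.y = np.asarray(y)
        if len(self.X) < k:
            raise ValueError(f"need at least k={k} cases")
        classes, counts = np.unique(self.y, return_counts=True)
        if (counts < k).any():
            bad = classes[counts < k][0]
            raise ValueError(
                f"class {bad!r} has fewer than k={k} members; "
                "stratified folds are impossible")
        self.rf_cfg = replace(rf_cfg, seed=seed)
        self.k = k
        self.seed = seed
        self.empty_mask_fitness = empty_mask_fitness
        self._folds = list(StratifiedKFold(
            n_splits=k, shuffle=True, random_state=seed).split(self.X, self.y))
        self._cache: dict[bytes, FitnessRecord] = {}
        self.evaluations = 0

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def __call__(self, mask: SelectionMask) -> FitnessRecord:
        key = mask.key()
        if key in self._cache:
            return self._cache[key]
        if mask.n_selected == 0:
            rec = FitnessRecord(
                mask=SelectionMask(mask.bits, self.empty_mask_fitness),
                cv_accuracies=np.full(self.k, self.empty_mask_fitness),
                mean_accuracy=self.empty_mask_fitness,
                evaluations_used=self.evaluations)
            self._cache[key] = rec
            return rec
        cols = mask.bits.astype(bool)
        accs = np.empty(self.k)
        for i, (tr, te) in enumerate(self._folds):
            model = train_rf(self.X[np.ix_(tr, np.flatnonzero(cols))],
                             self.y[tr], self.rf_cfg)
            pred = model.predict(self.X[np.ix_(te, np.flatnonzero(cols))])
            accs[i] = float(np.mean(pred == self.y[te]))
            self.evaluations += 1
        rec = FitnessRecord(mask=SelectionMask(mask.bits, float(accs.mean())),
                            cv_accuracies=accs,
                            mean_accuracy=float(accs.mean()),
                            evaluations_used=self.evaluations)
        self._cache[key] = rec
        return rec


def fitness(mask: SelectionMask, X, y, rf_cfg: RFConfig = RFConfig(),
            k: int = 5, seed: int = 0,
            empty_mask_fitness: float = 0.0) -> FitnessRecord:
    """One-shot cached-free fitness call (see :class:`FitnessEvaluator`)."""
    ev = FitnessEvaluator(X, y, rf_cfg, k=k, seed=seed,
                          empty_mask_fitness=empty_mask_fitness)
    return ev(mask)


def _better(a: FitnessRecord, b: FitnessRecord) -> bool:
    """True when a strictly beats b: higher fitness, then fewer selected
    features, then lexicographically smaller bits."""
    if a.mean_accuracy != b.mean_accuracy:
        return a.mean_accuracy > b.mean_accuracy
    if a.mask.n_selected != b.mask.n_selected:
        return a.mask.n_selected < b.mask.n_selected
    return tuple(a.mask.bits) < tuple(b.mask.bits)


def loa_select(X, y, cfg: LOAConfig = LOAConfig(),
               rf_cfg: RFConfig = RFConfig(), k: int = 5):
    """Run the two-phase binary search; returns (best record, history).

    The population starts as Bernoulli(1/2) masks with one individual
    forced to all-ones (the unselected baseline is always reachable), and
    ``history`` records the best-so-far fitness after each iteration.
    """
    X = np.asarray(X)
    D = X.shape[1]
    if D < 1:
        raise ValueError("need at least one feature column")
    rng = np.random.default_rng(cfg.seed)
    flip_rate = cfg.flip_rate if cfg.flip_rate is not None else min(1.0, 2.0 / D)
    ev = FitnessEvaluator(X, y, rf_cfg, k=k, seed=cfg.seed,
                          empty_mask_fitness=cfg.empty_mask_fitness)

    pop_bits = (rng.random((cfg.population_size, D)) < 0.5).astype(np.int8)
    pop_bits[0] = 1
    pop = [ev(SelectionMask(b)) for b in pop_bits]
    best = max(pop, key=lambda r: (r.mean_accuracy, -r.mask.n_selected))
    for r in pop:
        if _better(r, best):
            best = r

    history = []
    for it in range(cfg.iterations):
        frac = it / max(1, cfg.iterations - 1)
        p_escape = cfg.p_escape + frac * (cfg.p_escape_final - cfg.p_escape)
        fits = np.array([r.mean_accuracy for r in pop])
        order = np.argsort(-fits, kind="stable")
        elite = set(order[:cfg.elitism].tolist())

        for i in range(cfg.population_size):
            cur = pop[i]
            bits = cur.mask.bits.copy()
            if rng.random() < p_escape:  # ESCAPE: learn from a fitter member
                fitter = np.flatnonzero(fits > fits[i])
                guide = (pop[int(rng.choice(fitter))] if fitter.size
                         else best).mask.bits
                take = rng.random(D) < 0.5
                bits[take] = guide[take]
                flips = rng.random(D) < flip_rate
                bits[flips] = 1 - bits[flips]
            else:                        # HIDE: perturb its own mask
                n_flip = max(1, int(rng.binomial(D, flip_rate)))
                pos = rng.choice(D, size=min(n_flip, D), replace=False)
                bits[pos] = 1 - bits[pos]
            cand = ev(SelectionMask(bits))
            if i in elite and not _better(cand, cur):
                continue  # elitism: elite masks only ever improve
            if cand.mean_accuracy >= cur.mean_accuracy:  # greedy acceptance
                pop[i] = cand
                fits[i] = cand.mean_accuracy
                if _better(cand, best):
                    best = cand
        history.append(best.mean_accuracy)
    return best, history


def exhaustive_select(X, y, rf_cfg: RFConfig = RFConfig(), k: int = 5,
                      seed: int = 0):
    """Evaluate every non-empty mask (2^D - 1 of them; refuses D > 12) and
    return the argmax record; ties prefer fewer selected features, then
    lexicographically smallest bits.  The fitness evaluator is identical to
    the one the metaheuristic uses, so its optimum is a true upper bound."""
    X = np.asarray(X)
    D = X.shape[1]
    if D > 12:
        raise ValueError("exhaustive search refuses D > 12")
    ev = FitnessEvaluator(X, y, rf_cfg, k=k, seed=seed)
    best = None
    for code in range(1, 2**D):
        bits = np.array([(code >> j) & 1 for j in range(D)], dtype=np.int8)
        rec = ev(SelectionMask(bits))
        if best is None or _better(rec, best):
            best = rec
    best.evaluations_used = ev.evaluations  # (2^D - 1) * k forest fits
    return best


def apply_mask(X, mask: SelectionMask) -> np.ndarray:
    """Column subset of X selected by the mask, ascending column order."""
    X = np.asarray(X)
    if mask.bits.size != X.shape[1]:
        raise ValueError(f"mask length {mask.bits.size} != n columns {X.shape[1]}")
    if mask.n_selected == 0:
        raise ValueError("cannot apply an empty mask")
    return X[:, mask.bits.astype(bool)]
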