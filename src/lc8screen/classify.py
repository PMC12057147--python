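"""Composite-threshold binder classification and GA threshold training.

A window is called a binder when its linked 10-parameter score vector
passes *all ten* cuts simultaneously (strict inequalities): confidence and
interface pLDDT must exceed their cuts, the three PAE scores must fall
below theirs, for both the 1-client and the 2-client run.  Two cut sets
ship as defaults: an *exclusive* set tuned for a low false-positive rate
(for discovering new binders) and an *inclusive* set tuned for a low
false-negative rate (for exhaustively mapping sites in known binders).

Retraining uses a genetic algorithm.  Every threshold set evaluated during
the search contributes one (FPR, TPR) point to an archive; the reported
ROC is the Pareto frontier of that archive and its area is computed with
the conservative lower staircase, so the AUROC is a lower bound of the
attainable one.  Because the initial archive is seeded with the exhaustive
single-parameter ROC of every parameter, the composite frontier AUROC can
never fall below the best single-parameter AUROC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .interface import PARAM_NAMES, ScoreVector

__all__ = [
    "PARAM_DIRECTIONS",
    "ThresholdSet",
    "EXCLUSIVE",
    "INCLUSIVE",
    "RocCurve",
    "classify",
    "evaluate",
    "single_param_roc",
    "train_composite",
    "learning_curve",
    "FixedThresholdClassifier",
    "GAThresholdClassifier",
    "vectors_to_frame",
]

#: Comparison direction per parameter: confidence/pLDDT must exceed the
#: cut (">"), PAE scores must fall below it ("<").  Fixed by semantics.
PARAM_DIRECTIONS: dict[str, str] = {
    p: (">" if p.startswith(("conf", "plddt")) else "<") for p in PARAM_NAMES
}

_GE_MASK = np.array([PARAM_DIRECTIONS[p] == ">" for p in PARAM_NAMES])


@dataclass(frozen=True)
class ThresholdSet:
    """Ten named cut values with fixed comparison directions."""

    cuts: Mapping[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = [p for p in PARAM_NAMES if p not in self.cuts]
        extra = [p for p in self.cuts if p not in PARAM_NAMES]
        if missing or extra:
            raise ValueError(f"threshold set must cover exactly {PARAM_NAMES}; "
                             f"missing {missing}, extra {extra}")
        object.__setattr__(self, "cuts", dict(self.cuts))

    def as_array(self) -> np.ndarray:
        return np.array([self.cuts[p] for p in PARAM_NAMES], dtype=float)

    def to_json(self, path: str | Path) -> Path:
        doc = {
            "name": self.name,
            "parameters": [
                {"parameter": p, "cut": self.cuts[p],
                 "direction": PARAM_DIRECTIONS[p]}
                for p in PARAM_NAMES
            ],
        }
        path = Path(path)
        path.write_text(json.dumps(doc, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdSet":
        doc = json.loads(Path(path).read_text())
        return cls({e["parameter"]: e["cut"] for e in doc["parameters"]},
                   name=doc.get("name", "custom"))


#: Low-false-positive default cuts.
EXCLUSIVE = ThresholdSet(
    {
        "conf_2c": 0.78, "plddt_2c": 95.4, "ltop_2c": 4.97,
        "ptol_2c": 9.03, "dimer_2c": 0.922,
        "conf_1c": 0.88, "plddt_1c": 34.8, "ltop_1c": 8.14,
        "ptol_1c": 10.99, "dimer_1c": 1.158,
    },
    name="exclusive",
)

#: Low-false-negative default cuts.
INCLUSIVE = ThresholdSet(
    {
        "conf_2c": 0.62, "plddt_2c": 69.4, "ltop_2c": 4.80,
        "ptol_2c": 3.35, "dimer_2c": 1.103,
        "conf_1c": 0.77, "plddt_1c": 35.4, "ltop_1c": 11.30,
        "ptol_1c": 13.73, "dimer_1c": 1.249,
    },
    name="inclusive",
)

_NAMED_SETS = {"exclusive": EXCLUSIVE, "inclusive": INCLUSIVE}


def _as_matrix(X) -> np.ndarray:
    """Coerce vectors / DataFrame / array into an (n, 10) float matrix."""
    if isinstance(X, pd.DataFrame):
        return X[PARAM_NAMES].to_numpy(dtype=float)
    if isinstance(X, (list, tuple)) and X and isinstance(X[0], ScoreVector):
        return np.stack([v.as_array() for v in X])
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(PARAM_NAMES):
        raise ValueError(f"expected {len(PARAM_NAMES)} parameters, got {X.shape[1]}")
    return X


def _predict_matrix(X: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """Conjunction of all ten strict comparisons; True = binder."""
    passed = np.where(_GE_MASK, X > cuts, X < cuts)
    return passed.all(axis=1)


def vectors_to_frame(vectors: Sequence[ScoreVector]) -> pd.DataFrame:
    """Flatten ScoreVectors into a DataFrame with one column per parameter."""
    rows = []
    for v in vectors:
        row = {"protein_id": v.window.protein_id, "start": v.window.start,
               "end": v.window.end, "is_mutant": v.window.is_mutant,
               "label": v.label}
        row.update(v.values)
        rows.append(row)
    return pd.DataFrame(rows)


def _labels_to_bool(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "bi":
        return y.astype(bool)
    out = np.empty(len(y), dtype=bool)
    for i, lab in enumerate(y):
        if lab == "binder":
            out[i] = True
        elif lab == "nonbinder":
            out[i] = False
        else:
            raise ValueError(f"unlabeled vector: {lab!r}")
    return out


def classify(v: ScoreVector | Mapping[str, float], t: ThresholdSet) -> str:
    """Classify one vector: ``"binder"`` iff all ten conditions hold."""
    if isinstance(v, ScoreVector):
        values = v.values
    else:
        missing = [p for p in PARAM_NAMES if p not in v]
        if missing:
            raise ValueError(f"missing parameters: {missing}")
        values = v
    x = np.array([values[p] for p in PARAM_NAMES], dtype=float)
    return "binder" if _predict_matrix(x[None, :], t.as_array())[0] else "nonbinder"


def evaluate(vectors, t: ThresholdSet, y=None) -> dict:
    """Confusion counts and error rates of a threshold set on labeled data."""
    X = _as_matrix(vectors)
    if y is None:
        if not (isinstance(vectors, (list, tuple)) and vectors
                and isinstance(vectors[0], ScoreVector)):
            raise ValueError("labels required")
        y = [v.label for v in vectors]
    yb = _labels_to_bool(y)
    if X.shape[0] == 0:
        raise ValueError("empty evaluation set")
    pred = _predict_matrix(X, t.as_array())
    tp = int((pred & yb).sum())
    fp = int((pred & ~yb).sum())
    tn = int((~pred & ~yb).sum())
    fn = int((~pred & yb).sum())
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "fpr": fp / (fp + tn) if (fp + tn) else float("nan"),
        "fnr": fn / (fn + tp) if (fn + tp) else float("nan"),
        "accuracy": (tp + tn) / len(yb),
    }


# ---------------------------------------------------------------------------
# ROC machinery

@dataclass
class RocCurve:
    """A Pareto-frontier ROC staircase with its conservative area."""

    points: list[tuple[float, float]]
    auroc: float
    provenance: str = "composite"

    @classmethod
    def from_points(cls, points: Iterable[tuple[float, float]],
                    provenance: str = "composite") -> "RocCurve":
        pts = set((float(f), float(t)) for f, t in points)
        pts.update([(0.0, 0.0), (1.0, 1.0)])
        ordered = sorted(pts, key=lambda p: (p[0], -p[1]))
        frontier: list[tuple[float, float]] = []
        best = -1.0
        for f, t in ordered:
            if t > best:
                frontier.append((f, t))
                best = t
        auroc = _staircase_area(frontier)
        return cls(points=frontier, auroc=auroc, provenance=provenance)


def _staircase_area(points: Sequence[tuple[float, float]]) -> float:
    """Lower (conservative) staircase area under sorted ROC points.

    The last frontier point's TPR is held out to FPR = 1, since any
    frontier ends at or dominates (1, 1).
    """
    area = 0.0
    for (x0, y0), (x1, _) in zip(points[:-1], points[1:]):
        area += (x1 - x0) * y0
    x_last, y_last = points[-1]
    area += (1.0 - x_last) * y_last
    return float(area)


def _single_param_points(values: np.ndarray, yb: np.ndarray, direction: str):
    """(FPR, TPR, cut) for every distinct cut of one parameter."""
    cuts = np.concatenate([[-np.inf], np.unique(values), [np.inf]])
    n_pos = int(yb.sum())
    n_neg = int((~yb).sum())
    out = []
    for c in cuts:
        pred = values > c if direction == ">" else values < c
        out.append((int((pred & ~yb).sum()) / n_neg,
                    int((pred & yb).sum()) / n_pos, float(c)))
    return out


def single_param_roc(vectors, parameter: str, y=None) -> RocCurve:
    """Exhaustive ROC of one parameter, sweeping every observed value."""
    if parameter not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {parameter!r}")
    X = _as_matrix(vectors)
    if y is None:
        y = [v.label for v in vectors]
    yb = _labels_to_bool(y)
    if yb.all() or not yb.any():
        raise ValueError("both classes required")
    vals = X[:, PARAM_NAMES.index(parameter)]
    pts = _single_param_points(vals, yb, PARAM_DIRECTIONS[parameter])
    return RocCurve.from_points([(f, t) for f, t, _ in pts], provenance=parameter)


# ---------------------------------------------------------------------------
# Genetic-algorithm training

@dataclass
class GAConfig:
    population: int = 200
    generations: int = 300
    mutation_scale: float = 0.05   # Gaussian sd as fraction of observed range
    mutation_rate: float = 0.4     # per-gene mutation probability
    crossover_rate: float = 0.7
    tournament_size: int = 3
    elite_frac: float = 0.05
    seed: int | None = None


def _permissive_cuts(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Finite cuts that every observed value passes strictly."""
    span = np.maximum(hi - lo, 1e-9)
    return np.where(_GE_MASK, lo - span - 1.0, hi + span + 1.0)


def _rates(pred: np.ndarray, yb: np.ndarray) -> tuple[float, float, float]:
    tp = (pred & yb).sum()
    fp = (pred & ~yb).sum()
    fpr = fp / (~yb).sum()
    tpr = tp / yb.sum()
    acc = (tp + ((~pred) & (~yb)).sum()) / len(yb)
    return float(fpr), float(tpr), float(acc)


def _refine_margin(cuts: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Move each cut to the midpoint of its margin (max-margin refinement).

    Any cut between the nearest passing and nearest failing observed value
    leaves every per-parameter comparison — hence the conjunction and all
    training metrics — unchanged; the midpoint generalises best, instead
    of hugging a data edge the way exhaustively swept cuts do.
    """
    out = cuts.copy()
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    for j in range(X.shape[1]):
        v = X[:, j]
        c = cuts[j]
        if _GE_MASK[j]:  # pass iff v > c; keep c in [max(v<=c), min(v>c))
            passing = v[v > c]
            failing = v[v <= c]
            v_hi = passing.min() if passing.size else hi[j] + span[j]
            v_lo = failing.max() if failing.size else lo[j] - span[j]
        else:            # pass iff v < c; keep c in (max(v<c), min(v>=c)]
            passing = v[v < c]
            failing = v[v >= c]
            v_lo = passing.max() if passing.size else lo[j] - span[j]
            v_hi = failing.min() if failing.size else hi[j] + span[j]
        out[j] = 0.5 * (v_lo + v_hi)
    return out


def train_composite(
    vectors,
    y=None,
    ga_config: GAConfig | None = None,
    selection: str = "youden",
) -> tuple[ThresholdSet, RocCurve, dict]:
    """Evolve a composite threshold set, maximising the archive AUROC.

    Every evaluated set contributes one (FPR, TPR) point to an archive;
    the returned ROC is the Pareto frontier of the archive (plus the
    trivial corners).  The returned set is the frontier point maximising
    Youden's J = TPR − FPR (``selection="youden"``) or the accuracy
    (``selection="accuracy"``).  Reproducible given ``ga_config.seed``.
    """
    cfg = ga_config or GAConfig()
    X = _as_matrix(vectors)
    if y is None:
        y = [v.label for v in vectors]
    yb = _labels_to_bool(y)
    if yb.all() or not yb.any():
        raise ValueError("both classes required for training")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    permissive = _permissive_cuts(lo, hi)

    archive_fpr: list[float] = []
    archive_tpr: list[float] = []
    archive_acc: list[float] = []
    archive_cuts: list[np.ndarray] = []

    def record(cuts: np.ndarray) -> float:
        pred = _predict_matrix(X, cuts)
        fpr, tpr, acc = _rates(pred, yb)
        archive_fpr.append(fpr)
        archive_tpr.append(tpr)
        archive_acc.append(acc)
        archive_cuts.append(cuts)
        return tpr - fpr

    # Seed the archive with every single-parameter ROC so the composite
    # frontier dominates each individual parameter by construction; seed
    # the population with each parameter's best (Youden) cut.
    seeds: list[np.ndarray] = []
    for j, p in enumerate(PARAM_NAMES):
        pts = _single_param_points(X[:, j], yb, PARAM_DIRECTIONS[p])
        best_j, best_cut = -np.inf, None
        for fpr, tpr, cut in pts:
            cuts = permissive.copy()
            cuts[j] = np.clip(cut, lo[j] - span[j] - 1.0, hi[j] + span[j] + 1.0)
            record(cuts)
            if tpr - fpr > best_j:
                best_j, best_cut = tpr - fpr, cuts
        seeds.append(best_cut)

    pop = list(seeds)
    while len(pop) < cfg.population:
        pop.append(lo + rng.random(len(PARAM_NAMES)) * span)
    pop = pop[: cfg.population]
    fitness = np.array([record(c) for c in pop])

    n_elite = max(1, int(cfg.elite_frac * cfg.population))
    for _ in range(cfg.generations):
        order = np.argsort(fitness)[::-1]
        new_pop = [pop[i].copy() for i in order[:n_elite]]
        while len(new_pop) < cfg.population:
            idx = rng.integers(0, cfg.population, size=(2, cfg.tournament_size))
            p1 = pop[idx[0][np.argmax(fitness[idx[0]])]]
            p2 = pop[idx[1][np.argmax(fitness[idx[1]])]]
            if rng.random() < cfg.crossover_rate:
                mask = rng.random(len(PARAM_NAMES)) < 0.5
                child = np.where(mask, p1, p2)
            else:
                child = p1.copy()
            mut = rng.random(len(PARAM_NAMES)) < cfg.mutation_rate
            child = child + mut * rng.normal(0.0, cfg.mutation_scale * span)
            new_pop.append(child)
        pop = new_pop
        fitness = np.array([record(c) for c in pop])

    # Pareto frontier of the archive
    order = sorted(range(len(archive_fpr)),
                   key=lambda i: (archive_fpr[i], -archive_tpr[i]))
    frontier_idx: list[int] = []
    best_tpr = -1.0
    for i in order:
        if archive_tpr[i] > best_tpr:
            frontier_idx.append(i)
            best_tpr = archive_tpr[i]
    roc = RocCurve.from_points(
        [(archive_fpr[i], archive_tpr[i]) for i in frontier_idx]
    )
    if selection == "youden":
        key = lambda i: archive_tpr[i] - archive_fpr[i]
    elif selection == "accuracy":
        key = lambda i: archive_acc[i]
    else:
        raise ValueError("selection must be 'youden' or 'accuracy'")
    best_i = max(frontier_idx, key=key)
    best_cuts = _refine_margin(archive_cuts[best_i], X)
    best = ThresholdSet(dict(zip(PARAM_NAMES, best_cuts)), name="trained")
    info = {"fpr": archive_fpr[best_i], "tpr": archive_tpr[best_i],
            "accuracy": archive_acc[best_i], "auroc": roc.auroc,
            "n_evaluated": len(archive_fpr)}
    return best, roc, info


def learning_curve(
    vectors,
    fractions: Sequence[float],
    y=None,
    iterations: int = 10,
    seed: int | None = None,
    ga_config: GAConfig | None = None,
) -> pd.DataFrame:
    """Accuracy of the most-accurate frontier set vs training fraction.

    For each fraction, ``iterations`` random stratified splits are drawn;
    a composite set is trained on the fraction and the accuracy-maximal
    frontier set is evaluated on the held-out rest.
    """
    X = _as_matrix(vectors)
    if y is None:
        y = [v.label for v in vectors]
    yb = _labels_to_bool(y)
    rng = np.random.default_rng(seed)
    cfg = ga_config or GAConfig(population=40, generations=30)
    rows = []
    pos_idx = np.nonzero(yb)[0]
    neg_idx = np.nonzero(~yb)[0]
    for frac in fractions:
        if not (0.0 < frac < 1.0):
            raise ValueError("fractions must lie in (0, 1)")
        n_pos = int(round(frac * len(pos_idx)))
        n_neg = int(round(frac * len(neg_idx)))
        if n_pos == 0 or n_neg == 0 or n_pos == len(pos_idx) or n_neg == len(neg_idx):
            raise ValueError(f"fraction {frac} leaves an empty train or test side")
        accs = []
        for _ in range(iterations):
            train_idx = np.concatenate([
                rng.permutation(pos_idx)[:n_pos],
                rng.permutation(neg_idx)[:n_neg],
            ])
            test_mask = np.ones(len(yb), dtype=bool)
            test_mask[train_idx] = False
            sub_cfg = GAConfig(**{**cfg.__dict__, "seed": int(rng.integers(2**31))})
            t, _, _ = train_composite(X[train_idx], yb[train_idx],
                                      ga_config=sub_cfg, selection="accuracy")
            pred = _predict_matrix(X[test_mask], t.as_array())
            accs.append(float((pred == yb[test_mask]).mean()))
        rows.append({"fraction": frac, "mean_accuracy": float(np.mean(accs)),
                     "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Estimator wrappers

class FixedThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Apply a fixed (named or custom) threshold set as a classifier.

    Parameters
    ----------
    thresholds : {"exclusive", "inclusive"} or ThresholdSet
        The composite cut set; the two named defaults are the shipped
        low-false-positive and low-false-negative sets.
    """

    def __init__(self, thresholds: str | ThresholdSet = "exclusive"):
        self.thresholds = thresholds

    def _resolve(self) -> ThresholdSet:
        if isinstance(self.thresholds, ThresholdSet):
            return self.thresholds
        try:
            return _NAMED_SETS[self.thresholds]
        except KeyError:
            raise ValueError(
                f"thresholds must be a ThresholdSet or one of {list(_NAMED_SETS)}"
            ) from None

    def fit(self, X, y=None):
        X = _as_matrix(X)
        self.threshold_set_ = self._resolve()
        self.classes_ = np.array(["binder", "nonbinder"])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        if not hasattr(self, "threshold_set_"):
            self.fit(X)
        X = _as_matrix(X)
        pred = _predict_matrix(X, self.threshold_set_.as_array())
        return np.where(pred, "binder", "nonbinder")


class GAThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Genetic-algorithm-trained composite threshold classifier.

    ``fit`` evolves the ten cuts on labeled vectors, archiving every
    evaluated set; fitted attributes expose the chosen set
    (``threshold_set_``), the archive's Pareto-frontier ROC (``roc_``) and
    its conservative area (``auroc_``).
    """

    def __init__(self, population: int = 200, generations: int = 300,
                 mutation_scale: float = 0.05, mutation_rate: float = 0.4,
                 crossover_rate: float = 0.7, tournament_size: int = 3,
                 elite_frac: float = 0.05, selection: str = "youden",
                 random_state: int | None = None):
        self.population = population
        self.generations = generations
        self.mutation_scale = mutation_scale
        self.mutation_rate = mutation_rate
        self.crossover_rate = crossover_rate
        self.tournament_size = tournament_size
        self.elite_frac = elite_frac
        self.selection = selection
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_matrix(X)
        cfg = GAConfig(
            population=self.population, generations=self.generations,
            mutation_scale=self.mutation_scale, mutation_rate=self.mutation_rate,
            crossover_rate=self.crossover_rate, tournament_size=self.tournament_size,
            elite_frac=self.elite_frac, seed=self.random_state,
        )
        self.threshold_set_, self.roc_, info = train_composite(
            X, y, ga_config=cfg, selection=self.selection
        )
        self.auroc_ = self.roc_.auroc
        self.train_info_ = info
        self.classes_ = np.array(["binder", "nonbinder"])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = _as_matrix(X)
        pred = _predict_matrix(X, self.threshold_set_.as_array())
        return np.where(pred, "binder", "nonbinder")
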