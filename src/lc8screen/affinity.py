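"""Affinity correlation, prediction and filtering of candidate sites.

Scores from co-folding runs are correlated with experimentally measured
dissociation constants (Kd, µM) of known 8-residue LC8 motifs: ordinary
least-squares fits with multiple-testing-corrected p-values, and adjusted
mutual information (AMI) over a grid of binning strategies to catch
non-linear relationships.

Two shipped linear inversions convert a score into a rough Kd estimate,
one for motifs anchored by the canonical TQT triad and one for all other
anchors:

    Kd_TQT  = (best 1-client dimer PAE − 0.89) / 0.0035
    Kd_!TQT = (mean 1-client PtoL PAE  − 4.45) / 0.135

Raw predictions below 1 µM (including negative values, an inevitable
consequence of linear inversion) are floored at 1 µM.  Candidate sites
with predicted Kd above 40 µM, or whose anchor falls inside a structured
domain, are discarded: the calibration data contain essentially no weaker
affinities and LC8 binds only disordered regions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_mutual_info_score
from statsmodels.stats.multitest import multipletests

from .classify import ThresholdSet, _predict_matrix
from .colabfold import PredictionRun
from .interface import PARAM_NAMES, SCORE_FIELDS, ScoringConfig, DEFAULT_CONFIG, score_run

__all__ = [
    "AffinityRecord",
    "AffinityModel",
    "BinningStrategy",
    "FitResult",
    "TQT_MODEL",
    "NOT_TQT_MODEL",
    "KD_FLOOR_UM",
    "KD_FILTER_UM",
    "match_affinities",
    "metric_table",
    "linear_fit",
    "adjust_pvalues",
    "ami",
    "ami_grid",
    "success_rate",
    "pseudo_kd",
    "predict_affinity",
    "filter_predictions",
    "select_subset",
]

#: Floor applied to raw affinity predictions (µM).
KD_FLOOR_UM = 1.0
#: Predictions weaker than this (µM) are discarded rather than extrapolated.
KD_FILTER_UM = 40.0

#: The three affinity bin-edge sets (µM), spanning full and half orders of
#: magnitude (10^0.5 ≈ 3.16).
AFFINITY_EDGE_SETS: tuple[tuple[float, ...], ...] = (
    (0.0, 0.316, 1.0, 3.16, 10.0, 31.6, 100.0),
    (0.0, 1.0, 10.0, 100.0),
    (0.0, 0.316, 3.16, 31.6, 100.0),
)

SCORE_BINNINGS = ("geometric", "linear", "quantile")


@dataclass(frozen=True)
class AffinityRecord:
    """A known 8-residue LC8 motif with its measured Kd (µM)."""

    motif: str
    anchor_class: str  # "TQT" | "notTQT"
    kd: float

    def __post_init__(self) -> None:
        if len(self.motif) != 8:
            raise ValueError("motif must be 8 residues long")
        if self.anchor_class not in ("TQT", "notTQT"):
            raise ValueError("anchor_class must be 'TQT' or 'notTQT'")
        if not (np.isfinite(self.kd) and self.kd > 0):
            raise ValueError("kd must be finite and positive")


@dataclass
class AffinityModel:
    """Score→Kd linear inversion: Kd = (x − intercept) / slope.

    The constants come from an OLS fit of the predictor *on* Kd (i.e. the
    score is modelled as intercept + slope·Kd), so prediction inverts the
    line.  ``fit`` re-estimates the constants from data; the two shipped
    instances carry the published calibration.
    """

    anchor_class: str
    predictor: str
    intercept: float | None = None
    slope: float | None = None
    floor_um: float = KD_FLOOR_UM

    def fit(self, scores: Sequence[float], kd: Sequence[float]) -> "AffinityModel":
        res = linear_fit(np.asarray(kd, dtype=float), np.asarray(scores, dtype=float))
        self.slope = res.slope
        self.intercept = res.intercept
        return self

    def predict(self, score) -> np.ndarray | float:
        if self.slope is None or self.intercept is None:
            raise ValueError("model has no constants; call fit or use a shipped model")
        score = np.asarray(score, dtype=float)
        raw = (score - self.intercept) / self.slope
        out = np.maximum(raw, self.floor_um)
        return float(out) if out.ndim == 0 else out


#: Shipped calibration for TQT-anchored motifs (best-structure 1-client
#: dimer-interface PAE as predictor).
TQT_MODEL = AffinityModel(
    anchor_class="TQT", predictor="dimer_1c_best", intercept=0.89, slope=0.0035
)
#: Shipped calibration for other anchors (across-structure mean of the
#: 1-client PtoL PAE as predictor).
NOT_TQT_MODEL = AffinityModel(
    anchor_class="notTQT", predictor="ptol_1c_avg", intercept=4.45, slope=0.135
)


def predict_affinity(scores: dict, anchor_class: str) -> float:
    """Predict a Kd (µM) from run scores for the given anchor class.

    ``scores`` must contain the model's predictor: ``dimer_1c_best`` for
    TQT anchors, ``ptol_1c_avg`` otherwise.  Raw values below 1 µM are
    floored at 1 µM.
    """
    model = TQT_MODEL if anchor_class == "TQT" else NOT_TQT_MODEL
    if model.predictor not in scores:
        raise ValueError(f"missing predictor {model.predictor!r}")
    return float(model.predict(scores[model.predictor]))


# ---------------------------------------------------------------------------
# Linking runs to known affinities

def match_affinities(
    runs: Iterable[PredictionRun], records: Sequence[AffinityRecord]
) -> pd.DataFrame:
    """Join runs to affinity records by 8-mer substring match.

    Every run whose client window contains a record's motif is joined to
    that record; one record may match several runs (and vice versa), so
    the result can hold more rows than there are records.
    """
    rows = []
    for run in runs:
        if run.window is None:
            continue
        for rec in records:
            if rec.motif in run.window.sequence:
                rows.append({
                    "run_id": run.run_id,
                    "protein_id": run.window.protein_id,
                    "start": run.window.start,
                    "end": run.window.end,
                    "length": run.window.length,
                    "client_count": run.client_count,
                    "motif": rec.motif,
                    "anchor_class": rec.anchor_class,
                    "kd": rec.kd,
                })
    return pd.DataFrame(
        rows, columns=["run_id", "protein_id", "start", "end", "length",
                       "client_count", "motif", "anchor_class", "kd"]
    )


def metric_table(
    one_client: PredictionRun | None,
    two_client: PredictionRun | None,
    threshold: ThresholdSet | None = None,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """The 21 per-run metrics: best and mean of each score × client count,
    plus the success rate.

    "Best" follows the interface-pLDDT ordering used throughout; "mean"
    averages a score over all structures of the run.  The success rate is
    the fraction of (rank-paired) structures passing ``threshold``.  A
    missing side leaves its ten metrics absent and the row flagged
    incomplete.
    """
    out: dict[str, float] = {}
    per_structure: dict[str, np.ndarray] = {}
    for suffix, run in (("1c", one_client), ("2c", two_client)):
        if run is None:
            out["incomplete"] = True
            continue
        scores = score_run(run, config)
        arr = {f: np.array([getattr(s, _ATTR[f]) for s in scores]) for f in SCORE_FIELDS}
        best_i = int(np.argmax(arr["plddt"]))
        for f in SCORE_FIELDS:
            out[f"{f}_{suffix}_best"] = float(arr[f][best_i])
            out[f"{f}_{suffix}_avg"] = float(arr[f].mean())
            per_structure[f"{f}_{suffix}"] = arr[f]
    out.setdefault("incomplete", False)
    if threshold is not None and not out["incomplete"]:
        out["success_rate"] = _paired_success_rate(per_structure, threshold)
    return out


_ATTR = {"conf": "confidence", "plddt": "avg_plddt_bind",
         "ltop": "pae_ltop", "ptol": "pae_ptol", "dimer": "pae_dimer"}


def _paired_success_rate(per_structure: dict[str, np.ndarray],
                         t: ThresholdSet) -> float:
    n = min(len(v) for v in per_structure.values())
    X = np.column_stack([per_structure[p][:n] for p in PARAM_NAMES])
    return float(_predict_matrix(X, t.as_array()).mean())


def success_rate(
    run: PredictionRun,
    linked: PredictionRun,
    t: ThresholdSet,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> float:
    """Fraction of structures predicted to bind under a threshold set.

    Structures of the 1-client and 2-client runs are paired by rank to
    form per-structure 10-parameter vectors.  The run behaves like a tiny
    equilibrium ensemble: each structure is one "molecule" that is either
    bound (passes all ten cuts) or not.
    """
    one, two = (run, linked) if run.client_count == 1 else (linked, run)
    s1, s2 = score_run(one, config), score_run(two, config)
    if not s1 or not s2:
        raise ValueError("empty run")
    per = {}
    for suffix, ss in (("1c", s1), ("2c", s2)):
        for f in SCORE_FIELDS:
            per[f"{f}_{suffix}"] = np.array([getattr(s, _ATTR[f]) for s in ss])
    return _paired_success_rate(per, t)


def pseudo_kd(n_bound: int, n_total: int) -> float | None:
    """Pseudo-Kd of a prediction ensemble: #unbound² / #bound.

    Undefined (``None``) when nothing is bound; 0 when everything is.
    With ~25–50 "molecules" per run the boundaries occur often, which is
    why the success rate, not the pseudo-Kd, is the routine statistic.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_bound <= n_total):
        raise ValueError("n_bound must lie in [0, n_total]")
    if n_bound == 0:
        return None
    return (n_total - n_bound) ** 2 / n_bound


# ---------------------------------------------------------------------------
# Fits and multiple-testing correction

@dataclass
class FitResult:
    slope: float
    intercept: float
    r2: float
    rmse: float
    p: float
    n: int
    p_bonferroni: float | None = None
    p_bh: float | None = None


def linear_fit(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """OLS of y on x with R², RMSE and the two-sided p for slope ≠ 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        rmse=float(np.sqrt(np.mean(resid**2))),
        p=float(res.pvalue),
        n=len(x),
    )


def adjust_pvalues(ps: Sequence[float], method: str) -> np.ndarray:
    """Bonferroni or Benjamini–Hochberg adjusted p-values."""
    ps = np.asarray(ps, dtype=float)
    if ps.size and (ps.min() < 0 or ps.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "benjamini_hochberg": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError("method must be 'bonferroni' or 'benjamini_hochberg'")
    return multipletests(ps, method=key)[1]


# ---------------------------------------------------------------------------
# Adjusted mutual information over binning strategies

@dataclass(frozen=True)
class BinningStrategy:
    """How to discretise affinities and scores before computing AMI."""

    affinity_edges: tuple[float, ...] = AFFINITY_EDGE_SETS[0]
    score_binning: str = "geometric"
    k_bins: int = 6

    def __post_init__(self) -> None:
        edges = np.asarray(self.affinity_edges, dtype=float)
        if not np.all(np.diff(edges) > 0):
            raise ValueError("affinity edges must be strictly increasing")
        if self.score_binning not in SCORE_BINNINGS:
            raise ValueError(f"score_binning must be one of {SCORE_BINNINGS}")


def _bin_scores(values: np.ndarray, binning: str, k: int,
                reference: np.ndarray | None = None) -> np.ndarray:
    """Discretise scores with edges derived from ``reference`` (default:
    the values themselves) so sub-datasets share the full dataset's bins."""
    ref = values if reference is None else np.asarray(reference, dtype=float)
    lo, hi = ref.min(), ref.max()
    if binning == "linear":
        edges = np.linspace(lo, hi, k + 1)
    elif binning == "geometric":
        shift = 0.0 if lo > 0 else -lo + 1e-9  # geometric edges need positives
        edges = np.geomspace(lo + shift, hi + shift, k + 1) - shift
    elif binning == "quantile":
        edges = np.quantile(ref, np.linspace(0, 1, k + 1))
    else:
        raise ValueError(binning)
    return np.clip(np.digitize(values, edges[1:-1]), 0, k - 1)


def ami(
    scores: Sequence[float],
    kd: Sequence[float],
    strategy: BinningStrategy = BinningStrategy(),
    score_reference: Sequence[float] | None = None,
) -> float:
    """Adjusted mutual information between binned scores and affinities.

    AMI = (MI − E[MI]) / (max(H(x), H(y)) − E[MI]), with the expected MI
    taken under the permutation (hypergeometric) model, so chance
    agreement scores 0 and identical partitions score 1.  If either
    variable collapses into a single bin the result is defined as 0 (with
    a warning), since no information can be shared.
    """
    scores = np.asarray(scores, dtype=float)
    kd = np.asarray(kd, dtype=float)
    if len(scores) != len(kd) or len(scores) < 2:
        raise ValueError("need two aligned samples of length >= 2")
    kd_binned = np.digitize(kd, np.asarray(strategy.affinity_edges)[1:-1])
    sc_binned = _bin_scores(scores, strategy.score_binning, strategy.k_bins,
                            reference=score_reference)
    if len(np.unique(kd_binned)) < 2 or len(np.unique(sc_binned)) < 2:
        warnings.warn("a variable collapsed into a single bin; AMI defined as 0")
        return 0.0
    return float(adjusted_mutual_info_score(sc_binned, kd_binned,
                                            average_method="max"))


def ami_grid(
    scores: Sequence[float],
    kd: Sequence[float],
    k_bins: int = 6,
    score_reference: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Evaluate all 9 affinity×score binning combinations.

    Returns a tidy frame (affinity_edges, score_binning, ami); the maximum
    over the grid is the headline statistic for a score/dataset pair.
    """
    rows = []
    for edges in AFFINITY_EDGE_SETS:
        for binning in SCORE_BINNINGS:
            strat = BinningStrategy(affinity_edges=edges, score_binning=binning,
                                    k_bins=k_bins)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                value = ami(scores, kd, strat, score_reference=score_reference)
            rows.append({"affinity_edges": str(list(edges)),
                         "score_binning": binning, "ami": value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sub-dataset selection and candidate filtering

_ATOM_RE = re.compile(r"^\s*(!?)\s*(TQT|len\s*([=<>])\s*(\d+))\s*$")


def select_subset(table: pd.DataFrame, expression: str) -> pd.DataFrame:
    """Filter a metric table with a small anchor/length expression.

    Atoms: ``TQT`` (anchor class), ``len=N`` / ``len<N`` / ``len>N``
    (client window length); ``!`` negates an atom, ``&`` is AND and
    ``||`` is OR (OR binds last).  E.g. ``"TQT&len=14"`` or ``"!TQT"``.
    """
    def atom_mask(atom: str) -> pd.Series:
        m = _ATOM_RE.match(atom)
        if not m:
            raise ValueError(f"cannot parse filter atom {atom!r}")
        neg, body, op, num = m.groups()
        if body == "TQT":
            mask = table["anchor_class"] == "TQT"
        else:
            n = int(num)
            length = table["length"]
            mask = {"=": length == n, "<": length < n, ">": length > n}[op]
        return ~mask if neg else mask

    or_terms = expression.split("||")
    total = pd.Series(False, index=table.index)
    for term in or_terms:
        mask = pd.Series(True, index=table.index)
        for atom in term.split("&"):
            mask &= atom_mask(atom)
        total |= mask
    return table[total]


@dataclass(frozen=True)
class CandidateSite:
    """A predicted binding site awaiting affinity/structure filtering."""

    protein_id: str
    anchor_position: int          # protein-relative, 0-based
    anchor_class: str
    predicted_kd: float
    threshold_name: str = "exclusive"
    motif: str | None = None


def read_intervals(path) -> pd.DataFrame:
    """Read a BED-like file (protein_id, start, end; 0-based half-open)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["protein_id", "start", "end"])
    if (df["end"] <= df["start"]).any():
        raise ValueError("malformed interval: end must exceed start")
    return df


def filter_predictions(
    sites: Iterable[CandidateSite],
    structured: pd.DataFrame | None = None,
    kd_cutoff: float = KD_FILTER_UM,
) -> list[CandidateSite]:
    """Drop weak-affinity sites and sites inside structured domains.

    Sites with predicted Kd above ``kd_cutoff`` (default 40 µM) are
    discarded to avoid extrapolating past the calibration data; sites
    whose anchor lies inside a structured interval are discarded because
    LC8 binds only disordered regions.  Retained sites keep their
    provenance (which threshold admitted them).
    """
    if structured is not None:
        bad = {"start", "end", "protein_id"} - set(structured.columns)
        if bad:
            raise ValueError(f"malformed interval table, missing {sorted(bad)}")
        if (structured["end"] <= structured["start"]).any():
            raise ValueError("malformed interval: end must exceed start")
    kept = []
    for site in sites:
        if site.predicted_kd > kd_cutoff:
            continue
        if structured is not None:
            rows = structured[structured["protein_id"] == site.protein_id]
            inside = ((rows["start"] <= site.anchor_position)
                      & (site.anchor_position < rows["end"])).any()
            if inside:
                continue
        kept.append(site)
    return kept
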