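"""Interface scores extracted from LC8–client co-folding predictions.

Five per-structure scores summarise how confidently a predictor places a
client peptide in the LC8 binding groove:

1. ``conf``  — the model-ranking confidence (0.2·pTM + 0.8·ipTM);
2. ``plddt`` — mean pLDDT over the bound client region and the β3
   residues it contacts;
3. ``ltop``  — mean PAE of LC8 β3 aligned on the bound client (LtoP);
4. ``ptol``  — the transpose direction, client aligned on β3 (PtoL);
5. ``dimer`` — mean PAE across the LC8–LC8 dimer interface.

PAE is directional, so LtoP and PtoL are evaluated separately even though
they look symmetric by definition.  The β3 strand of each protomer is the
client's pairing partner; G63 is the landmark defining the anchor
(position 0) of the bound motif.

Scores from matched 1-client and 2-client runs of the same window are
linked into 10-parameter vectors for classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .colabfold import PredictionRun, StructureModel
from .windows import SequenceWindow

__all__ = [
    "ScoringConfig",
    "InterfaceScores",
    "ScoreVector",
    "SCORE_FIELDS",
    "PARAM_NAMES",
    "find_bound_region",
    "find_anchor",
    "directional_pae",
    "dimer_interface_pae",
    "score_structure",
    "score_run",
    "select_best",
    "link_runs",
]

SCORE_FIELDS = ("conf", "plddt", "ltop", "ptol", "dimer")
#: Canonical order of the ten linked parameters (2-client block first).
PARAM_NAMES = [f"{f}_2c" for f in SCORE_FIELDS] + [f"{f}_1c" for f in SCORE_FIELDS]


@dataclass(frozen=True)
class ScoringConfig:
    """Knobs of the interface-score extraction.

    ``beta3_span`` and ``g63_residue`` use 1-based LC8 residue numbering
    (the field convention); the span brackets the G63 landmark because the
    strand's exact limits vary slightly between depositions.  Contacts are
    evaluated on Cα–Cα distances.
    """

    beta3_span: tuple[int, int] = (60, 67)  # 1-based, inclusive
    g63_residue: int = 63                   # 1-based
    contact_cutoff: float = 8.0             # Å, Cα–Cα
    cterm_exclude: int = 3                  # residues dropped per protomer

    @property
    def beta3_local(self) -> np.ndarray:
        """0-based indices of the β3 span within an LC8 chain."""
        lo, hi = self.beta3_span
        return np.arange(lo - 1, hi)

    @property
    def g63_local(self) -> int:
        return self.g63_residue - 1


DEFAULT_CONFIG = ScoringConfig()


@dataclass
class InterfaceScores:
    """The five interface scores of one structure (groove-averaged)."""

    confidence: float
    avg_plddt_bind: float
    pae_ltop: float
    pae_ptol: float
    pae_dimer: float
    anchor_index: int | None = None
    bound_regions: dict | None = None  # chain id -> frozenset of client-local idx
    unbound: bool = False

    def as_dict(self, suffix: str) -> dict[str, float]:
        return {
            f"conf_{suffix}": self.confidence,
            f"plddt_{suffix}": self.avg_plddt_bind,
            f"ltop_{suffix}": self.pae_ltop,
            f"ptol_{suffix}": self.pae_ptol,
            f"dimer_{suffix}": self.pae_dimer,
        }


@dataclass
class ScoreVector:
    """Linked 10-parameter vector of one window (1-client + 2-client)."""

    window: SequenceWindow
    values: dict[str, float]
    label: str = "unknown"  # binder | nonbinder | unknown

    def __post_init__(self) -> None:
        missing = [p for p in PARAM_NAMES if p not in self.values]
        if missing:
            raise ValueError(f"incomplete score vector, missing {missing}")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[p] for p in PARAM_NAMES], dtype=float)


def _lc8_chains(model: StructureModel) -> list[str]:
    return [cid for cid, _ in model.chain_layout[:2]]


def _client_chains(model: StructureModel) -> list[str]:
    return [cid for cid, _ in model.chain_layout[2:]]


def find_bound_region(
    model: StructureModel,
    client_chain: str,
    beta3_residues: Sequence[int] | None = None,
    cutoff: float = 8.0,
) -> frozenset[int]:
    """Client residues (chain-local, 0-based) in contact with β3.

    A client residue belongs to the bound region when its Cα lies within
    ``cutoff`` Å of any β3 Cα of either LC8 protomer.  The set may be
    empty: an unbound prediction is a meaningful outcome, not an error.
    """
    if client_chain not in model.coordinates:
        raise KeyError(f"unknown chain {client_chain!r}")
    beta3 = np.asarray(
        DEFAULT_CONFIG.beta3_local if beta3_residues is None else beta3_residues
    )
    if beta3.size == 0:
        raise ValueError("beta3_residues must be nonempty")
    client_xyz = model.coordinates[client_chain]
    bound: set[int] = set()
    for lc8 in _lc8_chains(model):
        lc8_xyz = model.coordinates[lc8][beta3]
        d = cdist(client_xyz, lc8_xyz)
        bound.update(np.nonzero((d <= cutoff).any(axis=1))[0].tolist())
    return frozenset(bound)


def find_anchor(model: StructureModel, client_chain: str,
                config: ScoringConfig = DEFAULT_CONFIG) -> int:
    """Client residue (chain-local, 0-based) closest to G63 of either protomer.

    This residue defines motif position 0.  Ties break toward the lower
    client index.
    """
    if client_chain not in model.coordinates:
        raise KeyError(f"unknown chain {client_chain!r}")
    client_xyz = model.coordinates[client_chain]
    g63 = np.stack(
        [model.coordinates[c][config.g63_local] for c in _lc8_chains(model)]
    )
    d = cdist(client_xyz, g63).min(axis=1)
    return int(np.argmin(d))  # argmin returns the first (lowest) index on ties


def directional_pae(
    pae: np.ndarray, from_set: Iterable[int], to_set: Iterable[int]
) -> float:
    """Mean PAE of ``from_set`` aligned on ``to_set`` (global indices).

    PAE rows are the assessed residues and columns the aligned-on
    residues, so the two directions of an interface differ in practice and
    are reported separately.
    """
    fr = sorted(set(from_set))
    to = sorted(set(to_set))
    if not fr or not to:
        raise ValueError("no interface")
    if set(fr) & set(to):
        raise ValueError("from_set and to_set must be disjoint")
    return float(np.asarray(pae)[np.ix_(fr, to)].mean())


def dimer_interface_pae(
    model: StructureModel,
    cutoff: float = 8.0,
    cterm_exclude: int = 3,
) -> float:
    """Mean PAE over contacting LC8–LC8 residue pairs, both directions.

    The floppy C-terminal tail (last ``cterm_exclude`` residues of each
    protomer) is excluded so the value reflects the folded interface.
    This score tracks whether the dimer scaffold of a prediction is sound.
    """
    chains = _lc8_chains(model)
    if len(chains) != 2:
        raise ValueError("two LC8 chains required")
    a, b = chains
    na = model.chain_layout[0][1] - cterm_exclude
    nb = model.chain_layout[1][1] - cterm_exclude
    xa = model.coordinates[a][:na]
    xb = model.coordinates[b][:nb]
    d = cdist(xa, xb)
    ii, jj = np.nonzero(d <= cutoff)
    if ii.size == 0:
        raise ValueError("protomers not in contact")
    ga = np.arange(*model.chain_slice(a).indices(10**9))[:na]
    gb = np.arange(*model.chain_slice(b).indices(10**9))[:nb]
    vals = np.concatenate([model.pae[ga[ii], gb[jj]], model.pae[gb[jj], ga[ii]]])
    return float(vals.mean())


def _global_indices(model: StructureModel, chain: str, local: Iterable[int]) -> list[int]:
    off = model.chain_slice(chain).start
    return [off + i for i in local]


def score_structure(
    model: StructureModel, config: ScoringConfig = DEFAULT_CONFIG
) -> InterfaceScores:
    """Compute the five interface scores of one structure.

    For 2-client models each groove is scored and the groove values are
    averaged, giving a single value per score.  Unbound predictions
    (empty bound region) are still scored — falling back to the full
    client span and the client-wide PAE blocks — and flagged ``unbound``
    so nonbinders keep their (poor) scores for classifier training.
    """
    clients = _client_chains(model)
    if not clients:
        raise ValueError("no client chains in model")
    beta3_local = config.beta3_local
    plddt_vals, ltop_vals, ptol_vals = [], [], []
    bound_regions: dict[str, frozenset[int]] = {}
    all_unbound = True
    for client in clients:
        bound = find_bound_region(model, client, beta3_local, config.contact_cutoff)
        bound_regions[client] = bound
        client_xyz = model.coordinates[client]
        if bound:
            all_unbound = False
            # β3 residues (either protomer) contacting the bound region
            contacting: list[int] = []
            bound_xyz = client_xyz[sorted(bound)]
            for lc8 in _lc8_chains(model):
                d = cdist(model.coordinates[lc8][beta3_local], bound_xyz)
                hit = beta3_local[(d <= config.contact_cutoff).any(axis=1)]
                contacting.extend(_global_indices(model, lc8, hit))
            bound_global = _global_indices(model, client, sorted(bound))
            region = sorted(set(contacting) | set(bound_global))
            plddt_vals.append(float(model.plddt[region].mean()))
            ltop_vals.append(directional_pae(model.pae, contacting, bound_global))
            ptol_vals.append(directional_pae(model.pae, bound_global, contacting))
        else:
            # unbound: client-wide span against the full β3 of both protomers
            span = _global_indices(model, client, range(len(client_xyz)))
            beta3_global: list[int] = []
            for lc8 in _lc8_chains(model):
                beta3_global.extend(_global_indices(model, lc8, beta3_local))
            plddt_vals.append(float(model.plddt[span].mean()))
            ltop_vals.append(directional_pae(model.pae, beta3_global, span))
            ptol_vals.append(directional_pae(model.pae, span, beta3_global))
    anchor = find_anchor(model, clients[0], config)
    return InterfaceScores(
        confidence=model.confidence,
        avg_plddt_bind=float(np.mean(plddt_vals)),
        pae_ltop=float(np.mean(ltop_vals)),
        pae_ptol=float(np.mean(ptol_vals)),
        pae_dimer=dimer_interface_pae(model, config.contact_cutoff, config.cterm_exclude),
        anchor_index=anchor,
        bound_regions=bound_regions,
        unbound=all_unbound,
    )


def score_run(
    run: PredictionRun, config: ScoringConfig = DEFAULT_CONFIG
) -> list[InterfaceScores]:
    """Score every structure of a run, in rank order."""
    return [score_structure(m, config) for m in run.structures]


def select_best(
    run: PredictionRun, config: ScoringConfig = DEFAULT_CONFIG
) -> tuple[StructureModel, InterfaceScores]:
    """The structure maximising interface pLDDT (ties → lower rank).

    The ranking confidence score is a weaker discriminator than interface
    pLDDT, so run-level scores are taken from the structure with the best
    binding-interface pLDDT rather than from rank 1.
    """
    scores = score_run(run, config)
    best_i = max(range(len(scores)), key=lambda i: (scores[i].avg_plddt_bind,
                                                    -run.structures[i].rank))
    return run.structures[best_i], scores[best_i]


def link_runs(
    one_client: Iterable[PredictionRun],
    two_client: Iterable[PredictionRun],
    labels: dict | None = None,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> tuple[list[ScoreVector], list[PredictionRun]]:
    """Join matched 1-client and 2-client runs into 10-parameter vectors.

    Runs are joined on window identity (protein, coordinates, sequence and
    mutant status).  ``labels`` optionally maps window keys or protein ids
    to ``"binder"``/``"nonbinder"``.  Returns the linked vectors and the
    orphan runs that found no partner (reported, never silently dropped).
    """

    def index(runs: Iterable[PredictionRun], expected_count: int) -> dict:
        out: dict = {}
        for r in runs:
            if r.window is None:
                raise ValueError(f"run {r.run_id} carries no window identity")
            if r.client_count != expected_count:
                raise ValueError(
                    f"run {r.run_id}: client_count {r.client_count}, "
                    f"expected {expected_count}"
                )
            key = r.window.key
            if key in out:
                raise ValueError(f"ambiguous link: duplicate window {key}")
            out[key] = r
        return out

    one = index(one_client, 1)
    two = index(two_client, 2)
    vectors: list[ScoreVector] = []
    orphans: list[PredictionRun] = []
    for key in sorted(set(one) | set(two), key=str):
        if key not in one or key not in two:
            orphans.append(one.get(key) or two[key])
            continue
        r1, r2 = one[key], two[key]
        _, s1 = select_best(r1, config)
        _, s2 = select_best(r2, config)
        values = {**s1.as_dict("1c"), **s2.as_dict("2c")}
        label = "unknown"
        if labels is not None:
            label = labels.get(key, labels.get(r1.window.protein_id, "unknown"))
        vectors.append(ScoreVector(window=r1.window, values=values, label=label))
    return vectors, orphans
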