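"""Synthetic co-folding fixtures: run directories, score datasets, affinity data.

Everything needed to exercise the pipeline without a GPU structure
predictor.  The generated LC8 geometry is an *idealised deterministic Cα
trace*, not a real structure: every geometric operation downstream depends
only on pairwise Cα distances and the β3/G63 landmarks, so a straight
trace with the protomers 5 Å apart and the client placed at a configurable
distance from β3 reproduces the contact topology exactly.  PAE matrices
are block-structured (interface blocks at configured means over a uniform
background) because the score extractors consume only block means.

Do not mistake these fixtures for structures; they are test scaffolding
with exactly controllable score content.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .colabfold import PAE_MAX
from .interface import PARAM_NAMES, DEFAULT_CONFIG
from .windows import LC8_HUMAN

__all__ = [
    "FixtureConfig",
    "gen_run_dir",
    "gen_score_dataset",
    "gen_affinity_relation",
    "BINDER_MEANS",
    "NONBINDER_MEANS",
    "SCORE_SDS",
]

_CA_SPACING = 3.8       # Å between consecutive Cα in the idealised trace
_DIMER_GAP = 5.0        # Å between the two protomer traces
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class FixtureConfig:
    """Controls one generated run directory.

    ``score_means`` hold the five per-structure scores to bake into the
    JSON (confidence, interface pLDDT, LtoP, PtoL, dimer PAE);
    ``score_sds`` add per-structure Gaussian spread (all zero = exact
    no-noise mode, in which every extracted score equals its mean).
    """

    n_structures: int = 3
    client_count: int = 1
    bound: bool = True
    client_length: int = 16
    anchor_offset: int = 7          # client residue aligned with G63
    groove_distance: float = 5.0    # Å from client trace to the β3 trace
    unbound_distance: float = 50.0  # Å displacement for unbound fixtures
    background_pae: float = 15.0
    score_means: dict = field(default_factory=lambda: {
        "conf": 0.85, "plddt": 92.0, "ltop": 3.0, "ptol": 5.0, "dimer": 0.95,
    })
    score_sds: dict = field(default_factory=lambda: {
        "conf": 0.0, "plddt": 0.0, "ltop": 0.0, "ptol": 0.0, "dimer": 0.0,
    })
    protein_id: str = "synthetic"
    start: int = 0
    is_mutant: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.client_count not in (1, 2):
            raise ValueError("client_count must be 1 or 2")
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")
        if any(v < 0 for v in self.score_sds.values()):
            raise ValueError("score sds must be >= 0")
        if self.groove_distance <= 0 or self.unbound_distance <= 0:
            raise ValueError("distances must be positive")
        if not (0 <= self.anchor_offset < self.client_length):
            raise ValueError("anchor_offset outside client")


def _lc8_trace(y: float) -> np.ndarray:
    n = len(LC8_HUMAN)
    xyz = np.zeros((n, 3))
    xyz[:, 0] = np.arange(n) * _CA_SPACING
    xyz[:, 1] = y
    return xyz


def _client_trace(cfg: FixtureConfig, groove: int) -> np.ndarray:
    """Client Cα trace parallel to the β3 span of protomer A (groove 0)
    or B (groove 1), with residue ``anchor_offset`` aligned on G63."""
    g63_x = DEFAULT_CONFIG.g63_local * _CA_SPACING
    k = np.arange(cfg.client_length)
    xyz = np.zeros((cfg.client_length, 3))
    xyz[:, 0] = g63_x + (k - cfg.anchor_offset) * _CA_SPACING
    d = cfg.groove_distance if cfg.bound else cfg.unbound_distance
    xyz[:, 1] = -d if groove == 0 else _DIMER_GAP + d
    return xyz


def _write_pdb(path: Path, chains: dict[str, np.ndarray]) -> None:
    lines = []
    serial = 1
    for cid, xyz in chains.items():
        for i, (x, y, z) in enumerate(xyz, start=1):
            lines.append(
                f"ATOM  {serial:>5d}  CA  ALA {cid}{i:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _structure_scores(cfg: FixtureConfig, rng: np.random.Generator) -> dict:
    out = {}
    for key, mean in cfg.score_means.items():
        sd = cfg.score_sds.get(key, 0.0)
        v = mean if sd == 0 else rng.normal(mean, sd)
        if key == "conf":
            v = float(np.clip(v, 0.0, 1.0))
        elif key == "plddt":
            v = float(np.clip(v, 0.0, 100.0))
        else:
            v = float(np.clip(v, 0.0, PAE_MAX))
        out[key] = v
    return out


def gen_run_dir(cfg: FixtureConfig, path: str | Path) -> Path:
    """Emit a parseable prediction directory with controlled scores.

    Writes per-structure score JSONs (constant pLDDT, block-structured
    PAE, pTM/ipTM consistent with the confidence identity), Cα-only PDBs
    with the idealised dimer plus client chain(s), and a ``run.json``
    manifest.  Byte-identical output for identical config and seed.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    n_lc8 = len(LC8_HUMAN)
    L = cfg.client_length
    sequence = "".join(rng.choice(_AA, size=L))
    chains: dict[str, np.ndarray] = {"A": _lc8_trace(0.0), "B": _lc8_trace(_DIMER_GAP)}
    client_ids = "CD"[: cfg.client_count]
    for g, cid in enumerate(client_ids):
        chains[cid] = _client_trace(cfg, g)
    n_total = 2 * n_lc8 + cfg.client_count * L

    beta3 = DEFAULT_CONFIG.beta3_local
    beta3_global = np.concatenate([beta3, n_lc8 + beta3])
    client_global = np.arange(2 * n_lc8, n_total)

    # Per-structure scores, sorted so rank order tracks descending confidence
    draws = sorted(
        (_structure_scores(cfg, rng) for _ in range(cfg.n_structures)),
        key=lambda s: -s["conf"],
    )

    models = []
    for rank, sc in enumerate(draws, start=1):
        pae = np.full((n_total, n_total), cfg.background_pae)
        # dimer block, both directions
        pae[:n_lc8, n_lc8 : 2 * n_lc8] = sc["dimer"]
        pae[n_lc8 : 2 * n_lc8, :n_lc8] = sc["dimer"]
        # β3 -> client (LtoP) and client -> β3 (PtoL)
        pae[np.ix_(beta3_global, client_global)] = sc["ltop"]
        pae[np.ix_(client_global, beta3_global)] = sc["ptol"]
        np.fill_diagonal(pae, 0.0)
        doc = {
            "plddt": [sc["plddt"]] * n_total,
            "pae": [[round(v, 4) for v in row] for row in pae.tolist()],
            "ptm": round(sc["conf"], 6),
            "iptm": round(sc["conf"], 6),  # 0.2·c + 0.8·c == c
        }
        scores_name = f"scores_rank_{rank:03d}.json"
        pdb_name = f"model_rank_{rank:03d}.pdb"
        (path / scores_name).write_text(json.dumps(doc, sort_keys=True))
        _write_pdb(path / pdb_name, chains)
        models.append({"rank": rank, "scores": scores_name, "pdb": pdb_name})

    manifest = {
        "run_id": f"{cfg.protein_id}_{cfg.start}_{cfg.client_count}c",
        "client_count": cfg.client_count,
        "window": {
            "protein_id": cfg.protein_id,
            "start": cfg.start,
            "end": cfg.start + L,
            "sequence": sequence,
            "is_mutant": cfg.is_mutant,
            "anchor_offset": cfg.anchor_offset,
        },
        "models": models,
    }
    (path / "run.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return path


# ---------------------------------------------------------------------------
# Labeled score-vector datasets

#: Class-conditional means emulating the observed score distributions:
#: binders score confidently, nonbinders poorly, with the 2-client runs
#: separating slightly better than the 1-client runs.
BINDER_MEANS = {
    "conf_2c": 0.85, "plddt_2c": 93.0, "ltop_2c": 3.0, "ptol_2c": 5.0,
    "dimer_2c": 0.95, "conf_1c": 0.90, "plddt_1c": 80.0, "ltop_1c": 5.0,
    "ptol_1c": 7.0, "dimer_1c": 1.05,
}
NONBINDER_MEANS = {
    "conf_2c": 0.60, "plddt_2c": 68.0, "ltop_2c": 10.0, "ptol_2c": 14.0,
    "dimer_2c": 1.15, "conf_1c": 0.65, "plddt_1c": 45.0, "ltop_1c": 16.0,
    "ptol_1c": 18.0, "dimer_1c": 1.25,
}
SCORE_SDS = {
    "conf_2c": 0.12, "plddt_2c": 12.0, "ltop_2c": 4.5, "ptol_2c": 4.5,
    "dimer_2c": 0.12, "conf_1c": 0.12, "plddt_1c": 14.0, "ltop_1c": 5.0,
    "ptol_1c": 5.0, "dimer_1c": 0.12,
}


def _clip_param(name: str, v: np.ndarray) -> np.ndarray:
    if name.startswith("conf"):
        return np.clip(v, 0.0, 1.0)
    if name.startswith("plddt"):
        return np.clip(v, 0.0, 100.0)
    return np.clip(v, 0.0, PAE_MAX)


def gen_score_dataset(
    n_binders: int,
    n_nonbinders: int,
    separation: float = 1.0,
    seed: int | None = None,
    bimodal_1c: bool = False,
    bimodal_weight: float = 0.35,
    sd_scale: float = 1.0,
) -> pd.DataFrame:
    """Class-conditional Gaussian 10-parameter vectors, clipped to range.

    ``separation`` scales the binder/nonbinder mean gap: 1 reproduces the
    default class structure, 0 makes the classes identically distributed
    (a null dataset).  ``sd_scale`` scales every parameter's spread: a
    small value gives cleanly separable classes without pushing means out
    of range.  ``bimodal_1c`` mixes a nonbinder-like component into the
    binders' 1-client scores, emulating weak binders whose half-bound
    predictions look unconvincing.
    """
    if n_binders < 1 or n_nonbinders < 1:
        raise ValueError("need at least one sample per class")
    if sd_scale < 0:
        raise ValueError("sd_scale must be >= 0")
    rng = np.random.default_rng(seed)
    rows = {}
    for p in PARAM_NAMES:
        mu_n = NONBINDER_MEANS[p]
        mu_b = mu_n + separation * (BINDER_MEANS[p] - mu_n)
        sd = sd_scale * SCORE_SDS[p]
        b = rng.normal(mu_b, sd, size=n_binders)
        if bimodal_1c and p.endswith("_1c"):
            weak = rng.random(n_binders) < bimodal_weight
            b = np.where(weak, rng.normal(mu_n, sd, size=n_binders), b)
        n = rng.normal(mu_n, sd, size=n_nonbinders)
        rows[p] = _clip_param(p, np.concatenate([b, n]))
    df = pd.DataFrame(rows)
    df["label"] = ["binder"] * n_binders + ["nonbinder"] * n_nonbinders
    return df


def gen_affinity_relation(
    slope: float,
    intercept: float,
    noise_sd: float,
    n: int,
    seed: int | None = None,
    score_range: tuple[float, float] = (1.0, 10.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Scores and Kd values with a known linear relation plus noise.

    ``kd = slope·score + intercept + N(0, noise_sd)``, floored at a small
    positive value so every Kd is physically meaningful.  Used for
    parameter-recovery checks of the affinity fits.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    rng = np.random.default_rng(seed)
    scores = rng.uniform(*score_range, size=n)
    kd = slope * scores + intercept + rng.normal(0.0, noise_sd, size=n)
    return scores, np.maximum(kd, 0.01)
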