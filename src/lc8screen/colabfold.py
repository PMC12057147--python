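"""Reader for ColabFold-style prediction output directories.

A run directory holds, per predicted structure, a score JSON (per-residue
pLDDT, full PAE matrix, pTM, ipTM) and a PDB coordinate file, plus an
optional ``run.json`` manifest recording the client window and the chain
convention (LC8 protomers first, clients after).  Score JSONs are
authoritative for confidence values; PDBs supply Cα geometry only.

The model-ranking confidence score of a multimer prediction is the
weighted average 0.2·pTM + 0.8·ipTM.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from .windows import SequenceWindow

__all__ = [
    "PAE_MAX",
    "StructureModel",
    "PredictionRun",
    "compute_confidence",
    "parse_run_dir",
]

#: Upper bound of AlphaFold's predicted aligned error, in Å.
PAE_MAX = 31.5

# Accepted JSON key aliases; ColabFold releases differ in naming.
_SCORE_KEYS = {
    "plddt": ("plddt",),
    "pae": ("pae", "predicted_aligned_error"),
    "ptm": ("ptm",),
    "iptm": ("iptm",),
}

_RANK_RE = re.compile(r"rank[_.]?(\d+)")


def compute_confidence(ptm: float, iptm: float) -> float:
    """Model-ranking confidence: 0.2·pTM + 0.8·ipTM."""
    if not (0.0 <= ptm <= 1.0 and 0.0 <= iptm <= 1.0):
        raise ValueError("ptm and iptm must lie in [0, 1]")
    return 0.2 * ptm + 0.8 * iptm


@dataclass
class StructureModel:
    """One predicted structure with its confidence scores and Cα trace.

    ``plddt`` and ``pae`` are indexed over all residues of all chains,
    concatenated in ``chain_layout`` order.  ``coordinates`` maps chain id
    to an (n, 3) array of Cα positions in Å.
    """

    rank: int
    plddt: np.ndarray
    pae: np.ndarray
    ptm: float
    iptm: float
    chain_layout: list[tuple[str, int]]
    coordinates: dict[str, np.ndarray]
    confidence: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.pae = np.asarray(self.pae, dtype=float)
        n = sum(c for _, c in self.chain_layout)
        if self.pae.ndim != 2 or self.pae.shape[0] != self.pae.shape[1]:
            raise ValueError("pae must be a square matrix")
        if self.pae.shape[0] != n:
            raise ValueError("pae side does not match total residue count")
        if self.plddt.shape != (n,):
            raise ValueError("plddt length does not match total residue count")
        if self.pae.min() < 0.0 or self.pae.max() > PAE_MAX:
            raise ValueError(f"pae entries must lie in [0, {PAE_MAX}]")
        if self.plddt.min() < 0.0 or self.plddt.max() > 100.0:
            raise ValueError("plddt values must lie in [0, 100]")
        expected = compute_confidence(self.ptm, self.iptm)
        if self.confidence is None:
            self.confidence = expected
        elif not math.isclose(self.confidence, expected, abs_tol=1e-6):
            raise ValueError("confidence inconsistent with 0.2·pTM + 0.8·ipTM")
        for cid, count in self.chain_layout:
            xyz = self.coordinates.get(cid)
            if xyz is None or len(xyz) != count:
                raise ValueError(f"inconsistent run: chain {cid} coordinate count")

    def chain_slice(self, chain_id: str) -> slice:
        """Global residue-index slice of one chain within plddt/pae."""
        off = 0
        for cid, count in self.chain_layout:
            if cid == chain_id:
                return slice(off, off + count)
            off += count
        raise KeyError(f"unknown chain {chain_id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chain_layout]


@dataclass
class PredictionRun:
    """One co-folding run: ranked structures of LC8₂ plus 1 or 2 clients."""

    run_id: str
    window: SequenceWindow | None
    client_count: int
    structures: list[StructureModel]

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValueError("no structures")
        if self.client_count not in (1, 2):
            raise ValueError("client_count must be 1 or 2")
        layouts = {tuple(s.chain_layout) for s in self.structures}
        if len(layouts) != 1:
            raise ValueError("inconsistent run: structures differ in chain layout")
        self.structures.sort(key=lambda s: s.rank)

    @property
    def lc8_chains(self) -> list[str]:
        return [cid for cid, _ in self.structures[0].chain_layout[:2]]

    @property
    def client_chains(self) -> list[str]:
        return [cid for cid, _ in self.structures[0].chain_layout[2:]]


def _get_score(doc: dict, name: str):
    for key in _SCORE_KEYS[name]:
        if key in doc:
            return doc[key]
    return None


def _read_ca_coords(pdb_path: Path) -> dict[str, np.ndarray]:
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("model", str(pdb_path))
    coords: dict[str, np.ndarray] = {}
    model = next(iter(structure))
    for chain in model:
        xyz = [res["CA"].coord for res in chain if "CA" in res]
        coords[chain.id] = np.asarray(xyz, dtype=float)
    return coords


def _model_from_files(rank: int, scores_path: Path, pdb_path: Path) -> StructureModel:
    doc = json.loads(scores_path.read_text())
    plddt = _get_score(doc, "plddt")
    pae = _get_score(doc, "pae")
    ptm = _get_score(doc, "ptm")
    iptm = _get_score(doc, "iptm")
    if plddt is None or pae is None or ptm is None:
        raise ValueError(f"inconsistent run: missing score keys in {scores_path.name}")
    if iptm is None:
        raise ValueError(
            f"missing iptm in {scores_path.name}: monomer-style score file"
        )
    coords = _read_ca_coords(pdb_path)
    layout = [(cid, len(xyz)) for cid, xyz in coords.items()]
    total = sum(c for _, c in layout)
    if total != len(plddt):
        raise ValueError(
            f"inconsistent run: {total} PDB residues vs {len(plddt)} pLDDT values"
        )
    return StructureModel(
        rank=rank,
        plddt=np.asarray(plddt, dtype=float),
        pae=np.asarray(pae, dtype=float),
        ptm=float(ptm),
        iptm=float(iptm),
        chain_layout=layout,
        coordinates=coords,
    )


def parse_run_dir(path: str | Path) -> PredictionRun:
    """Parse one prediction directory into a :class:`PredictionRun`.

    Prefers a ``run.json`` manifest (written by this package's fixture
    generator and by the ``windows`` pipeline); otherwise falls back to the
    ColabFold filename convention, pairing ``*scores*rank_N*.json`` with
    the PDB file carrying the same rank token.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"not a directory: {path}")
    manifest_path = path / "run.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        window = None
        if manifest.get("window"):
            wd = manifest["window"]
            window = SequenceWindow(
                protein_id=wd["protein_id"],
                start=wd["start"],
                end=wd["end"],
                sequence=wd["sequence"],
                is_mutant=bool(wd.get("is_mutant", False)),
                anchor_offset=wd.get("anchor_offset"),
            )
        models = [
            _model_from_files(m["rank"], path / m["scores"], path / m["pdb"])
            for m in manifest["models"]
        ]
        if not models:
            raise ValueError("no structures")
        return PredictionRun(
            run_id=manifest.get("run_id", path.name),
            window=window,
            client_count=int(manifest["client_count"]),
            structures=models,
        )

    score_files = sorted(p for p in path.glob("*.json") if "scores" in p.name)
    pdb_files = {p.name: p for p in path.glob("*.pdb")}
    models = []
    for sf in score_files:
        m = _RANK_RE.search(sf.name)
        if m is None:
            continue
        rank = int(m.group(1))
        pdb_match = [
            p for name, p in pdb_files.items() if _RANK_RE.search(name)
            and int(_RANK_RE.search(name).group(1)) == rank
        ]
        if not pdb_match:
            raise ValueError(f"inconsistent run: no PDB for rank {rank}")
        models.append(_model_from_files(rank, sf, pdb_match[0]))
    if not models:
        raise ValueError("no structures")
    client_count = len(models[0].chain_layout) - 2
    return PredictionRun(
        run_id=path.name, window=None, client_count=client_count, structures=models
    )
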