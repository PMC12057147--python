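"""Client-window preparation for LC8 co-folding runs.

LC8 (DYNLL1) recognises 8–10-residue linear motifs inside intrinsically
disordered regions.  To scan a full-length client protein for candidate
motifs, its sequence is tiled into short overlapping windows, each of which
is later co-folded with an LC8 dimer.  This module builds those windows,
generates the AAA anchor-mutant nonbinder controls, and writes the
multi-chain FASTA inputs a structure predictor consumes.

Coordinates are 0-based half-open throughout; conversion to the 1-based
residue numbering used in reports happens only at presentation time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "LC8_HUMAN",
    "SequenceWindow",
    "make_windows",
    "mutate_anchor_aaa",
    "write_prediction_fasta",
    "write_window_manifest",
]

#: Human DYNLL1 (LC8), 89 residues.  G63 (1-based) is the groove landmark
#: that defines anchor position 0 of a bound client.  The ortholog used for
#: a run is recorded in output metadata and is configurable per call.
LC8_HUMAN = (
    "MCDRKAVIKNADMSEEMQQDSVECATQALEKYNIEKDIAAHIKKEFDKKYNPTWHCIVGR"
    "NFGSYVTHETKHFIYFYLGQVAILLFKSG"
)

_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

MIN_WINDOW = 10
MAX_WINDOW = 71


@dataclass(frozen=True)
class SequenceWindow:
    """A client subsequence with protein-relative coordinates.

    ``start``/``end`` are 0-based half-open indices into the parent
    protein.  ``anchor_offset`` (window-relative) marks the anchor residue
    when known.  ``is_mutant`` flags AAA anchor-triad mutants, which serve
    as nonbinder controls.
    """

    protein_id: str
    start: int
    end: int
    sequence: str
    is_mutant: bool = False
    anchor_offset: int | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("window coordinates do not match sequence length")
        n = len(self.sequence)
        if not (MIN_WINDOW <= n <= MAX_WINDOW):
            raise ValueError(
                f"window length {n} outside accepted range "
                f"[{MIN_WINDOW}, {MAX_WINDOW}]"
            )
        bad = set(self.sequence) - _AMINO_ACIDS
        if bad:
            raise ValueError(f"non-amino-acid characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple:
        """Identity used when linking 1-client and 2-client runs."""
        return (self.protein_id, self.start, self.end, self.sequence, self.is_mutant)


def _validate_sequence(sequence: str) -> None:
    bad = set(sequence) - _AMINO_ACIDS
    if bad:
        raise ValueError(f"non-amino-acid characters: {sorted(bad)}")


def make_windows(
    sequence: str,
    window: int = 16,
    overlap: int = 8,
    protein_id: str = "protein",
) -> list[SequenceWindow]:
    """Tile ``sequence`` into overlapping windows.

    Windows start at multiples of ``window - overlap``.  When the final
    stride would run past the end of the sequence, one last window is
    anchored at the sequence end instead, so every residue is covered.

    Parameters
    ----------
    sequence : str
        Full protein sequence (standard amino acids).
    window : int, default 16
        Window length in residues.
    overlap : int, default 8
        Overlap between consecutive windows; ``0 <= overlap < window``.

    Returns
    -------
    list of SequenceWindow, ordered by start position.
    """
    if not (0 <= overlap < window):
        raise ValueError("overlap must satisfy 0 <= overlap < window")
    _validate_sequence(sequence)
    n = len(sequence)
    if n < window:
        raise ValueError("sequence too short")
    stride = window - overlap
    starts = list(range(0, n - window + 1, stride))
    if starts[-1] + window < n:
        starts.append(n - window)
    return [
        SequenceWindow(protein_id, s, s + window, sequence[s : s + window])
        for s in starts
    ]


def mutate_anchor_aaa(w: SequenceWindow, anchor_offset: int) -> SequenceWindow:
    """Replace the anchor triad (anchor ± 1) with AAA.

    The anchoring triad (canonically T-Q-T) is the most conserved part of
    an LC8 motif; mutating it to AAA abolishes binding, giving a matched
    nonbinder control with identical context.
    """
    if not (1 <= anchor_offset <= w.length - 2):
        raise ValueError("triad out of bounds")
    seq = (
        w.sequence[: anchor_offset - 1] + "AAA" + w.sequence[anchor_offset + 2 :]
    )
    return replace(w, sequence=seq, is_mutant=True, anchor_offset=anchor_offset)


def _record_id(w: SequenceWindow, chain_role: str, client_count: int) -> str:
    tag = "AAA" if w.is_mutant else "WT"
    return f"{w.protein_id}|{w.start}-{w.end}|{tag}|{client_count}c|{chain_role}"


def write_prediction_fasta(
    w: SequenceWindow,
    client_count: int,
    path: str | Path,
    lc8_sequence: str = LC8_HUMAN,
) -> Path:
    """Write the multi-record FASTA input for one co-folding run.

    The record order encodes the chain convention used downstream: two LC8
    protomers first, then ``client_count`` copies of the client window.
    """
    if client_count not in (1, 2):
        raise ValueError("client_count must be 1 or 2")
    if not lc8_sequence:
        raise ValueError("lc8_sequence must be nonempty")
    _validate_sequence(lc8_sequence)
    records = [
        SeqRecord(Seq(lc8_sequence), id=_record_id(w, "LC8_A", client_count), description=""),
        SeqRecord(Seq(lc8_sequence), id=_record_id(w, "LC8_B", client_count), description=""),
    ]
    for i in range(client_count):
        records.append(
            SeqRecord(
                Seq(w.sequence),
                id=_record_id(w, f"client_{'CD'[i]}", client_count),
                description="",
            )
        )
    path = Path(path)
    SeqIO.write(records, str(path), "fasta")
    return path


def write_window_manifest(windows: list[SequenceWindow], path: str | Path) -> Path:
    """Write a CSV manifest of generated windows (one row per window)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["protein_id", "start", "end", "sequence", "is_mutant", "anchor_offset"])
        for w in windows:
            wr.writerow(
                [w.protein_id, w.start, w.end, w.sequence, int(w.is_mutant),
                 "" if w.anchor_offset is None else w.anchor_offset]
            )
    return path
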