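"""Qualitative-Bayesian evidence ledger with decibel log-odds.

Competing hypotheses are compared pairwise on a log-odds scale in
decibels: 10·log₁₀ of the likelihood ratio of one piece of evidence under
the two hypotheses.  Because independent evidence multiplies likelihoods,
the dB contributions simply add, and a prior enters as one more additive
offset.  A third pairwise comparison sharing a base hypothesis follows by
subtraction: dB(A/C) = dB(A/B) − dB(C/B).

The packaged example ledger scores nine observations from an LC8
binder/nonbinder co-folding screen against three hypotheses about the
structure predictor — that it memorised structures (Hs), learned the
natural energy function (Hn), or learned an inaccurate energy function
sharing the natural minima (Hi).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "EvidenceItem",
    "HypothesisComparison",
    "total",
    "derive",
    "load_ledger",
    "save_ledger",
    "example_ledger",
    "totals_report",
]


@dataclass(frozen=True)
class EvidenceItem:
    """One piece of evidence with its dB contribution per comparison."""

    id: str
    description: str
    contributions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "contributions",
                           {k: float(v) for k, v in self.contributions.items()})


@dataclass
class HypothesisComparison:
    """An aggregated pairwise comparison: prior + summed evidence, in dB."""

    name: str
    prior_db: float = 0.0
    evidence_db: float = 0.0

    @property
    def total_db(self) -> float:
        return self.prior_db + self.evidence_db


def total(
    ledger: Iterable[EvidenceItem], comparison: str, prior_db: float = 0.0
) -> float:
    """Grand total for one comparison: prior plus the sum of contributions.

    An item that does not define the comparison contributes 0 dB (with a
    warning), since silence on a comparison is not evidence either way.
    """
    s = prior_db
    for item in ledger:
        if comparison in item.contributions:
            s += item.contributions[comparison]
        else:
            warnings.warn(
                f"evidence {item.id} defines no contribution for {comparison!r}; "
                "treated as 0 dB"
            )
    return s


def derive(comparison_ab: float, comparison_cb: float) -> float:
    """dB of A vs C from A-vs-B and C-vs-B (shared base hypothesis B)."""
    return comparison_ab - comparison_cb


def totals_report(
    ledger: list[EvidenceItem], priors: Mapping[str, float] | None = None
) -> dict[str, HypothesisComparison]:
    """Aggregate every comparison present in the ledger."""
    priors = priors or {}
    names = sorted({c for item in ledger for c in item.contributions})
    out = {}
    for name in names:
        ev = total(ledger, name)
        out[name] = HypothesisComparison(name=name, prior_db=priors.get(name, 0.0),
                                         evidence_db=ev)
    return out


def load_ledger(path: str | Path) -> list[EvidenceItem]:
    """Load a ledger from YAML (list of {id, description, contributions})."""
    doc = yaml.safe_load(Path(path).read_text())
    return [
        EvidenceItem(id=e["id"], description=e.get("description", ""),
                     contributions=e.get("contributions", {}))
        for e in doc["evidence"]
    ]


def save_ledger(ledger: Iterable[EvidenceItem], path: str | Path) -> Path:
    path = Path(path)
    doc = {"evidence": [
        {"id": e.id, "description": e.description,
         "contributions": dict(e.contributions)}
        for e in ledger
    ]}
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def example_ledger() -> list[EvidenceItem]:
    """The packaged nine-item energy-function evidence ledger."""
    ref = resources.files("lc8screen.data") / "energy_function_evidence.yaml"
    with resources.as_file(ref) as path:
        return load_ledger(path)


def export_totals_csv(
    report: Mapping[str, HypothesisComparison], path: str | Path
) -> Path:
    """CSV export of a totals report (bar-chart friendly layout)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["comparison", "prior_db", "evidence_db", "total_db"])
        for name, cmp_ in sorted(report.items()):
            wr.writerow([name, cmp_.prior_db, cmp_.evidence_db, cmp_.total_db])
    return path
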