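"""Tallying findings and the accept/reject decision.

The rejection thresholds, applied independent of dataset size, are:

* a QC killer (missing raw data, shuffled genotypes) — reject outright;
* more than seven errors in total;
* more than five errors of one category;
* more than five total errors from three or more categories;
* errors from more than three categories.

"Errors" are confirmed occurrences: unconfirmed suspects (allele-call
plausibility, lost intermediates) do not count but block a PASS until
adjudicated (status PENDING).  On a PASS a unique, permanent accession
number is issued, idempotent per dataset content.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .ce_checks import ErrorCategory, ErrorFinding
from .io import Dataset

__all__ = [
    "QCCounts",
    "QCVerdict",
    "tally",
    "decide",
    "AccessionLedger",
    "assign_accession",
]


@dataclass
class QCCounts:
    """Confirmed-occurrence totals feeding the decision rules."""

    per_category: dict[str, int] = field(default_factory=dict)
    killer_present: bool = False
    unresolved_suspects: int = 0

    @property
    def total(self) -> int:
        return sum(self.per_category.values())

    @property
    def categories_present(self) -> int:
        return sum(1 for v in self.per_category.values() if v > 0)

    @property
    def max_category(self) -> int:
        return max(self.per_category.values(), default=0)


@dataclass
class QCVerdict:
    status: str  # PASS | REJECT | PENDING
    triggered_rules: list[str] = field(default_factory=list)
    accession: Optional[str] = None
    unresolved_suspects: int = 0

    def __post_init__(self) -> None:
        if self.status not in ("PASS", "REJECT", "PENDING"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "REJECT" and not self.triggered_rules:
            raise ValueError("REJECT requires at least one triggered rule")


def tally(findings: Sequence[ErrorFinding], mps: bool = False) -> QCCounts:
    """Aggregate findings into decision inputs.

    Only confirmed error findings count; killers set ``killer_present``
    instead of contributing occurrences.  For MPS datasets, findings
    confined to the declared CE-translation table are excluded.
    """
    counts = QCCounts()
    for f in findings:
        if mps and f.ce_table_only:
            continue
        if not f.is_error:
            continue
        if f.category is ErrorCategory.QC_KILLER:
            counts.killer_present = True
            continue
        if not f.confirmed:
            if not f.resolved:
                counts.unresolved_suspects += 1
            continue
        key = f.category.value
        counts.per_category[key] = counts.per_category.get(key, 0) + f.occurrences
    return counts


def decide(counts: QCCounts) -> QCVerdict:
    """Apply the rejection thresholds to a tally.

    Boundary behaviour is exact: 7 total errors pass, 8 reject; 5 in one
    category pass, 6 reject; 5 total over >= 3 categories pass, 6 reject;
    3 categories pass, 4 reject.  The three-or-more reading of the combined
    rule keeps the final more-than-three-categories rule non-redundant.
    """
    rules = []
    if counts.killer_present:
        rules.append("qc-killer")
    if counts.total > 7:
        rules.append("total>7")
    if counts.max_category > 5:
        rules.append("category>5")
    if counts.categories_present >= 3 and counts.total > 5:
        rules.append("total>5-from->=3-categories")
    if counts.categories_present > 3:
        rules.append("categories>3")
    if rules:
        return QCVerdict(
            status="REJECT",
            triggered_rules=rules,
            unresolved_suspects=counts.unresolved_suspects,
        )
    if counts.unresolved_suspects > 0:
        return QCVerdict(
            status="PENDING", unresolved_suspects=counts.unresolved_suspects
        )
    return QCVerdict(status="PASS")


# --- accession numbers -------------------------------------------------------

_BASE36 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _check_character(sequence: int, width: int = 6) -> str:
    """Weighted modulo-36 check character over the zero-padded digits."""
    digits = f"{sequence:0{width}d}"
    total = sum((i + 1) * int(c) for i, c in enumerate(digits))
    return _BASE36[total % 36]


def format_accession(sequence: int, prefix: str = "STRQC") -> str:
    return f"{prefix}{sequence:06d}{_check_character(sequence)}"


class AccessionLedger:
    """Append-only ledger mapping dataset content hashes to accessions.

    Re-submitting byte-identical content re-issues the same accession;
    distinct content always receives a fresh sequential number.  The ledger
    persists as JSON lines when a path is given, or lives in memory.
    """

    def __init__(self, path: Optional[str] = None, prefix: str = "STRQC"):
        self.path = Path(path) if path else None
        self.prefix = prefix
        self._by_hash: dict[str, str] = {}
        self._next = 1
        if self.path and self.path.exists():
            with open(self.path, "r", encoding="utf-8") as fh:
                for line in fh:
                    if not line.strip():
                        continue
                    entry = json.loads(line)
                    self._by_hash[entry["content_hash"]] = entry["accession"]
                    self._next = max(self._next, entry["sequence"] + 1)

    def issue(self, content_hash: str) -> str:
        if content_hash in self._by_hash:
            return self._by_hash[content_hash]
        sequence = self._next
        accession = format_accession(sequence, self.prefix)
        self._next += 1
        self._by_hash[content_hash] = accession
        if self.path:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(
                    json.dumps(
                        {
                            "content_hash": content_hash,
                            "accession": accession,
                            "sequence": sequence,
                        }
                    )
                    + "\n"
                )
        return accession


def assign_accession(dataset: Dataset, ledger: AccessionLedger) -> str:
    """Issue (or re-issue) the accession for a dataset's content."""
    return ledger.issue(dataset.content_hash())
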