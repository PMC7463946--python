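"""Locus catalog: canonical STR locus identities and the allele-designation grammar.

Forensic STR alleles are named by repeat count on a per-locus repeat unit
(typically 4 bp).  Microvariant ("intermediate") alleles carry an incomplete
repeat unit and are written with a dot: ``9.3`` means 9 full repeats plus
3 bases.  Every detector in :mod:`strqc.ce_checks` consults this module, so
the catalog is configuration, not code: a :class:`LocusCatalog` can be built
from a YAML file (see ``data/default_catalog.yaml`` for the schema) or
constructed programmatically with toy loci for testing.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import yaml

__all__ = [
    "AlleleStatus",
    "AlleleDesignation",
    "RepeatBlock",
    "LocusSpec",
    "LocusCatalog",
    "IncomparableAllelesError",
    "parse_allele",
    "parse_numeric_lenient",
    "parse_amelogenin_genotype",
    "compare_alleles",
    "damerau_levenshtein",
    "load_catalog",
    "default_catalog",
]


class AlleleStatus(str, Enum):
    VALID_NUMERIC = "VALID_NUMERIC"
    VALID_SEX = "VALID_SEX"
    PLACEHOLDER = "PLACEHOLDER"
    INVALID = "INVALID"


@dataclass(frozen=True)
class AlleleDesignation:
    """One parsed allele designation, as submitted.

    ``whole_repeats``/``partial_bases`` are populated only for
    ``VALID_NUMERIC``; ``sex_symbol`` only for ``VALID_SEX``; ``reason`` is a
    machine-readable token explaining ``INVALID``/``PLACEHOLDER`` status.
    """

    raw_text: str
    status: AlleleStatus
    whole_repeats: Optional[int] = None
    partial_bases: Optional[int] = None
    sex_symbol: Optional[str] = None
    reason: Optional[str] = None

    @property
    def is_numeric(self) -> bool:
        return self.status is AlleleStatus.VALID_NUMERIC

    def total_bases(self, repeat_unit_length: int) -> int:
        if not self.is_numeric:
            raise IncomparableAllelesError(
                f"designation {self.raw_text!r} is not numeric"
            )
        return self.whole_repeats * repeat_unit_length + self.partial_bases

    def normalized(self) -> str:
        """Canonical string form: ``12`` or ``9.3``."""
        if not self.is_numeric:
            raise IncomparableAllelesError(
                f"designation {self.raw_text!r} is not numeric"
            )
        if self.partial_bases:
            return f"{self.whole_repeats}.{self.partial_bases}"
        return str(self.whole_repeats)


@dataclass(frozen=True)
class RepeatBlock:
    """One motif block of an MPS repeat structure.

    ``counted`` blocks contribute their repeat count to the length-based
    (CE-equivalent) allele designation; uncounted blocks are fixed spacers.
    """

    motif: str
    min_count: int = 0
    max_count: int = 1000
    counted: bool = True

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("repeat block motif must be non-empty")
        if self.min_count > self.max_count:
            raise ValueError("min_count > max_count")


@dataclass
class LocusSpec:
    """Constraints and identity for one STR locus."""

    canonical_name: str
    aliases: frozenset[str] = frozenset()
    repeat_unit_length: int = 4
    allele_range: tuple[float, float] = (1.0, 50.0)
    allowed_partials: Optional[frozenset[int]] = None
    observed_alleles: Optional[frozenset[str]] = None
    is_sex_marker: bool = False
    expected_intermediates: tuple[tuple[str, float], ...] = ()
    repeat_structure: Optional[tuple[RepeatBlock, ...]] = None
    flank_5: Optional[str] = None
    flank_3: Optional[str] = None

    def __post_init__(self) -> None:
        if self.allowed_partials is None:
            # default: any partial shorter than the repeat unit
            self.allowed_partials = frozenset(range(1, self.repeat_unit_length))
        lo, hi = self.allele_range
        if lo > hi:
            raise ValueError(f"{self.canonical_name}: allele_range min > max")
        if any(p >= self.repeat_unit_length or p < 1 for p in self.allowed_partials):
            raise ValueError(
                f"{self.canonical_name}: allowed partials must lie in "
                f"1..{self.repeat_unit_length - 1}"
            )
        if self.repeat_structure is not None:
            if not any(b.counted for b in self.repeat_structure):
                raise ValueError(
                    f"{self.canonical_name}: repeat structure needs >=1 counted block"
                )
            if not (self.flank_5 and self.flank_3):
                raise ValueError(
                    f"{self.canonical_name}: repeat structure requires flank anchors"
                )

    def designation_value(self, text: str) -> Optional[float]:
        """Numeric value (repeats + partial/unit) of a designation, or None."""
        d = parse_numeric_lenient(text, self)
        if d is None:
            return None
        return d.whole_repeats + d.partial_bases / self.repeat_unit_length

    def in_range(self, d: AlleleDesignation) -> bool:
        v = d.whole_repeats + d.partial_bases / self.repeat_unit_length
        lo, hi = self.allele_range
        return lo <= v <= hi


class IncomparableAllelesError(ValueError):
    """Raised when ordering is requested for non-numeric designations."""


def _normalize_locus_name(name: str) -> str:
    return re.sub(r"[\s\-_]+", "", name).casefold()


PLACEHOLDER_DESIGNATIONS = frozenset({"1", "99"})

_NUMERIC_RE = re.compile(r"(?P<whole>\d+)(?:\.(?P<partial>\d+))?")


def parse_allele(
    text: str,
    spec: LocusSpec,
    accept_rare_placeholders: bool = False,
) -> AlleleDesignation:
    """Parse one submitted allele designation against a locus spec.

    Never raises on malformed input: anything outside the forensic
    designation grammar comes back ``INVALID`` with a reason token.  The
    plausibility policy is two-tiered: designations beyond an extended
    window (more than twice the locus range maximum) are grammar-level
    rejections here, while in-window but out-of-range values parse as
    ``VALID_NUMERIC`` and are left to the allele-call plausibility check.
    """
    raw = text
    text = text.strip()
    if not text:
        return AlleleDesignation(raw, AlleleStatus.INVALID, reason="empty")

    if spec.is_sex_marker:
        sym = text.upper()
        if sym in ("X", "Y"):
            return AlleleDesignation(raw, AlleleStatus.VALID_SEX, sex_symbol=sym)
        return AlleleDesignation(
            raw, AlleleStatus.INVALID, reason="impossible-sex-allele"
        )

    if text in PLACEHOLDER_DESIGNATIONS:
        if accept_rare_placeholders:
            return AlleleDesignation(
                raw, AlleleStatus.PLACEHOLDER, reason="rare-allele-placeholder"
            )
        return AlleleDesignation(
            raw, AlleleStatus.INVALID, reason="placeholder-not-accepted"
        )

    if "," in text:
        return AlleleDesignation(raw, AlleleStatus.INVALID, reason="comma-separator")
    if "+" in text or "-" in text or "−" in text:
        return AlleleDesignation(raw, AlleleStatus.INVALID, reason="sign-character")
    if re.search(r"[A-Za-z]", text):
        return AlleleDesignation(raw, AlleleStatus.INVALID, reason="letter-designation")

    m = _NUMERIC_RE.fullmatch(text)
    if m is None:
        return AlleleDesignation(raw, AlleleStatus.INVALID, reason="bad-character")

    whole = int(m.group("whole"))
    partial = int(m.group("partial")) if m.group("partial") is not None else 0

    if whole == 0 and partial == 0:
        return AlleleDesignation(raw, AlleleStatus.INVALID, reason="zero")
    if partial >= spec.repeat_unit_length:
        return AlleleDesignation(
            raw, AlleleStatus.INVALID, reason="partial-ge-repeat-unit"
        )
    if partial and partial not in spec.allowed_partials:
        return AlleleDesignation(
            raw, AlleleStatus.INVALID, reason="partial-not-allowed"
        )
    if whole == 0:
        return AlleleDesignation(raw, AlleleStatus.INVALID, reason="zero")
    if whole > 2 * spec.allele_range[1] or whole < 1:
        return AlleleDesignation(
            raw, AlleleStatus.INVALID, reason="implausible-repeat-number"
        )
    return AlleleDesignation(
        raw, AlleleStatus.VALID_NUMERIC, whole_repeats=whole, partial_bases=partial
    )


def parse_numeric_lenient(text: str, spec: LocusSpec) -> Optional[AlleleDesignation]:
    """Grammar-only numeric parse ignoring the plausibility window.

    Used where a numeric value is needed for alleles that may legitimately
    belong to a different locus (locus-swap detection).  Returns None if the
    text is not of the form ``whole[.partial]`` with partial < unit length.
    """
    m = _NUMERIC_RE.fullmatch(text.strip())
    if m is None:
        return None
    whole = int(m.group("whole"))
    partial = int(m.group("partial")) if m.group("partial") is not None else 0
    if whole == 0 or partial >= spec.repeat_unit_length:
        return None
    return AlleleDesignation(
        text, AlleleStatus.VALID_NUMERIC, whole_repeats=whole, partial_bases=partial
    )


def parse_amelogenin_genotype(
    a: str, b: str
) -> tuple[bool, list[str]]:
    """Validate a sex-marker genotype; Y|Y is biologically impossible.

    Returns ``(valid, problems)`` where problems are message strings; the
    caller turns them into findings rather than exceptions.
    """
    problems: list[str] = []
    symbols = []
    for raw in (a, b):
        sym = raw.strip().upper()
        if sym in ("X", "Y"):
            symbols.append(sym)
        else:
            problems.append(f"impossible amelogenin allele {raw.strip()!r}")
    if len(symbols) == 2 and symbols[0] == "Y" and symbols[1] == "Y":
        problems.append("impossible amelogenin genotype Y|Y")
    return (not problems, problems)


def compare_alleles(a: AlleleDesignation, b: AlleleDesignation, spec: LocusSpec) -> int:
    """Total-base-length ordering of two numeric designations at one locus."""
    ta = a.total_bases(spec.repeat_unit_length)
    tb = b.total_bases(spec.repeat_unit_length)
    return (ta > tb) - (ta < tb)


def damerau_levenshtein(a: str, b: str) -> int:
    """Edit distance with adjacent transpositions (optimal string alignment)."""
    la, lb = len(a), len(b)
    d = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        d[i][0] = i
    for j in range(lb + 1):
        d[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1, d[i - 1][j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                d[i][j] = min(d[i][j], d[i - 2][j - 2] + 1)
    return d[la][lb]


class LocusCatalog:
    """An immutable collection of :class:`LocusSpec` with name resolution.

    Lookup is insensitive to case, spaces and hyphens; aliases resolve to
    the canonical name.  A name that exactly matches one locus is never
    fuzzy-merged into another (``D2S441`` stays distinct from ``D2S411``).
    """

    def __init__(self, specs: Iterable[LocusSpec]):
        self._specs: dict[str, LocusSpec] = {}
        self._index: dict[str, str] = {}
        for spec in specs:
            if spec.canonical_name in self._specs:
                raise ValueError(f"duplicate canonical name {spec.canonical_name!r}")
            self._specs[spec.canonical_name] = spec
            for name in {spec.canonical_name, *spec.aliases}:
                key = _normalize_locus_name(name)
                if key in self._index and self._index[key] != spec.canonical_name:
                    raise ValueError(
                        f"name {name!r} collides between "
                        f"{self._index[key]!r} and {spec.canonical_name!r}"
                    )
                self._index[key] = spec.canonical_name

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def __contains__(self, name: str) -> bool:
        return _normalize_locus_name(name) in self._index

    @property
    def canonical_names(self) -> list[str]:
        return list(self._specs)

    def get(self, name: str) -> Optional[LocusSpec]:
        canonical = self._index.get(_normalize_locus_name(name))
        return self._specs[canonical] if canonical else None

    def canonicalize(
        self, name: str, max_distance: int = 2, max_suggestions: int = 3
    ) -> tuple[Optional[str], list[str]]:
        """Resolve a submitted locus name.

        Returns ``(canonical_name, [])`` on an exact (normalized) match and
        ``(None, suggestions)`` otherwise, suggestions ranked by
        Damerau-Levenshtein distance (ties broken alphabetically).
        """
        key = _normalize_locus_name(name)
        if not key:
            return None, []
        if key in self._index:
            return self._index[key], []
        scored = []
        for cand_key, canonical in self._index.items():
            dist = damerau_levenshtein(key, cand_key)
            if dist <= max_distance:
                scored.append((dist, canonical))
        scored.sort(key=lambda t: (t[0], t[1]))
        seen: list[str] = []
        for _, canonical in scored:
            if canonical not in seen:
                seen.append(canonical)
        return None, seen[:max_suggestions]


# --- catalog (de)serialization -------------------------------------------

def _spec_from_mapping(record: Mapping) -> LocusSpec:
    blocks = None
    if record.get("repeat_structure"):
        blocks = tuple(
            RepeatBlock(
                motif=str(b["motif"]).upper(),
                min_count=int(b.get("min_count", 0)),
                max_count=int(b.get("max_count", 1000)),
                counted=bool(b.get("counted", True)),
            )
            for b in record["repeat_structure"]
        )
    intermediates = tuple(
        (str(x[0]), float(x[1])) for x in record.get("expected_intermediates", [])
    )
    return LocusSpec(
        canonical_name=str(record["name"]),
        aliases=frozenset(str(a) for a in record.get("aliases", [])),
        repeat_unit_length=int(record.get("repeat_unit_length", 4)),
        allele_range=tuple(float(v) for v in record.get("allele_range", [1, 50])),
        allowed_partials=(
            frozenset(int(p) for p in record["allowed_partials"])
            if "allowed_partials" in record
            else None
        ),
        observed_alleles=(
            frozenset(str(a) for a in record["observed_alleles"])
            if "observed_alleles" in record
            else None
        ),
        is_sex_marker=bool(record.get("is_sex_marker", False)),
        expected_intermediates=intermediates,
        repeat_structure=blocks,
        flank_5=record.get("flank_5"),
        flank_3=record.get("flank_3"),
    )


def load_catalog(path) -> LocusCatalog:
    """Load a locus catalog from a YAML file (see the shipped default
    catalog for the schema: a top-level ``loci`` list of records)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "loci" not in doc:
        raise ValueError(f"{path}: catalog file must contain a top-level 'loci' list")
    return LocusCatalog(_spec_from_mapping(rec) for rec in doc["loci"])


def default_catalog() -> LocusCatalog:
    """The catalog of common forensic autosomal loci shipped with the package."""
    ref = importlib.resources.files("strqc").joinpath("data/default_catalog.yaml")
    with importlib.resources.as_file(ref) as path:
        return load_catalog(path)
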