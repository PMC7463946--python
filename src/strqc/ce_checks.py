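"""Error detectors for CE genotype-table submissions.

Each detector scans a :class:`~strqc.io.Dataset` and returns located
:class:`ErrorFinding` objects; none of them raises on bad data — bad data is
the subject matter.  The twelve categories cover the defects recurrently
seen in forensic STR population datasets: duplicated profiles, descending
allele pairs, non-conforming allele designations, implausible allele calls,
incomplete genotypes, wrong locus names, aneuploid cells, unassessable
submissions (missing raw data / shuffled genotypes), identifier collisions,
metadata mismatches, whole-column locus swaps and intermediate alleles lost
to rounding.

Counting conventions (used by the decision engine): a cell-scope finding
contributes one occurrence; a group of c identical profiles contributes
c − 1; dataset- and locus-scope findings contribute one.  Suspect findings
(allele-call plausibility, lost intermediates) start unconfirmed and only
count toward rejection after adjudication against raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .catalog import (
    AlleleStatus,
    LocusCatalog,
    LocusSpec,
    compare_alleles,
    parse_allele,
    parse_amelogenin_genotype,
    parse_numeric_lenient,
)
from .io import Dataset, GenotypeRecord

__all__ = [
    "ErrorCategory",
    "ErrorFinding",
    "Adjudication",
    "apply_adjudications",
    "check_identical_genotypes",
    "check_allele_order",
    "check_allele_nomenclature",
    "check_allele_plausibility",
    "check_completeness",
    "check_locus_names",
    "check_ploidy",
    "check_killers",
    "check_raw_concordance",
    "check_identifiers",
    "check_metadata_match",
    "check_locus_swap",
    "check_lost_intermediates",
]


class ErrorCategory(str, Enum):
    IDENTICAL_GENOTYPES = "IDENTICAL_GENOTYPES"
    NON_ASCENDING = "NON_ASCENDING"
    ALLELE_NOMENCLATURE = "ALLELE_NOMENCLATURE"
    ALLELE_CALL_SUSPECT = "ALLELE_CALL_SUSPECT"
    INCOMPLETE_GENOTYPE = "INCOMPLETE_GENOTYPE"
    LOCUS_NOMENCLATURE = "LOCUS_NOMENCLATURE"
    ANEUPLOIDY = "ANEUPLOIDY"
    QC_KILLER = "QC_KILLER"
    DUPLICATE_IDENTIFIER = "DUPLICATE_IDENTIFIER"
    INFO_MISMATCH = "INFO_MISMATCH"
    LOCUS_SWAP = "LOCUS_SWAP"
    LOST_INTERMEDIATE = "LOST_INTERMEDIATE"
    # MPS-specific categories
    ERRONEOUS_SEQUENCE = "ERRONEOUS_SEQUENCE"
    SEQUENCE_ORIENTATION = "SEQUENCE_ORIENTATION"
    CE_TRANSLATION = "CE_TRANSLATION"
    EXPECTED_FR_DISCREPANCY = "EXPECTED_FR_DISCREPANCY"
    INSUFFICIENT_FLANK = "INSUFFICIENT_FLANK"


#: categories whose findings start unconfirmed and need raw-data adjudication
SUSPECT_CATEGORIES = frozenset(
    {ErrorCategory.ALLELE_CALL_SUSPECT, ErrorCategory.LOST_INTERMEDIATE}
)


@dataclass
class ErrorFinding:
    """One located, categorized defect.

    ``occurrences`` is the finding's contribution to the rejection tallies;
    ``confirmed`` is False for suspects awaiting raw-data adjudication and
    ``resolved`` flips once an adjudication has been applied.  ``is_error``
    is False for informational findings (expected flanking-region
    discrepancies) that never count toward a verdict; ``ce_table_only``
    marks findings confined to the declared CE-translation table of an MPS
    submission, which are reported but excluded from the MPS verdict.
    """

    category: ErrorCategory
    scope: str  # cell | record | locus | dataset
    message: str
    sample_ids: list[str] = field(default_factory=list)
    locus: Optional[str] = None
    occurrences: int = 1
    confirmed: bool = True
    resolved: bool = False
    is_error: bool = True
    ce_table_only: bool = False
    mps: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.occurrences < 1:
            raise ValueError("occurrences must be >= 1")
        if self.scope not in ("cell", "record", "locus", "dataset"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.scope == "cell" and (len(self.sample_ids) != 1 or not self.locus):
            raise ValueError("cell-scope findings name exactly one sample and locus")


Adjudication = tuple  # (sample_id, locus, decision) with decision in
#                       {"confirmed_error", "verified_correct"}


def apply_adjudications(
    findings: Sequence[ErrorFinding], adjudications: Iterable[Adjudication]
) -> list[ErrorFinding]:
    """Resolve suspect findings against raw-data adjudications.

    ``confirmed_error`` confirms the finding (it now counts toward the
    verdict); ``verified_correct`` resolves it as a false alarm.  A
    locus-scope suspect (lost intermediates) matches on locus alone; pass
    an empty sample id for those.  Returns the same finding objects.
    """
    for sample_id, locus, decision in adjudications:
        if decision not in ("confirmed_error", "verified_correct"):
            raise ValueError(f"unknown adjudication decision {decision!r}")
        for f in findings:
            if f.category not in SUSPECT_CATEGORIES or f.resolved:
                continue
            if f.locus != locus:
                continue
            if f.scope != "locus" and sample_id not in f.sample_ids:
                continue
            f.resolved = True
            f.confirmed = decision == "confirmed_error"
    return list(findings)


# --- shared helpers --------------------------------------------------------

def _resolved_loci(
    dataset: Dataset, catalog: LocusCatalog
) -> list[tuple[str, Optional[LocusSpec]]]:
    """Raw header name -> catalog spec (None when unknown)."""
    return [(locus, catalog.get(locus)) for locus in dataset.loci]


def _is_zero_zero(alleles: Sequence[str]) -> bool:
    return len(alleles) == 2 and all(a.strip() == "0" for a in alleles)


def _complete_profile(
    record: GenotypeRecord, loci: Sequence[str]
) -> dict[str, tuple[str, str]]:
    """Unordered diploid pairs per locus, skipping untyped/aneuploid cells."""
    out = {}
    for locus in loci:
        pair = record.unordered_genotype(locus)
        if pair is not None and not _is_zero_zero(pair):
            out[locus] = pair
    return out


# --- (i) identical genotypes ----------------------------------------------

def _profiles_match(
    pa: dict[str, tuple[str, str]],
    pb: dict[str, tuple[str, str]],
    min_shared_loci: int,
) -> bool:
    """True when the two profiles agree at > min_shared_loci co-typed loci
    with zero disagreements at any co-typed locus."""
    shared = 0
    for locus, pair in pa.items():
        other = pb.get(locus)
        if other is None:
            continue
        if other != pair:
            return False
        shared += 1
    return shared > min_shared_loci


def check_identical_genotypes(
    dataset: Dataset,
    pool: Optional[Sequence[Dataset]] = None,
    min_shared_loci: int = 15,
) -> list[ErrorFinding]:
    """Detect repeated profiles within the dataset and against a pool.

    Two profiles are duplicates when they agree (as unordered allele pairs)
    at strictly more than ``min_shared_loci`` co-typed complete loci and
    disagree nowhere they are co-typed.  A group of c identical profiles
    yields one finding with c − 1 occurrences.  Allele order within a cell
    is ignored, so non-ascending pairs cannot mask duplicates.
    """
    profiles = [_complete_profile(r, dataset.loci) for r in dataset.records]
    n = len(profiles)
    # union-find over matching pairs
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _profiles_match(profiles[i], profiles[j], min_shared_loci):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    findings = []
    for members in groups.values():
        if len(members) < 2:
            continue
        ids = [dataset.records[i].sample_id for i in members]
        findings.append(
            ErrorFinding(
                category=ErrorCategory.IDENTICAL_GENOTYPES,
                scope="record",
                message=(
                    f"{len(members)} identical profiles "
                    f"(> {min_shared_loci} shared loci): {', '.join(ids)}"
                ),
                sample_ids=ids,
                occurrences=len(members) - 1,
            )
        )

    for ext in pool or []:
        ext_profiles = [_complete_profile(r, ext.loci) for r in ext.records]
        matched: list[tuple[str, str]] = []
        for i, pa in enumerate(profiles):
            for j, pb in enumerate(ext_profiles):
                if _profiles_match(pa, pb, min_shared_loci):
                    matched.append(
                        (dataset.records[i].sample_id, ext.records[j].sample_id)
                    )
        if matched:
            findings.append(
                ErrorFinding(
                    category=ErrorCategory.IDENTICAL_GENOTYPES,
                    scope="dataset",
                    message=(
                        f"{len(matched)} profile(s) also present in "
                        f"{ext.metadata.population_name or ext.source_path}: "
                        + "; ".join(f"{a}~{b}" for a, b in matched[:10])
                    ),
                    sample_ids=[a for a, _ in matched],
                    occurrences=len(matched),
                )
            )
    return findings


# --- (ii) non-ascending allele pairs --------------------------------------

def check_allele_order(dataset: Dataset, catalog: LocusCatalog) -> list[ErrorFinding]:
    """Flag diploid cells whose alleles are not reported in ascending order.

    Ordering is by total base length (microvariant 9.3 sorts between 9 and
    10); homozygous pairs pass.  Only cells where both designations parse
    numerically are assessed.
    """
    findings = []
    for locus, spec in _resolved_loci(dataset, catalog):
        if spec is None or spec.is_sex_marker:
            continue
        for rec in dataset.records:
            alleles = rec.genotypes.get(locus, [])
            if len(alleles) != 2:
                continue
            a = parse_allele(alleles[0], spec)
            b = parse_allele(alleles[1], spec)
            if a.is_numeric and b.is_numeric and compare_alleles(a, b, spec) > 0:
                findings.append(
                    ErrorFinding(
                        category=ErrorCategory.NON_ASCENDING,
                        scope="cell",
                        message=f"alleles {alleles[0]}|{alleles[1]} not in ascending order",
                        sample_ids=[rec.sample_id],
                        locus=locus,
                    )
                )
    return findings


# --- (iii) allele nomenclature --------------------------------------------

def check_allele_nomenclature(
    dataset: Dataset,
    catalog: LocusCatalog,
    accept_rare_placeholders: bool = False,
) -> list[ErrorFinding]:
    """Flag designations outside the forensic nomenclature grammar.

    One finding per offending cell.  Sex-marker cells are validated as
    genotypes (Y|Y is impossible even though Y is a valid symbol).  Cells
    that are exactly ``0|0`` are left to the incomplete-genotype check.
    ``1``/``99`` placeholders produce no finding only when
    ``accept_rare_placeholders`` is set.
    """
    findings = []
    for locus, spec in _resolved_loci(dataset, catalog):
        if spec is None:
            continue
        for rec in dataset.records:
            alleles = rec.genotypes.get(locus, [])
            if not alleles or _is_zero_zero(alleles):
                continue
            problems: list[str] = []
            if spec.is_sex_marker and len(alleles) == 2:
                _, problems = parse_amelogenin_genotype(alleles[0], alleles[1])
            else:
                for raw in alleles:
                    d = parse_allele(raw, spec, accept_rare_placeholders)
                    if d.status is AlleleStatus.INVALID:
                        problems.append(f"{raw!r}: {d.reason}")
            if problems:
                findings.append(
                    ErrorFinding(
                        category=ErrorCategory.ALLELE_NOMENCLATURE,
                        scope="cell",
                        message="; ".join(problems),
                        sample_ids=[rec.sample_id],
                        locus=locus,
                    )
                )
    return findings


# --- (iv) allele-call plausibility ----------------------------------------

def check_allele_plausibility(
    dataset: Dataset, catalog: LocusCatalog
) -> list[ErrorFinding]:
    """Flag well-formed alleles that are implausible for the locus.

    A numeric designation outside the locus allele range, or absent from
    the configured set of established alleles, yields a suspect finding
    (``confirmed=False``) requesting raw-data inspection; adjudications flip
    it to a confirmed error or a verified correct call.
    """
    findings = []
    for locus, spec in _resolved_loci(dataset, catalog):
        if spec is None or spec.is_sex_marker:
            continue
        for rec in dataset.records:
            suspects = []
            for raw in rec.genotypes.get(locus, []):
                d = parse_allele(raw, spec)
                if not d.is_numeric:
                    continue
                if not spec.in_range(d):
                    suspects.append(f"{raw!r} outside range {spec.allele_range}")
                elif (
                    spec.observed_alleles is not None
                    and d.normalized() not in spec.observed_alleles
                ):
                    suspects.append(f"{raw!r} not among established alleles")
            if suspects:
                findings.append(
                    ErrorFinding(
                        category=ErrorCategory.ALLELE_CALL_SUSPECT,
                        scope="cell",
                        message="; ".join(suspects) + " — raw data inspection requested",
                        sample_ids=[rec.sample_id],
                        locus=locus,
                        confirmed=False,
                    )
                )
    return findings


# --- (v) incomplete genotypes ---------------------------------------------

def check_completeness(dataset: Dataset, catalog=None) -> list[ErrorFinding]:
    """Flag missing allele pairs and 0|0 genotypes.

    Only complete genotypes are databased; downstream frequency counting
    must drop these cells and adapt the per-locus allele count.
    """
    findings = []
    for locus in dataset.loci:
        for rec in dataset.records:
            alleles = rec.genotypes.get(locus, [])
            if len(alleles) == 0 or _is_zero_zero(alleles):
                what = "0|0 genotype" if alleles else "missing allele pair"
                findings.append(
                    ErrorFinding(
                        category=ErrorCategory.INCOMPLETE_GENOTYPE,
                        scope="cell",
                        message=f"{what}; only complete genotypes are databased",
                        sample_ids=[rec.sample_id],
                        locus=locus,
                    )
                )
    return findings


# --- (vi) locus nomenclature ----------------------------------------------

def _looks_like_allele(name: str) -> bool:
    import re

    return bool(re.fullmatch(r"\d+(\.\d+)?(\|\d+(\.\d+)?)*", name.strip()))


def check_locus_names(dataset: Dataset, catalog: LocusCatalog) -> list[ErrorFinding]:
    """Flag unknown locus names; attach edit-distance suggestions.

    Accepted alias spellings (case, spaces, hyphens) produce no finding.  A
    header row that looks like genotype data (most names parse as alleles)
    is reported as one dataset-scope missing-header finding.
    """
    names = dataset.loci
    allele_like = sum(_looks_like_allele(n) for n in names)
    if names and allele_like >= max(1, len(names) // 2):
        return [
            ErrorFinding(
                category=ErrorCategory.LOCUS_NOMENCLATURE,
                scope="dataset",
                message="locus names appear to be missing (header row looks like genotypes)",
            )
        ]
    findings = []
    for name in names:
        canonical, suggestions = catalog.canonicalize(name)
        if canonical is None:
            hint = f"; did you mean {', '.join(suggestions)}?" if suggestions else ""
            findings.append(
                ErrorFinding(
                    category=ErrorCategory.LOCUS_NOMENCLATURE,
                    scope="locus",
                    message=f"unknown locus name {name!r}{hint}",
                    locus=name,
                    extra={"suggestions": suggestions},
                )
            )
    return findings


# --- (vii) aneuploidy ------------------------------------------------------

def check_ploidy(dataset: Dataset) -> list[ErrorFinding]:
    """Flag cells with one allele or three or more alleles.

    Tri-allelic cells are additionally marked for exclusion from frequency
    databasing.  A locus that is non-diploid in every record is escalated to
    a single locus-scope finding (consistently tetra-/haploid locus) in
    place of the per-cell findings.
    """
    findings = []
    for locus in dataset.loci:
        cell_findings = []
        non_diploid = 0
        typed = 0
        for rec in dataset.records:
            alleles = rec.genotypes.get(locus, [])
            if len(alleles) == 0:
                continue
            typed += 1
            if len(alleles) == 2:
                continue
            non_diploid += 1
            tri = len(alleles) >= 3
            cell_findings.append(
                ErrorFinding(
                    category=ErrorCategory.ANEUPLOIDY,
                    scope="cell",
                    message=(
                        f"{len(alleles)} allele(s) reported"
                        + ("; excluded from frequency databasing" if tri else "")
                    ),
                    sample_ids=[rec.sample_id],
                    locus=locus,
                    extra={"exclude_from_frequencies": True} if tri else {},
                )
            )
        if typed > 0 and non_diploid == typed:
            findings.append(
                ErrorFinding(
                    category=ErrorCategory.ANEUPLOIDY,
                    scope="locus",
                    message=f"locus is consistently non-diploid across all {typed} records",
                    locus=locus,
                    extra={"exclude_from_frequencies": True},
                )
            )
        else:
            findings.extend(cell_findings)
    return findings


# --- (viii) QC killers ------------------------------------------------------

def check_killers(dataset: Dataset) -> list[ErrorFinding]:
    """Attestation killers: a submission without raw data or with shuffled
    genotypes cannot be assessed and is rejected regardless of content."""
    findings = []
    if not dataset.metadata.raw_data_available:
        findings.append(
            ErrorFinding(
                category=ErrorCategory.QC_KILLER,
                scope="dataset",
                message="complete raw data not available",
            )
        )
    if not dataset.metadata.genotypes_unshuffled:
        findings.append(
            ErrorFinding(
                category=ErrorCategory.QC_KILLER,
                scope="dataset",
                message="genotypes not submitted in original (unshuffled) order",
            )
        )
    return findings


def check_raw_concordance(
    dataset: Dataset, raw_reference: Optional[Dataset]
) -> list[ErrorFinding]:
    """Audit submitted genotypes against a raw-data reference table.

    Records are matched by sample id; any discordant locus (as unordered
    allele pairs) makes the record a killer finding.  The audit is optional:
    without a reference no finding is produced.
    """
    if raw_reference is None:
        return []
    raw_by_id = {r.sample_id: r for r in raw_reference.records}
    shared_loci = [l for l in dataset.loci if l in raw_reference.loci]
    findings = []
    for rec in dataset.records:
        ref = raw_by_id.get(rec.sample_id)
        if ref is None:
            continue
        discordant = []
        for locus in shared_loci:
            if sorted(rec.genotypes.get(locus, [])) != sorted(
                ref.genotypes.get(locus, [])
            ):
                discordant.append(locus)
        if discordant:
            findings.append(
                ErrorFinding(
                    category=ErrorCategory.QC_KILLER,
                    scope="record",
                    message=(
                        "submitted genotypes discordant with raw data at "
                        + ", ".join(discordant)
                    ),
                    sample_ids=[rec.sample_id],
                    extra={"discordant_loci": discordant},
                )
            )
    return findings


# --- (ix) non-unique sample identifiers ------------------------------------

def check_identifiers(dataset: Dataset) -> list[ErrorFinding]:
    """Flag one identifier used for multiple *different* genotypes.

    The same identifier on identical profiles is left to the
    identical-genotypes check.  One finding per colliding pair.
    """
    by_id: dict[str, list[GenotypeRecord]] = {}
    for rec in dataset.records:
        by_id.setdefault(rec.sample_id, []).append(rec)
    findings = []
    for sample_id, recs in by_id.items():
        if len(recs) < 2:
            continue
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                gi = {l: sorted(recs[i].genotypes.get(l, [])) for l in dataset.loci}
                gj = {l: sorted(recs[j].genotypes.get(l, [])) for l in dataset.loci}
                if gi != gj:
                    findings.append(
                        ErrorFinding(
                            category=ErrorCategory.DUPLICATE_IDENTIFIER,
                            scope="record",
                            message=f"identifier {sample_id!r} used for different genotypes",
                            sample_ids=[sample_id],
                        )
                    )
    return findings


# --- (x) information mismatch -----------------------------------------------

def check_metadata_match(
    dataset: Dataset,
    catalog: Optional[LocusCatalog] = None,
    missing_locus_whitelist: Iterable[str] = (),
) -> list[ErrorFinding]:
    """Compare declared sample size and locus list against the submission.

    Loci whose absence is explained elsewhere (already published for the
    population) can be whitelisted.  Comparison is on canonical names when
    a catalog is given.
    """

    def canon(name: str) -> str:
        if catalog is not None:
            c, _ = catalog.canonicalize(name)
            if c is not None:
                return c
        return name.strip().casefold().replace(" ", "").replace("-", "")

    findings = []
    declared_n = dataset.metadata.declared_sample_size
    if declared_n != dataset.n_records:
        findings.append(
            ErrorFinding(
                category=ErrorCategory.INFO_MISMATCH,
                scope="dataset",
                message=(
                    f"declared sample size {declared_n} but "
                    f"{dataset.n_records} records submitted"
                ),
            )
        )
    declared = dataset.metadata.declared_loci
    if declared:
        whitelist = {canon(x) for x in missing_locus_whitelist}
        header = {canon(x) for x in dataset.loci}
        declared_set = {canon(x) for x in declared}
        for name in declared:
            if canon(name) not in header and canon(name) not in whitelist:
                findings.append(
                    ErrorFinding(
                        category=ErrorCategory.INFO_MISMATCH,
                        scope="dataset",
                        message=f"declared locus {name!r} missing from the submission",
                    )
                )
        for name in dataset.loci:
            if canon(name) not in declared_set:
                findings.append(
                    ErrorFinding(
                        category=ErrorCategory.INFO_MISMATCH,
                        scope="dataset",
                        message=f"submitted locus {name!r} not declared in the metadata",
                    )
                )
    return findings


# --- (xi) locus swapping -----------------------------------------------------

def check_locus_swap(
    dataset: Dataset,
    catalog: LocusCatalog,
    swap_fraction_threshold: float = 0.8,
    min_samples: int = 20,
) -> list[ErrorFinding]:
    """Detect whole-column transposition of two loci via allele ranges.

    For a locus pair (A, B): when in at least ``swap_fraction_threshold`` of
    assessable records the A-column alleles fall outside A's range but
    inside B's — and symmetrically — over at least ``min_samples`` records,
    the pair is reported as swapped.  Loci with heavily overlapping ranges
    are an acknowledged blind spot of this heuristic.
    """
    resolved = [
        (locus, spec)
        for locus, spec in _resolved_loci(dataset, catalog)
        if spec is not None and not spec.is_sex_marker
    ]
    # numeric cell values per column, computed once
    values: dict[str, list[Optional[list[float]]]] = {}
    for locus, spec in resolved:
        col = []
        for rec in dataset.records:
            alleles = rec.genotypes.get(locus, [])
            if not alleles:
                col.append(None)
                continue
            parsed = [parse_numeric_lenient(a, spec) for a in alleles]
            if any(p is None for p in parsed):
                col.append(None)
            else:
                col.append(
                    [
                        p.whole_repeats + p.partial_bases / spec.repeat_unit_length
                        for p in parsed
                    ]
                )
        values[locus] = col

    def misplaced_fraction(src: str, own: LocusSpec, other: LocusSpec):
        lo_o, hi_o = own.allele_range
        lo_x, hi_x = other.allele_range
        n = hits = 0
        for vals in values[src]:
            if vals is None:
                continue
            n += 1
            if all(not (lo_o <= v <= hi_o) and (lo_x <= v <= hi_x) for v in vals):
                hits += 1
        return n, (hits / n if n else 0.0)

    findings = []
    for i in range(len(resolved)):
        for j in range(i + 1, len(resolved)):
            locus_a, spec_a = resolved[i]
            locus_b, spec_b = resolved[j]
            if spec_a.canonical_name == spec_b.canonical_name:
                continue
            n_a, frac_a = misplaced_fraction(locus_a, spec_a, spec_b)
            n_b, frac_b = misplaced_fraction(locus_b, spec_b, spec_a)
            if (
                min(n_a, n_b) >= min_samples
                and frac_a >= swap_fraction_threshold
                and frac_b >= swap_fraction_threshold
            ):
                findings.append(
                    ErrorFinding(
                        category=ErrorCategory.LOCUS_SWAP,
                        scope="dataset",
                        message=(
                            f"alleles of {locus_a!r} and {locus_b!r} appear "
                            f"transposed ({frac_a:.0%}/{frac_b:.0%} of records)"
                        ),
                        extra={"loci": [locus_a, locus_b]},
                    )
                )
    return findings


# --- (xii) lost intermediate alleles -----------------------------------------

def check_lost_intermediates(
    dataset: Dataset, catalog: LocusCatalog, min_n: int = 100
) -> list[ErrorFinding]:
    """Flag loci where expected microvariant alleles are entirely absent.

    For a locus configured with expected intermediates (e.g. TH01 9.3) and
    at least ``min_n`` typed individuals: if no partial-repeat allele at all
    is observed while the expected population frequency implies five or
    more copies, the locus is reported as a conspicuity (rounded-off
    decimals), unconfirmed until raw data are inspected.
    """
    findings = []
    for locus, spec in _resolved_loci(dataset, catalog):
        if spec is None or not spec.expected_intermediates:
            continue
        typed = 0
        partials = 0
        for rec in dataset.records:
            alleles = rec.genotypes.get(locus, [])
            parsed = [parse_allele(a, spec) for a in alleles]
            numeric = [p for p in parsed if p.is_numeric]
            if len(numeric) == 2:
                typed += 1
            partials += sum(1 for p in numeric if p.partial_bases)
        if typed < min_n or partials > 0:
            continue
        two_n = 2 * typed
        expected = max(freq * two_n for _, freq in spec.expected_intermediates)
        if expected >= 5:
            designations = ", ".join(d for d, _ in spec.expected_intermediates)
            findings.append(
                ErrorFinding(
                    category=ErrorCategory.LOST_INTERMEDIATE,
                    scope="locus",
                    message=(
                        f"no intermediate alleles observed although {designations} "
                        f"expected at >= {expected:.0f} copies in 2n={two_n}; "
                        "possible rounding of decimal designations"
                    ),
                    locus=locus,
                    confirmed=False,
                )
            )
    return findings
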