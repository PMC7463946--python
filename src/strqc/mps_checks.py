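"""MPS-specific validation: repeat-structure parsing, orientation and
CE translation.

Sequenced STR alleles are validated against a per-locus repeat structure
(ordered motif blocks between fixed 5'/3' flank anchors, forward-strand
reference).  Parsing is greedy and anchored — adequate for validating
submitted allele strings; a sequence the structure cannot explain is itself
a finding (erroneous sequence), not an exception.  A parse yields the
repeat counts, any leftover partial bases, and the flanking-region length
deviation (FR indel offset), from which the length-based CE designation is
recomputed and compared with the submitter's declared CE translation.
Discrepancies exactly explained by an FR indel are expected and
informational; unexplained ones are repeat-counting errors.

Sequence-level nomenclature strings are deliberately never emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from Bio.Seq import reverse_complement

from .catalog import (
    AlleleDesignation,
    AlleleStatus,
    LocusCatalog,
    LocusSpec,
    parse_numeric_lenient,
)
from .ce_checks import ErrorCategory, ErrorFinding
from .io import MPSAlleleSequence

__all__ = [
    "SequenceParse",
    "ParseFailure",
    "parse_structure",
    "resolve_orientation",
    "translate_to_ce",
    "length_equivalent_ce",
    "analyze_sequences",
    "check_ce_consistency",
]

#: bases of flank used as the anchor adjacent to the repeat region
ANCHOR_LENGTH = 10


@dataclass(frozen=True)
class SequenceParse:
    """A successful decomposition of one allele sequence."""

    block_counts: tuple[int, ...]  # one count per structure block
    partial_bases: int  # leftover bases of the final counted motif
    flank_indel_offset: int  # observed minus reference flank length, bases
    orientation: str = "forward"  # forward | reverse


@dataclass(frozen=True)
class ParseFailure:
    reason: str
    insufficient_flank: bool = False


ParseResult = Union[SequenceParse, ParseFailure]


def _anchors(spec: LocusSpec) -> tuple[str, str]:
    k = ANCHOR_LENGTH
    return spec.flank_5[-k:], spec.flank_3[:k]


def parse_structure(seq: str, spec: LocusSpec) -> ParseResult:
    """Anchored greedy parse of one sequence against the locus structure.

    The flank anchors are located first; between them each block's motif is
    matched left to right, maximizing the repeat count.  Up to
    motif-length − 1 trailing bases matching a prefix of the final counted
    motif become the partial.  The deviation of observed flank lengths from
    the reference flanks is returned as the FR indel offset.
    """
    if spec.repeat_structure is None:
        return ParseFailure("locus has no configured repeat structure")
    seq = seq.upper()
    if "N" in seq:
        return ParseFailure("sequence contains ambiguous bases (N)")
    anchor5, anchor3 = _anchors(spec)
    i5 = seq.find(anchor5)
    blocks = spec.repeat_structure
    first_counted = next(b for b in blocks if b.counted)
    if i5 < 0:
        # a read starting inside the repeat tract lacks the 5' flank entirely
        if seq.startswith(first_counted.motif * 2):
            return ParseFailure(
                "5' flanking region absent or truncated beyond the anchor",
                insufficient_flank=True,
            )
        return ParseFailure("5' flank anchor not found")
    repeat_start = i5 + len(anchor5)
    i3 = seq.find(anchor3, repeat_start)
    if i3 < 0:
        if seq.endswith(blocks[-1].motif * 2):
            return ParseFailure(
                "3' flanking region absent or truncated beyond the anchor",
                insufficient_flank=True,
            )
        return ParseFailure("3' flank anchor not found")

    offset = (repeat_start - len(spec.flank_5)) + (len(seq) - i3 - len(spec.flank_3))
    region = seq[repeat_start:i3]

    counts = []
    pos = 0
    last_counted_index = max(i for i, b in enumerate(blocks) if b.counted)
    partial = 0
    for bi, block in enumerate(blocks):
        m = block.motif
        count = 0
        while region.startswith(m, pos):
            count += 1
            pos += len(m)
        if bi == last_counted_index:
            rest = region[pos:]
            if rest and len(rest) < len(m) and m.startswith(rest):
                partial = len(rest)
                pos = len(region)
        if not (block.min_count <= count <= block.max_count):
            return ParseFailure(
                f"block {m} repeated {count}x, outside "
                f"[{block.min_count}, {block.max_count}]"
            )
        counts.append(count)
    if pos != len(region):
        return ParseFailure(
            f"unmatched residue {region[pos:pos + 20]!r} in the repeat region"
        )
    return SequenceParse(
        block_counts=tuple(counts),
        partial_bases=partial,
        flank_indel_offset=offset,
    )


def resolve_orientation(seq: str, spec: LocusSpec) -> ParseResult:
    """Parse forward, falling back to the reverse complement.

    Forward-strand reporting is the convention; a sequence that parses only
    after reverse complementing comes back with ``orientation="reverse"``
    (the caller turns that into an orientation finding).  Both failing
    yields the forward failure, preferring an insufficient-flank reason.
    """
    forward = parse_structure(seq, spec)
    if isinstance(forward, SequenceParse):
        return forward
    rc = parse_structure(reverse_complement(seq), spec)
    if isinstance(rc, SequenceParse):
        return SequenceParse(
            block_counts=rc.block_counts,
            partial_bases=rc.partial_bases,
            flank_indel_offset=rc.flank_indel_offset,
            orientation="reverse",
        )
    if isinstance(rc, ParseFailure) and rc.insufficient_flank and not forward.insufficient_flank:
        return rc
    return forward


def translate_to_ce(parse: SequenceParse, spec: LocusSpec) -> AlleleDesignation:
    """Sequence-based CE designation: counted repeats plus partial bases."""
    whole = sum(
        c for c, b in zip(parse.block_counts, spec.repeat_structure) if b.counted
    )
    text = f"{whole}.{parse.partial_bases}" if parse.partial_bases else str(whole)
    return AlleleDesignation(
        raw_text=text,
        status=AlleleStatus.VALID_NUMERIC,
        whole_repeats=whole,
        partial_bases=parse.partial_bases,
    )


def length_equivalent_ce(parse: SequenceParse, spec: LocusSpec) -> AlleleDesignation:
    """The designation a length-based (CE) instrument would report.

    An FR indel shifts the apparent fragment length without changing the
    repeat count, so the length-equivalent designation folds the offset
    into the repeat arithmetic.
    """
    seq_based = translate_to_ce(parse, spec)
    unit = spec.repeat_unit_length
    total = seq_based.total_bases(unit) + parse.flank_indel_offset
    whole, partial = divmod(total, unit)
    text = f"{whole}.{partial}" if partial else str(whole)
    return AlleleDesignation(
        raw_text=text,
        status=AlleleStatus.VALID_NUMERIC,
        whole_repeats=whole,
        partial_bases=partial,
    )


@dataclass
class SequenceAnalysis:
    sequence: MPSAlleleSequence
    parse: Optional[SequenceParse]
    findings: list[ErrorFinding] = field(default_factory=list)


def _mps_finding(category, seq: MPSAlleleSequence, message: str, **kw) -> ErrorFinding:
    return ErrorFinding(
        category=category,
        scope="cell",
        message=message,
        sample_ids=[seq.sample_id],
        locus=seq.locus,
        mps=True,
        **kw,
    )


def analyze_sequences(
    sequences: Sequence[MPSAlleleSequence], catalog: LocusCatalog
) -> list[SequenceAnalysis]:
    """Parse and orient every submitted allele sequence.

    Produces per-sequence findings for unparseable (erroneous) sequences,
    reverse-orientation reporting and insufficient flanking regions.
    """
    analyses = []
    for seq in sequences:
        spec = catalog.get(seq.locus)
        if spec is None or spec.repeat_structure is None:
            analyses.append(
                SequenceAnalysis(
                    seq,
                    None,
                    [
                        _mps_finding(
                            ErrorCategory.ERRONEOUS_SEQUENCE,
                            seq,
                            f"no repeat structure configured for locus {seq.locus!r}",
                        )
                    ],
                )
            )
            continue
        result = resolve_orientation(seq.sequence, spec)
        if isinstance(result, ParseFailure):
            category = (
                ErrorCategory.INSUFFICIENT_FLANK
                if result.insufficient_flank
                else ErrorCategory.ERRONEOUS_SEQUENCE
            )
            analyses.append(
                SequenceAnalysis(
                    seq, None, [_mps_finding(category, seq, result.reason)]
                )
            )
            continue
        findings = []
        if result.orientation == "reverse":
            findings.append(
                _mps_finding(
                    ErrorCategory.SEQUENCE_ORIENTATION,
                    seq,
                    "sequence reported in reverse instead of forward (5'-3') direction",
                )
            )
        analyses.append(SequenceAnalysis(seq, result, findings))
    return analyses


def check_ce_consistency(
    analyses: Sequence[SequenceAnalysis], catalog: LocusCatalog
) -> list[ErrorFinding]:
    """Compare declared CE translations with sequence-based recounting.

    A mismatch exactly explained by the parse's FR indel offset is an
    expected discrepancy (informational, never an error); any other
    mismatch is a repeat-counting error in the CE translation.
    """
    findings = []
    for an in analyses:
        seq = an.sequence
        if an.parse is None or seq.declared_ce_allele is None:
            continue
        spec = catalog.get(seq.locus)
        recomputed = translate_to_ce(an.parse, spec)
        declared = parse_numeric_lenient(seq.declared_ce_allele, spec)
        if declared is None:
            findings.append(
                _mps_finding(
                    ErrorCategory.CE_TRANSLATION,
                    seq,
                    f"declared CE allele {seq.declared_ce_allele!r} is not a "
                    "valid designation",
                )
            )
            continue
        decl = (declared.whole_repeats, declared.partial_bases)
        if decl == (recomputed.whole_repeats, recomputed.partial_bases):
            continue
        equivalent = length_equivalent_ce(an.parse, spec)
        if an.parse.flank_indel_offset != 0 and decl == (
            equivalent.whole_repeats,
            equivalent.partial_bases,
        ):
            findings.append(
                _mps_finding(
                    ErrorCategory.EXPECTED_FR_DISCREPANCY,
                    seq,
                    f"declared {seq.declared_ce_allele} vs sequence-based "
                    f"{recomputed.normalized()}: explained by a "
                    f"{an.parse.flank_indel_offset:+d} bp flanking-region indel",
                    is_error=False,
                )
            )
        else:
            findings.append(
                _mps_finding(
                    ErrorCategory.CE_TRANSLATION,
                    seq,
                    f"declared CE allele {seq.declared_ce_allele} but "
                    f"sequence-based count gives {recomputed.normalized()}",
                )
            )
    return findings
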