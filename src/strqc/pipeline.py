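"""End-to-end QC orchestration: run all detectors in a fixed order, apply
adjudications, tally, decide, and issue the accession on a PASS.

The stepwise order is fixed for reproducible reports (finding content is
order-independent): locus names, allele nomenclature, allele order, ploidy,
completeness, identifiers, identical genotypes, allele plausibility, locus
swaps, lost intermediates, metadata match, killers, then the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import ce_checks
from .catalog import LocusCatalog, default_catalog
from .ce_checks import Adjudication, ErrorFinding, apply_adjudications
from .decision import AccessionLedger, QCCounts, QCVerdict, assign_accession, decide, tally
from .io import Dataset, MPSAlleleSequence
from .mps_checks import analyze_sequences, check_ce_consistency

__all__ = ["QCResult", "run_qc", "run_mps_qc"]


@dataclass
class QCResult:
    findings: list[ErrorFinding]
    counts: QCCounts
    verdict: QCVerdict


def run_qc(
    dataset: Dataset,
    catalog: Optional[LocusCatalog] = None,
    *,
    pool: Optional[Sequence[Dataset]] = None,
    raw_reference: Optional[Dataset] = None,
    adjudications: Iterable[Adjudication] = (),
    accept_rare_placeholders: bool = False,
    missing_locus_whitelist: Iterable[str] = (),
    ledger: Optional[AccessionLedger] = None,
) -> QCResult:
    """Run the full CE QC pipeline on one dataset."""
    catalog = catalog or default_catalog()
    findings: list[ErrorFinding] = []
    findings += ce_checks.check_locus_names(dataset, catalog)
    findings += ce_checks.check_allele_nomenclature(
        dataset, catalog, accept_rare_placeholders
    )
    findings += ce_checks.check_allele_order(dataset, catalog)
    findings += ce_checks.check_ploidy(dataset)
    findings += ce_checks.check_completeness(dataset, catalog)
    findings += ce_checks.check_identifiers(dataset)
    findings += ce_checks.check_identical_genotypes(dataset, pool=pool)
    findings += ce_checks.check_allele_plausibility(dataset, catalog)
    findings += ce_checks.check_locus_swap(dataset, catalog)
    findings += ce_checks.check_lost_intermediates(dataset, catalog)
    findings += ce_checks.check_metadata_match(
        dataset, catalog, missing_locus_whitelist
    )
    findings += ce_checks.check_killers(dataset)
    findings += ce_checks.check_raw_concordance(dataset, raw_reference)
    apply_adjudications(findings, adjudications)
    counts = tally(findings)
    verdict = decide(counts)
    if verdict.status == "PASS":
        verdict.accession = assign_accession(dataset, ledger or AccessionLedger())
    return QCResult(findings=findings, counts=counts, verdict=verdict)


def run_mps_qc(
    sequences: Sequence[MPSAlleleSequence],
    declared_ce: Optional[Dataset],
    catalog: Optional[LocusCatalog] = None,
    *,
    adjudications: Iterable[Adjudication] = (),
    ledger: Optional[AccessionLedger] = None,
) -> QCResult:
    """Run MPS-specific QC: sequence parsing, orientation, CE translation.

    The declared CE-translation table additionally runs through the CE
    detectors; those findings are reported (they often pinpoint problems in
    the MPS data) but are excluded from the verdict tally, which is based
    on the sequence-level findings and the submission attestations only.
    """
    catalog = catalog or default_catalog()
    analyses = analyze_sequences(sequences, catalog)
    findings: list[ErrorFinding] = [f for an in analyses for f in an.findings]
    findings += check_ce_consistency(analyses, catalog)

    if declared_ce is not None:
        ce_result = run_qc(declared_ce, catalog, adjudications=adjudications)
        for f in ce_result.findings:
            if f.category is not ce_checks.ErrorCategory.QC_KILLER:
                f.ce_table_only = True
            findings.append(f)
    apply_adjudications(findings, adjudications)
    counts = tally(findings, mps=True)
    verdict = decide(counts)
    if verdict.status == "PASS" and declared_ce is not None:
        verdict.accession = assign_accession(declared_ce, ledger or AccessionLedger())
    elif verdict.status == "PASS":
        verdict.accession = (ledger or AccessionLedger()).issue(
            "mps:" + ",".join(sorted(s.sample_id + "/" + s.locus for s in sequences))
        )
    return QCResult(findings=findings, counts=counts, verdict=verdict)
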