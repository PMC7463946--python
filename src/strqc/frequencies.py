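"""Allele counting, frequencies and the 5/2n minimum-frequency floor.

Allele frequencies are reported twice: raw (count / 2n_L, summing to one
per locus) and floored at the conventional forensic minimum 5/2n, where n
is the number of individuals actually contributing complete diploid
genotypes at the locus.  2n_L is adapted per locus: incomplete, aneuploid
and tri-allelic cells are excluded from counting, so a locus with missing
genotypes carries a smaller 2n than the nominal sample size.  Floored
frequencies are not renormalized — the floor is a casework lower bound, not
a probability model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .catalog import LocusCatalog, compare_alleles, parse_allele
from .io import Dataset

__all__ = ["FrequencyTable", "compute_frequencies", "summary_parameters", "MIN_COUNT_NUMERATOR"]

#: numerator of the conventional minimum allele-frequency bound (5/2n)
MIN_COUNT_NUMERATOR = 5


@dataclass
class LocusFrequencies:
    locus: str
    counts: dict[str, int]  # normalized designation -> allele copies
    alleles_sampled: int  # 2n_L
    excluded_cells: list[tuple[str, str]] = field(default_factory=list)

    def raw(self, allele: str) -> float:
        return self.counts[allele] / self.alleles_sampled

    def floored(self, allele: str) -> float:
        return max(self.raw(allele), MIN_COUNT_NUMERATOR / self.alleles_sampled)

    def floor_applied(self, allele: str) -> bool:
        return self.counts[allele] < MIN_COUNT_NUMERATOR


@dataclass
class FrequencyTable:
    """Per-locus allele counts and (raw, floored) frequency columns."""

    loci: dict[str, LocusFrequencies]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lf in self.loci.values():
            for allele, count in lf.counts.items():
                rows.append(
                    {
                        "locus": lf.locus,
                        "allele": allele,
                        "count": count,
                        "alleles_sampled": lf.alleles_sampled,
                        "raw": lf.raw(allele),
                        "floored": lf.floored(allele),
                        "floor_applied": lf.floor_applied(allele),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "locus",
                "allele",
                "count",
                "alleles_sampled",
                "raw",
                "floored",
                "floor_applied",
            ],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FrequencyTable":
        loci: dict[str, LocusFrequencies] = {}
        for locus, group in frame.groupby("locus", sort=False):
            loci[str(locus)] = LocusFrequencies(
                locus=str(locus),
                counts={str(r.allele): int(r.count) for r in group.itertuples()},
                alleles_sampled=int(group["alleles_sampled"].iloc[0]),
            )
        return cls(loci=loci)


def _excluded_cells(findings) -> set[tuple[str, str]]:
    out = set()
    for f in findings or []:
        if f.extra.get("exclude_from_frequencies"):
            for sid in f.sample_ids or [None]:
                out.add((sid, f.locus))
    return out


def compute_frequencies(
    dataset: Dataset,
    catalog: LocusCatalog,
    findings: Optional[Sequence] = None,
    verdict=None,
    allow_unchecked: bool = False,
) -> FrequencyTable:
    """Count alleles and compute raw and 5/2n-floored frequencies.

    Intended for datasets that passed QC: pass the verdict to enforce that,
    or set ``allow_unchecked`` for exploratory use.  Homozygotes contribute
    two copies to one allele.  Cells flagged for exclusion (tri-allelic),
    incomplete cells and cells that do not parse as two numeric alleles are
    skipped, and the locus 2n is adapted accordingly.  Sex markers are not
    frequency-databased.  A locus with zero complete genotypes is omitted
    with a warning.
    """
    if verdict is not None and verdict.status != "PASS" and not allow_unchecked:
        raise ValueError(
            f"dataset verdict is {verdict.status}; pass allow_unchecked=True "
            "to compute frequencies anyway"
        )
    excluded = _excluded_cells(findings)
    loci: dict[str, LocusFrequencies] = {}
    for locus in dataset.loci:
        spec = catalog.get(locus)
        if spec is None or spec.is_sex_marker:
            continue
        counts: dict[str, int] = {}
        skipped: list[tuple[str, str]] = []
        complete = 0
        for rec in dataset.records:
            alleles = rec.genotypes.get(locus, [])
            if (rec.sample_id, locus) in excluded or len(alleles) != 2:
                skipped.append((rec.sample_id, locus))
                continue
            parsed = [parse_allele(a, spec) for a in alleles]
            if not all(p.is_numeric for p in parsed):
                skipped.append((rec.sample_id, locus))
                continue
            complete += 1
            for p in parsed:
                key = p.normalized()
                counts[key] = counts.get(key, 0) + 1
        if complete == 0:
            warnings.warn(
                f"locus {locus!r}: no complete genotypes; omitted from the table",
                stacklevel=2,
            )
            continue
        ordered = dict(
            sorted(
                counts.items(),
                key=lambda kv: spec.designation_value(kv[0]),
            )
        )
        loci[locus] = LocusFrequencies(
            locus=locus,
            counts=ordered,
            alleles_sampled=2 * complete,
            excluded_cells=skipped,
        )
    return FrequencyTable(loci=loci)


def summary_parameters(table: FrequencyTable, dataset: Dataset) -> pd.DataFrame:
    """Per-locus observed and (bias-corrected) expected heterozygosity.

    Hobs = heterozygous complete genotypes / complete genotypes;
    Hexp = (2n / (2n - 1)) * (1 - sum p_i^2) on raw frequencies.
    """
    rows = []
    for locus, lf in table.loci.items():
        two_n = lf.alleles_sampled
        n = two_n // 2
        excluded = {s for s, _ in lf.excluded_cells}
        het = 0
        for rec in dataset.records:
            if rec.sample_id in excluded:
                continue
            alleles = rec.genotypes.get(locus, [])
            if len(alleles) == 2 and sorted(alleles)[0] != sorted(alleles)[1]:
                het += 1
        sum_p2 = sum((c / two_n) ** 2 for c in lf.counts.values())
        hexp = (two_n / (two_n - 1)) * (1 - sum_p2) if two_n > 1 else 0.0
        rows.append(
            {
                "locus": locus,
                "n_complete": n,
                "n_alleles": len(lf.counts),
                "Hobs": het / n if n else 0.0,
                "Hexp": hexp,
            }
        )
    return pd.DataFrame(rows, columns=["locus", "n_complete", "n_alleles", "Hobs", "Hexp"])
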