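"""Readers and writers for submission and output artifacts.

Everything is string-first: cells are preserved verbatim (``12.0`` stays
distinct from ``12``) and record order is preserved exactly as read, because
shuffling, placeholders and column shifts are themselves the evidence the
checks look for.  Numeric interpretation happens only in
:mod:`strqc.catalog`.

Two CE table dialects are supported and must be declared explicitly:

``paired-column``
    two adjacent columns per locus, both headed with the locus name;
``piped-cell``
    one column per locus, alleles joined with ``|`` inside the cell.

MPS submissions are FASTA-like files whose headers carry
``sampleID;locus;alleleIndex[;declaredCEallele]``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

__all__ = [
    "MetadataDeclaration",
    "GenotypeRecord",
    "Dataset",
    "MPSAlleleSequence",
    "DatasetReadError",
    "CE_DIALECTS",
    "read_ce_dataset",
    "read_mps_dataset",
    "write_ce_dataset",
    "write_mps_fasta",
    "load_metadata",
    "write_frequency_table",
    "read_frequency_table",
    "write_qc_report",
]

CE_DIALECTS = ("paired-column", "piped-cell")


class DatasetReadError(ValueError):
    """Structural problem in a submission file, naming row/column/line."""


@dataclass
class MetadataDeclaration:
    """The submitter's non-genetic declarations accompanying a dataset."""

    population_name: str = ""
    region: str = ""
    declared_sample_size: int = 0
    declared_loci: list[str] = field(default_factory=list)
    kit: str = ""
    raw_data_available: bool = True
    genotypes_unshuffled: bool = True
    ethics_statement: str = ""

    def __post_init__(self) -> None:
        if self.declared_sample_size <= 0:
            raise ValueError("declared_sample_size must be positive")


@dataclass
class GenotypeRecord:
    """One individual's row: raw locus name -> allele strings as submitted."""

    sample_id: str
    genotypes: dict[str, list[str]]

    def unordered_genotype(self, locus: str) -> Optional[tuple[str, str]]:
        """Diploid allele pair as an order-free tuple (None when not diploid)."""
        alleles = self.genotypes.get(locus)
        if not alleles or len(alleles) != 2:
            return None
        a, b = sorted(alleles)
        return (a, b)


@dataclass
class Dataset:
    """One submission: ordered records plus the metadata declaration."""

    records: list[GenotypeRecord]
    metadata: MetadataDeclaration
    method: str = "CE"  # "CE" | "MPS"
    source_path: str = ""
    loci: list[str] = field(default_factory=list)  # header order, raw names

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("a dataset must contain at least one record")
        if self.method not in ("CE", "MPS"):
            raise ValueError(f"unknown method {self.method!r}")
        if not self.loci:
            self.loci = list(self.records[0].genotypes)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def content_hash(self) -> str:
        """Stable hash of genotype content + population, for accession reuse."""
        import hashlib

        h = hashlib.sha256()
        h.update(self.metadata.population_name.encode())
        for rec in self.records:
            h.update(rec.sample_id.encode())
            for locus in self.loci:
                h.update(b"\x00")
                for allele in rec.genotypes.get(locus, []):
                    h.update(allele.encode())
                    h.update(b"\x01")
        return h.hexdigest()


@dataclass
class MPSAlleleSequence:
    """One sequenced allele from an MPS submission."""

    sample_id: str
    locus: str
    allele_index: int
    sequence: str
    declared_ce_allele: Optional[str] = None

    def __post_init__(self) -> None:
        if self.allele_index not in (1, 2):
            raise ValueError("allele_index must be 1 or 2")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("sequence may contain only A/C/G/T/N")


def load_metadata(path) -> MetadataDeclaration:
    """Read a metadata declaration from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f for f in MetadataDeclaration.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise DatasetReadError(f"{path}: unknown metadata fields {sorted(unknown)}")
    return MetadataDeclaration(**doc)


def _read_rows(path, delimiter: Optional[str]) -> list[list[str]]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        if delimiter is None:
            delimiter = "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","
        return [row for row in csv.reader(fh, delimiter=delimiter)]


def read_ce_dataset(
    path,
    dialect: str,
    metadata: MetadataDeclaration,
    delimiter: Optional[str] = None,
) -> Dataset:
    """Read a CE genotype table.

    The first column holds the sample identifier and the first row the locus
    names.  Cells are kept verbatim; empty genotypes become empty allele
    lists.  Structural problems raise :class:`DatasetReadError` naming the
    offending row or column.
    """
    if dialect not in CE_DIALECTS:
        raise DatasetReadError(f"unknown CE dialect {dialect!r}; use one of {CE_DIALECTS}")
    rows = _read_rows(path, delimiter)
    if not rows:
        raise DatasetReadError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2:
        raise DatasetReadError(f"{path}: header row has no locus columns")
    locus_cells = header[1:]

    if dialect == "paired-column":
        if len(locus_cells) % 2 != 0:
            raise DatasetReadError(
                f"{path}: paired-column dialect needs an even number of "
                f"locus columns, got {len(locus_cells)}"
            )
        loci: list[str] = []
        for i in range(0, len(locus_cells), 2):
            a, b = locus_cells[i], locus_cells[i + 1]
            if a != b and b.strip() != "":
                raise DatasetReadError(
                    f"{path}: columns {i + 2} and {i + 3} should repeat one "
                    f"locus name, got {a!r} vs {b!r}"
                )
            if a in loci:
                raise DatasetReadError(
                    f"{path}: locus {a!r} appears in more than one column pair"
                )
            loci.append(a)
    else:
        loci = list(locus_cells)
        dupes = {x for x in loci if loci.count(x) > 1}
        if dupes:
            raise DatasetReadError(
                f"{path}: duplicate header columns for {sorted(dupes)}"
            )

    records: list[GenotypeRecord] = []
    for rownum, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue  # blank line
        if len(row) != len(header):
            raise DatasetReadError(
                f"{path}: row {rownum} has {len(row)} cells, expected {len(header)}"
            )
        sample_id = row[0].strip()
        if not sample_id:
            raise DatasetReadError(f"{path}: row {rownum} has an empty sample id")
        genotypes: dict[str, list[str]] = {}
        if dialect == "paired-column":
            for idx, locus in enumerate(loci):
                a, b = row[1 + 2 * idx], row[2 + 2 * idx]
                alleles = [c.strip() for c in (a, b) if c.strip() != ""]
                genotypes[locus] = alleles
        else:
            for idx, locus in enumerate(loci):
                cell = row[1 + idx].strip()
                genotypes[locus] = (
                    [] if cell == "" else [c.strip() for c in cell.split("|")]
                )
        records.append(GenotypeRecord(sample_id=sample_id, genotypes=genotypes))
    if not records:
        raise DatasetReadError(f"{path}: no genotype rows found")
    return Dataset(
        records=records,
        metadata=metadata,
        method="CE",
        source_path=str(path),
        loci=loci,
    )


def read_mps_dataset(
    path, metadata: MetadataDeclaration
) -> tuple[list[MPSAlleleSequence], Optional[Dataset]]:
    """Read a FASTA-like MPS submission.

    Returns the sequences plus, when declared CE alleles are present, a
    parallel CE-style :class:`Dataset` used for translation cross-checks.
    Sequence lines may wrap; sequences are upper-cased.
    """
    from Bio import SeqIO

    sequences: list[MPSAlleleSequence] = []
    seen: set[tuple[str, str, int]] = set()
    for recnum, record in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        header = record.description.strip()
        parts = header.split(";")
        if len(parts) not in (3, 4):
            raise DatasetReadError(
                f"{path}: entry {recnum}: header {header!r} must be "
                "'sample;locus;alleleIndex[;CEallele]'"
            )
        sample_id, locus, index_text = parts[0], parts[1], parts[2]
        if not sample_id or not locus:
            raise DatasetReadError(
                f"{path}: entry {recnum}: empty sample id or locus name"
            )
        try:
            allele_index = int(index_text)
        except ValueError:
            raise DatasetReadError(
                f"{path}: entry {recnum}: allele index {index_text!r} is not an integer"
            ) from None
        if allele_index not in (1, 2):
            raise DatasetReadError(
                f"{path}: entry {recnum}: allele index must be 1 or 2, got {allele_index}"
            )
        seq = str(record.seq).upper().strip()
        if not seq:
            raise DatasetReadError(f"{path}: entry {recnum}: empty sequence")
        if set(seq) - set("ACGTN"):
            raise DatasetReadError(
                f"{path}: entry {recnum}: non-nucleotide characters in sequence"
            )
        key = (sample_id, locus, allele_index)
        if key in seen:
            raise DatasetReadError(
                f"{path}: entry {recnum}: duplicate entry for sample "
                f"{sample_id!r}, locus {locus!r}, allele {allele_index}"
            )
        seen.add(key)
        sequences.append(
            MPSAlleleSequence(
                sample_id=sample_id,
                locus=locus,
                allele_index=allele_index,
                sequence=seq,
                declared_ce_allele=parts[3].strip() if len(parts) == 4 else None,
            )
        )
    if not sequences:
        raise DatasetReadError(f"{path}: no sequence entries found")

    ce_dataset = _declared_ce_dataset(sequences, metadata, str(path))
    return sequences, ce_dataset


def _declared_ce_dataset(
    sequences: list[MPSAlleleSequence],
    metadata: MetadataDeclaration,
    source_path: str,
) -> Optional[Dataset]:
    if not any(s.declared_ce_allele is not None for s in sequences):
        return None
    loci: list[str] = []
    order: list[str] = []
    by_sample: dict[str, dict[str, dict[int, str]]] = {}
    for s in sequences:
        if s.locus not in loci:
            loci.append(s.locus)
        if s.sample_id not in by_sample:
            by_sample[s.sample_id] = {}
            order.append(s.sample_id)
        if s.declared_ce_allele is not None:
            by_sample[s.sample_id].setdefault(s.locus, {})[s.allele_index] = (
                s.declared_ce_allele
            )
    records = []
    for sample_id in order:
        genotypes = {
            locus: [
                by_sample[sample_id].get(locus, {})[i]
                for i in sorted(by_sample[sample_id].get(locus, {}))
            ]
            for locus in loci
        }
        records.append(GenotypeRecord(sample_id=sample_id, genotypes=genotypes))
    return Dataset(
        records=records,
        metadata=metadata,
        method="MPS",
        source_path=source_path,
        loci=loci,
    )


def write_ce_dataset(dataset: Dataset, path, dialect: str = "piped-cell") -> None:
    """Write a dataset back out as a CE table (verbatim cells)."""
    if dialect not in CE_DIALECTS:
        raise DatasetReadError(f"unknown CE dialect {dialect!r}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        if dialect == "piped-cell":
            writer.writerow(["Sample"] + dataset.loci)
            for rec in dataset.records:
                writer.writerow(
                    [rec.sample_id]
                    + ["|".join(rec.genotypes.get(l, [])) for l in dataset.loci]
                )
        else:
            header = ["Sample"]
            for locus in dataset.loci:
                header += [locus, locus]
            writer.writerow(header)
            for rec in dataset.records:
                row = [rec.sample_id]
                for locus in dataset.loci:
                    alleles = rec.genotypes.get(locus, [])
                    if len(alleles) > 2:
                        raise DatasetReadError(
                            f"{rec.sample_id}/{locus}: paired-column dialect "
                            "cannot hold more than two alleles"
                        )
                    row += [
                        alleles[0] if len(alleles) > 0 else "",
                        alleles[1] if len(alleles) > 1 else "",
                    ]
                writer.writerow(row)


def write_mps_fasta(sequences: Sequence["MPSAlleleSequence"], path, width: int = 70) -> None:
    """Write MPS allele sequences in the FASTA-like submission format."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in sequences:
            ce = f";{s.declared_ce_allele}" if s.declared_ce_allele is not None else ""
            fh.write(f">{s.sample_id};{s.locus};{s.allele_index}{ce}\n")
            for i in range(0, len(s.sequence), width):
                fh.write(s.sequence[i : i + width] + "\n")


# --- output artifacts ------------------------------------------------------

FREQUENCY_COLUMNS = ["locus", "allele", "count", "alleles_sampled", "raw", "floored", "floor_applied"]


def write_frequency_table(table, path) -> None:
    """Write a frequency table as delimited text (one row per locus+allele)."""
    frame = table.to_frame()
    frame.to_csv(path, index=False, columns=FREQUENCY_COLUMNS)


def read_frequency_table(path):
    """Read back a written frequency table into a :class:`FrequencyTable`."""
    import pandas as pd

    from .frequencies import FrequencyTable

    frame = pd.read_csv(
        path, dtype={"locus": str, "allele": str, "count": int, "alleles_sampled": int}
    )
    return FrequencyTable.from_frame(frame)


def _finding_to_mapping(finding) -> dict:
    d = asdict(finding)
    d["category"] = finding.category.value
    d["scope"] = finding.scope
    return d


def write_qc_report(verdict, findings, path, format: str = "text") -> None:
    """Write the QC report in ``text`` or ``structured`` (JSON) form.

    The structured format is schema-versioned JSON with the verdict,
    triggered rules and every finding (category, location, message,
    occurrences, confirmation state).
    """
    if format == "structured":
        doc = {
            "schema": "strqc-report/1",
            "verdict": {
                "status": verdict.status,
                "triggered_rules": list(verdict.triggered_rules),
                "accession": verdict.accession,
                "unresolved_suspects": verdict.unresolved_suspects,
            },
            "findings": [_finding_to_mapping(f) for f in findings],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
        return
    if format != "text":
        raise ValueError(f"unknown report format {format!r}")
    lines = [
        "STR dataset quality-control report",
        "==================================",
        f"Verdict: {verdict.status}",
    ]
    if verdict.triggered_rules:
        lines.append("Triggered rules: " + ", ".join(verdict.triggered_rules))
    if verdict.accession:
        lines.append(f"Accession: {verdict.accession}")
    if verdict.unresolved_suspects:
        lines.append(f"Unresolved suspect findings: {verdict.unresolved_suspects}")
    lines.append(f"Findings: {len(findings)}")
    for f in findings:
        where = []
        if f.sample_ids:
            where.append("samples " + ",".join(f.sample_ids[:5]))
        if f.locus:
            where.append(f"locus {f.locus}")
        loc = " @ " + "; ".join(where) if where else ""
        lines.append(
            f"  [{f.category.value}] x{f.occurrences}{loc}: {f.message}"
            + ("" if f.confirmed else " (unconfirmed)")
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
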