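"""Synthetic submissions with known allele spectra and injected errors.

The generator emulates what population laboratories submit to an STR
frequency database: a genotype table of a few hundred individuals typed at
common forensic loci, sampled under Hardy-Weinberg proportions from a
per-locus allele spectrum (microvariants included so partial-repeat
ordering is exercised), with a consistent metadata declaration.  The
companion injector corrupts a clean dataset with exactly the planned number
of occurrences of any error category and records every change in a
ground-truth manifest — the answer key for detector recall/precision tests
and for end-to-end decision tests.  Applying the manifest inverse restores
the clean dataset bit for bit.

All randomness flows from a single root seed, fanned out per injection, so
any corruption is reproducible in isolation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .catalog import LocusCatalog, LocusSpec, default_catalog, parse_numeric_lenient
from .io import Dataset, GenotypeRecord, MetadataDeclaration, MPSAlleleSequence

__all__ = [
    "PopulationModel",
    "Injection",
    "ErrorInjectionPlan",
    "ManifestEntry",
    "GroundTruthManifest",
    "DEFAULT_SPECTRA",
    "INVALID_DESIGNATIONS",
    "default_population_model",
    "generate_clean_dataset",
    "inject_errors",
    "restore_clean",
    "generate_mps_fixture",
    "corrupt_mps",
]

#: invalid designation strings seen in real submissions, used by the injector
INVALID_DESIGNATIONS = (
    "9+", "-9", "18.9", "0", "115", "1314", "9R", "13NEW", "M", "OL", "R", "9,3",
)

#: per-locus allele spectra (within the default catalog's ranges); values
#: are plausible European-like frequencies rounded to two decimals, chosen
#: once as fixture conditions, each spectrum summing to one
DEFAULT_SPECTRA: dict[str, dict[str, float]] = {
    "TH01": {"6": 0.23, "7": 0.17, "8": 0.11, "9": 0.14, "9.3": 0.30, "10": 0.05},
    "vWA": {"14": 0.10, "15": 0.11, "16": 0.20, "17": 0.27, "18": 0.22, "19": 0.10},
    "FGA": {"19": 0.06, "20": 0.13, "21": 0.17, "22": 0.22, "23": 0.13, "24": 0.14,
            "25": 0.10, "26": 0.05},
    "D5S818": {"9": 0.05, "10": 0.05, "11": 0.36, "12": 0.35, "13": 0.15, "14": 0.04},
    "TPOX": {"8": 0.54, "9": 0.08, "10": 0.05, "11": 0.26, "12": 0.07},
    "D16S539": {"9": 0.11, "10": 0.06, "11": 0.32, "12": 0.26, "13": 0.18, "14": 0.07},
    "D18S51": {"12": 0.13, "13": 0.12, "14": 0.17, "15": 0.14, "16": 0.14, "17": 0.12,
               "18": 0.08, "19": 0.10},
    "D8S1179": {"10": 0.09, "11": 0.07, "12": 0.14, "13": 0.33, "14": 0.22,
                "15": 0.11, "16": 0.04},
    "D3S1358": {"14": 0.11, "15": 0.26, "16": 0.24, "17": 0.21, "18": 0.15, "19": 0.03},
    "D7S820": {"8": 0.16, "9": 0.15, "10": 0.26, "11": 0.21, "12": 0.16, "13": 0.06},
    "D13S317": {"8": 0.12, "9": 0.08, "10": 0.06, "11": 0.32, "12": 0.26, "13": 0.11,
                "14": 0.05},
    "CSF1PO": {"9": 0.04, "10": 0.25, "11": 0.30, "12": 0.33, "13": 0.07, "14": 0.01},
    "D21S11": {"28": 0.16, "29": 0.22, "30": 0.25, "30.2": 0.04, "31": 0.07,
               "31.2": 0.10, "32.2": 0.11, "33.2": 0.05},
    "D2S1338": {"17": 0.18, "18": 0.09, "19": 0.12, "20": 0.14, "21": 0.04,
                "22": 0.04, "23": 0.12, "24": 0.13, "25": 0.11, "26": 0.03},
    "D19S433": {"12": 0.08, "13": 0.25, "14": 0.37, "14.2": 0.02, "15": 0.18,
                "15.2": 0.04, "16": 0.06},
    "D12S391": {"17": 0.10, "18": 0.22, "19": 0.14, "20": 0.13, "21": 0.11,
                "22": 0.15, "23": 0.11, "24": 0.04},
    "D2S441": {"10": 0.22, "11": 0.34, "11.3": 0.06, "12": 0.04, "13": 0.03,
               "14": 0.31},
    "D10S1248": {"12": 0.06, "13": 0.25, "14": 0.31, "15": 0.22, "16": 0.12,
                 "17": 0.04},
    "D22S1045": {"11": 0.13, "14": 0.05, "15": 0.34, "16": 0.32, "17": 0.12,
                 "18": 0.04},
    "D1S1656": {"11": 0.10, "12": 0.13, "13": 0.09, "14": 0.09, "15": 0.15,
                "15.3": 0.05, "16": 0.14, "16.3": 0.04, "17.3": 0.12, "18.3": 0.09},
    "D6S1043": {"11": 0.22, "12": 0.23, "13": 0.12, "14": 0.14, "17": 0.07,
                "18": 0.11, "19": 0.11},
}


@dataclass
class PopulationModel:
    """Sampling model for one synthetic submission."""

    loci: dict[str, dict[str, float]]
    n_individuals: int = 500
    seed: int = 0
    male_fraction: float = 0.5
    include_sex_marker: bool = True
    population_name: str = "Synthetic population"
    region: str = "simulated"
    kit: str = "SimKit 1.0"

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        for locus, spectrum in self.loci.items():
            total = sum(spectrum.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{locus}: spectrum sums to {total}, not 1")


def default_population_model(
    n_individuals: int = 500,
    seed: int = 0,
    n_loci: int = 8,
    include_sex_marker: bool = True,
) -> PopulationModel:
    """A model over the first ``n_loci`` default-spectrum loci.

    The default of 500 individuals sits in the middle of the 100-1000
    genotypes a typical population submission contains.
    """
    names = list(DEFAULT_SPECTRA)[:n_loci]
    return PopulationModel(
        loci={name: dict(DEFAULT_SPECTRA[name]) for name in names},
        n_individuals=n_individuals,
        seed=seed,
        include_sex_marker=include_sex_marker,
    )


def _designation_value(text: str, spec: Optional[LocusSpec]) -> float:
    unit = spec.repeat_unit_length if spec else 4
    d = parse_numeric_lenient(text, spec) if spec else None
    if d is None:
        whole, _, part = text.partition(".")
        return float(whole) + (int(part) / unit if part else 0.0)
    return d.whole_repeats + d.partial_bases / unit


def generate_clean_dataset(
    model: PopulationModel, catalog: Optional[LocusCatalog] = None
) -> Dataset:
    """Draw a clean submission under Hardy-Weinberg proportions.

    Genotypes are independent across loci; allele pairs are written in
    ascending order; sample ids are unique and sequential; the metadata
    declaration matches the content exactly.
    """
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(model.seed)
    n = model.n_individuals
    width = max(4, len(str(n)))
    sample_ids = [f"S{i:0{width}d}" for i in range(1, n + 1)]

    loci_order: list[str] = []
    columns: dict[str, list[list[str]]] = {}
    if model.include_sex_marker:
        loci_order.append("AMEL")
        males = rng.random(n) < model.male_fraction
        columns["AMEL"] = [["X", "Y"] if m else ["X", "X"] for m in males]
    for locus, spectrum in model.loci.items():
        spec = catalog.get(locus)
        alleles = list(spectrum)
        probs = np.asarray([spectrum[a] for a in alleles], dtype=float)
        probs = probs / probs.sum()  # guard fp rounding of configured decimals
        draws = rng.choice(len(alleles), size=(n, 2), p=probs)
        col = []
        for a_idx, b_idx in draws:
            pair = sorted(
                (alleles[a_idx], alleles[b_idx]),
                key=lambda t: _designation_value(t, spec),
            )
            col.append(pair)
        loci_order.append(locus)
        columns[locus] = col

    records = [
        GenotypeRecord(
            sample_id=sample_ids[i],
            genotypes={locus: list(columns[locus][i]) for locus in loci_order},
        )
        for i in range(n)
    ]
    metadata = MetadataDeclaration(
        population_name=model.population_name,
        region=model.region,
        declared_sample_size=n,
        declared_loci=list(loci_order),
        kit=model.kit,
        raw_data_available=True,
        genotypes_unshuffled=True,
        ethics_statement="simulated data; no human subjects",
    )
    return Dataset(
        records=records,
        metadata=metadata,
        method="CE",
        source_path="<synthetic>",
        loci=loci_order,
    )


# --- error injection --------------------------------------------------------

@dataclass
class Injection:
    """One planned corruption: a category, how many occurrences, options."""

    category: str
    occurrences: int = 1
    params: dict = field(default_factory=dict)


@dataclass
class ErrorInjectionPlan:
    injections: list[Injection] = field(default_factory=list)
    seed: int = 0


@dataclass
class ManifestEntry:
    category: str
    kind: str
    sample_id: Optional[str] = None
    locus: Optional[str] = None
    original: object = None
    corrupted: object = None
    details: dict = field(default_factory=dict)


@dataclass
class GroundTruthManifest:
    """The answer key: every corruption applied, with its original value."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def occurrences(self, category: str) -> int:
        return sum(e.details.get("occurrences", 1) for e in self.entries
                   if e.category == category)

    def cells(self, category: str) -> set[tuple[str, str]]:
        return {
            (e.sample_id, e.locus)
            for e in self.entries
            if e.category == category and e.sample_id and e.locus
        }


class _CellPicker:
    """Samples distinct (record, locus) cells across all injections."""

    def __init__(self, dataset: Dataset, catalog: LocusCatalog):
        self.dataset = dataset
        self.catalog = catalog
        self.used: set[tuple[int, str]] = set()

    def pick(self, rng, predicate, count: int) -> list[tuple[int, str]]:
        candidates = [
            (i, locus)
            for i, rec in enumerate(self.dataset.records)
            for locus in self.dataset.loci
            if (i, locus) not in self.used and predicate(rec, locus)
        ]
        if len(candidates) < count:
            raise ValueError(
                f"not enough eligible cells ({len(candidates)} < {count})"
            )
        chosen_idx = rng.choice(len(candidates), size=count, replace=False)
        chosen = [candidates[int(k)] for k in chosen_idx]
        self.used.update(chosen)
        return chosen


def _autosomal(catalog: LocusCatalog, locus: str) -> bool:
    spec = catalog.get(locus)
    return spec is not None and not spec.is_sex_marker


def inject_errors(
    dataset: Dataset,
    plan: ErrorInjectionPlan,
    catalog: Optional[LocusCatalog] = None,
) -> tuple[Dataset, GroundTruthManifest]:
    """Apply exactly the planned corruptions to a copy of the dataset.

    Each category's operator reproduces the real-world mechanism of that
    error (clerical swaps, placeholder strings, dropped alleles, header
    misspellings, column transpositions, rounded-off microvariants, ...).
    Cell-level corruptions land on distinct cells.  Returns the corrupted
    dataset and the manifest; :func:`restore_clean` inverts it.
    """
    catalog = catalog or default_catalog()
    ds = copy.deepcopy(dataset)
    manifest = GroundTruthManifest()
    picker = _CellPicker(ds, catalog)
    for k, injection in enumerate(plan.injections):
        rng = np.random.default_rng([plan.seed, k])
        op = _OPERATORS.get(injection.category)
        if op is None:
            raise ValueError(f"no injection operator for {injection.category!r}")
        op(ds, catalog, picker, rng, injection, manifest)
    return ds, manifest


def _set_cell(ds, manifest, category, kind, i, locus, new_alleles, **details):
    rec = ds.records[i]
    manifest.entries.append(
        ManifestEntry(
            category=category,
            kind=kind,
            sample_id=rec.sample_id,
            locus=locus,
            original=list(rec.genotypes[locus]),
            corrupted=list(new_alleles),
            details=details,
        )
    )
    rec.genotypes[locus] = list(new_alleles)


def _inject_identical(ds, catalog, picker, rng, injection, manifest):
    group_size = int(injection.params.get("group_size", 2))
    for _ in range(injection.occurrences):
        src = int(rng.integers(0, len(ds.records)))
        source = ds.records[src]
        new_ids = []
        for c in range(group_size - 1):
            new_id = f"{source.sample_id}DUP{len(manifest.entries)}{c}"
            ds.records.append(
                GenotypeRecord(
                    sample_id=new_id,
                    genotypes={l: list(a) for l, a in source.genotypes.items()},
                )
            )
            new_ids.append(new_id)
        ds.metadata.declared_sample_size = len(ds.records)
        manifest.entries.append(
            ManifestEntry(
                category="IDENTICAL_GENOTYPES",
                kind="duplicate-records",
                sample_id=source.sample_id,
                details={
                    "added_ids": new_ids,
                    "occurrences": group_size - 1,
                },
            )
        )


def _inject_non_ascending(ds, catalog, picker, rng, injection, manifest):
    clerical = bool(injection.params.get("clerical", False))

    def heterozygous(rec, locus):
        if not _autosomal(catalog, locus):
            return False
        spec = catalog.get(locus)
        a = rec.genotypes.get(locus, [])
        if len(a) != 2:
            return False
        va = _designation_value(a[0], spec) if parse_numeric_lenient(a[0], spec) else None
        vb = _designation_value(a[1], spec) if parse_numeric_lenient(a[1], spec) else None
        if va is None or vb is None or va == vb:
            return False
        if clerical:
            # need a multi-digit second allele whose leading digit can drop
            high = a[1]
            return "." not in high and len(high) >= 2 and int(high[1:]) > 0 and int(high[1:]) < va
        return True

    for i, locus in picker.pick(rng, heterozygous, injection.occurrences):
        a = ds.records[i].genotypes[locus]
        if clerical:
            new = [a[0], a[1][1:]]
        else:
            new = [a[1], a[0]]
        _set_cell(ds, manifest, "NON_ASCENDING", "descending-pair", i, locus, new)


def _inject_nomenclature(ds, catalog, picker, rng, injection, manifest):
    def eligible(rec, locus):
        return _autosomal(catalog, locus) and len(rec.genotypes.get(locus, [])) == 2

    for i, locus in picker.pick(rng, eligible, injection.occurrences):
        a = list(ds.records[i].genotypes[locus])
        which = int(rng.integers(0, 2))
        a[which] = INVALID_DESIGNATIONS[int(rng.integers(0, len(INVALID_DESIGNATIONS)))]
        _set_cell(ds, manifest, "ALLELE_NOMENCLATURE", "invalid-designation", i, locus, a)


def _inject_suspect(ds, catalog, picker, rng, injection, manifest):
    def eligible(rec, locus):
        return _autosomal(catalog, locus) and len(rec.genotypes.get(locus, [])) == 2

    for i, locus in picker.pick(rng, eligible, injection.occurrences):
        spec = catalog.get(locus)
        hi = int(spec.allele_range[1])
        bogus = str(int(rng.integers(hi + 2, min(2 * hi, hi + 6) + 1)))
        a = list(ds.records[i].genotypes[locus])
        a[1] = bogus
        _set_cell(ds, manifest, "ALLELE_CALL_SUSPECT", "out-of-range-allele", i, locus, a)


def _inject_incomplete(ds, catalog, picker, rng, injection, manifest):
    def eligible(rec, locus):
        return _autosomal(catalog, locus) and len(rec.genotypes.get(locus, [])) == 2

    for i, locus in picker.pick(rng, eligible, injection.occurrences):
        mode = injection.params.get("mode") or ("blank" if rng.random() < 0.5 else "zero")
        new = [] if mode == "blank" else ["0", "0"]
        _set_cell(ds, manifest, "INCOMPLETE_GENOTYPE", mode, i, locus, new)


def _misspell(name: str, rng) -> str:
    ops = ["drop", "double", "swap"]
    for _ in range(20):
        op = ops[int(rng.integers(0, len(ops)))]
        pos = int(rng.integers(0, len(name)))
        if op == "drop" and len(name) > 2:
            new = name[:pos] + name[pos + 1:]
        elif op == "double":
            new = name[:pos] + name[pos] + name[pos:]
        elif op == "swap" and pos < len(name) - 1 and name[pos] != name[pos + 1]:
            new = name[:pos] + name[pos + 1] + name[pos] + name[pos + 2:]
        else:
            continue
        if new != name:
            return new
    return name + "X"


def _inject_locus_name(ds, catalog, picker, rng, injection, manifest):
    eligible = [l for l in ds.loci if _autosomal(catalog, l)]
    if injection.occurrences > len(eligible):
        raise ValueError("more locus-name corruptions than loci")
    chosen_idx = rng.choice(len(eligible), size=injection.occurrences, replace=False)
    for k in chosen_idx:
        old = eligible[int(k)]
        new = _misspell(old, rng)
        while catalog.get(new) is not None or new in ds.loci:
            new = _misspell(new, rng)
        ds.loci[ds.loci.index(old)] = new
        for rec in ds.records:
            rec.genotypes[new] = rec.genotypes.pop(old)
        if old in ds.metadata.declared_loci:
            ds.metadata.declared_loci[ds.metadata.declared_loci.index(old)] = new
        manifest.entries.append(
            ManifestEntry(
                category="LOCUS_NOMENCLATURE",
                kind="misspelled-header",
                locus=new,
                original=old,
                corrupted=new,
            )
        )


def _inject_aneuploidy(ds, catalog, picker, rng, injection, manifest):
    def eligible(rec, locus):
        return _autosomal(catalog, locus) and len(rec.genotypes.get(locus, [])) == 2

    for i, locus in picker.pick(rng, eligible, injection.occurrences):
        a = list(ds.records[i].genotypes[locus])
        mode = injection.params.get("mode") or ("drop" if rng.random() < 0.5 else "extra")
        if mode == "drop":
            new = [a[0]]
        else:
            spectrum = sorted({a[0], a[1]})
            new = a + [spectrum[0]]
        _set_cell(ds, manifest, "ANEUPLOIDY", mode, i, locus, new)


def _inject_killer(ds, catalog, picker, rng, injection, manifest):
    mode = injection.params.get("mode", "raw_data")
    for _ in range(injection.occurrences):
        if mode == "raw_data":
            manifest.entries.append(
                ManifestEntry(
                    category="QC_KILLER", kind="attestation-raw-data",
                    original=ds.metadata.raw_data_available, corrupted=False,
                )
            )
            ds.metadata.raw_data_available = False
        elif mode == "shuffle_attestation":
            manifest.entries.append(
                ManifestEntry(
                    category="QC_KILLER", kind="attestation-unshuffled",
                    original=ds.metadata.genotypes_unshuffled, corrupted=False,
                )
            )
            ds.metadata.genotypes_unshuffled = False
        elif mode == "shuffle":
            perm = rng.permutation(len(ds.records))
            originals = [
                {l: list(a) for l, a in rec.genotypes.items()} for rec in ds.records
            ]
            for i, rec in enumerate(ds.records):
                rec.genotypes = {
                    l: list(a) for l, a in originals[int(perm[i])].items()
                }
            manifest.entries.append(
                ManifestEntry(
                    category="QC_KILLER", kind="shuffled-genotypes",
                    details={"permutation": [int(p) for p in perm]},
                    original=originals,
                )
            )
        else:
            raise ValueError(f"unknown QC_KILLER mode {mode!r}")


def _inject_duplicate_id(ds, catalog, picker, rng, injection, manifest):
    for _ in range(injection.occurrences):
        i, j = rng.choice(len(ds.records), size=2, replace=False)
        i, j = int(i), int(j)
        if ds.records[i].genotypes == ds.records[j].genotypes:
            continue
        manifest.entries.append(
            ManifestEntry(
                category="DUPLICATE_IDENTIFIER",
                kind="reused-identifier",
                sample_id=ds.records[i].sample_id,
                original=ds.records[j].sample_id,
                corrupted=ds.records[i].sample_id,
                details={"record_index": j},
            )
        )
        ds.records[j].sample_id = ds.records[i].sample_id


def _inject_info_mismatch(ds, catalog, picker, rng, injection, manifest):
    for _ in range(injection.occurrences):
        mode = injection.params.get("mode") or (
            "sample_size" if rng.random() < 0.5 else "extra_locus"
        )
        if mode == "sample_size":
            delta = int(rng.integers(1, 6))
            manifest.entries.append(
                ManifestEntry(
                    category="INFO_MISMATCH", kind="declared-sample-size",
                    original=ds.metadata.declared_sample_size,
                    corrupted=ds.metadata.declared_sample_size + delta,
                )
            )
            ds.metadata.declared_sample_size += delta
        else:
            bogus = "SE33" if "SE33" not in ds.metadata.declared_loci else "PentaE"
            manifest.entries.append(
                ManifestEntry(
                    category="INFO_MISMATCH", kind="declared-extra-locus",
                    original=list(ds.metadata.declared_loci), corrupted=bogus,
                )
            )
            ds.metadata.declared_loci.append(bogus)


def _inject_locus_swap(ds, catalog, picker, rng, injection, manifest):
    pair = injection.params.get("loci")
    if pair is None:
        # prefer a pair whose spectra occupy disjoint parts of their ranges
        preferred = [("TH01", "FGA"), ("TH01", "vWA"), ("TPOX", "FGA")]
        pair = next(
            (p for p in preferred if p[0] in ds.loci and p[1] in ds.loci), None
        )
        if pair is None:
            raise ValueError("no suitable locus pair for a swap; pass params['loci']")
    a, b = pair
    for _ in range(injection.occurrences):
        for rec in ds.records:
            rec.genotypes[a], rec.genotypes[b] = rec.genotypes[b], rec.genotypes[a]
        manifest.entries.append(
            ManifestEntry(
                category="LOCUS_SWAP", kind="transposed-columns",
                original=[a, b], corrupted=[b, a], details={"loci": [a, b]},
            )
        )


def _inject_lost_intermediates(ds, catalog, picker, rng, injection, manifest):
    locus = injection.params.get("locus")
    if locus is None:
        locus = next(
            (
                l
                for l in ds.loci
                if catalog.get(l) is not None and catalog.get(l).expected_intermediates
            ),
            None,
        )
        if locus is None:
            raise ValueError("no locus with expected intermediates in the dataset")
    spec = catalog.get(locus)
    for _ in range(injection.occurrences):
        changed = []
        for rec in ds.records:
            alleles = rec.genotypes.get(locus, [])
            rounded = []
            touched = False
            for raw in alleles:
                d = parse_numeric_lenient(raw, spec)
                if d is not None and d.partial_bases:
                    rounded.append(str(d.whole_repeats))
                    touched = True
                else:
                    rounded.append(raw)
            if touched:
                changed.append((rec.sample_id, list(alleles), rounded))
                rec.genotypes[locus] = rounded
        manifest.entries.append(
            ManifestEntry(
                category="LOST_INTERMEDIATE",
                kind="rounded-microvariants",
                locus=locus,
                original=[(s, a) for s, a, _ in changed],
                details={"cells_changed": len(changed)},
            )
        )


_OPERATORS = {
    "IDENTICAL_GENOTYPES": _inject_identical,
    "NON_ASCENDING": _inject_non_ascending,
    "ALLELE_NOMENCLATURE": _inject_nomenclature,
    "ALLELE_CALL_SUSPECT": _inject_suspect,
    "INCOMPLETE_GENOTYPE": _inject_incomplete,
    "LOCUS_NOMENCLATURE": _inject_locus_name,
    "ANEUPLOIDY": _inject_aneuploidy,
    "QC_KILLER": _inject_killer,
    "DUPLICATE_IDENTIFIER": _inject_duplicate_id,
    "INFO_MISMATCH": _inject_info_mismatch,
    "LOCUS_SWAP": _inject_locus_swap,
    "LOST_INTERMEDIATE": _inject_lost_intermediates,
}


def restore_clean(corrupted: Dataset, manifest: GroundTruthManifest) -> Dataset:
    """Invert a manifest, reproducing the clean dataset exactly."""
    ds = copy.deepcopy(corrupted)
    for entry in reversed(manifest.entries):
        if entry.kind == "duplicate-records":
            added = set(entry.details["added_ids"])
            ds.records = [r for r in ds.records if r.sample_id not in added]
            ds.metadata.declared_sample_size = len(ds.records)
        elif entry.kind == "misspelled-header":
            new, old = entry.corrupted, entry.original
            ds.loci[ds.loci.index(new)] = old
            for rec in ds.records:
                rec.genotypes[old] = rec.genotypes.pop(new)
            if new in ds.metadata.declared_loci:
                ds.metadata.declared_loci[ds.metadata.declared_loci.index(new)] = old
        elif entry.kind == "attestation-raw-data":
            ds.metadata.raw_data_available = entry.original
        elif entry.kind == "attestation-unshuffled":
            ds.metadata.genotypes_unshuffled = entry.original
        elif entry.kind == "shuffled-genotypes":
            for rec, genotypes in zip(ds.records, entry.original):
                rec.genotypes = {l: list(a) for l, a in genotypes.items()}
        elif entry.kind == "reused-identifier":
            ds.records[entry.details["record_index"]].sample_id = entry.original
        elif entry.kind == "declared-sample-size":
            ds.metadata.declared_sample_size = entry.original
        elif entry.kind == "declared-extra-locus":
            ds.metadata.declared_loci = list(entry.original)
        elif entry.kind == "transposed-columns":
            a, b = entry.details["loci"]
            for rec in ds.records:
                rec.genotypes[a], rec.genotypes[b] = rec.genotypes[b], rec.genotypes[a]
        elif entry.kind == "rounded-microvariants":
            for sample_id, alleles in entry.original:
                for rec in ds.records:
                    if rec.sample_id == sample_id:
                        rec.genotypes[entry.locus] = list(alleles)
                        break
        elif entry.sample_id is not None and entry.locus is not None:
            for rec in ds.records:
                if (
                    rec.sample_id == entry.sample_id
                    and rec.genotypes.get(entry.locus) == entry.corrupted
                ):
                    rec.genotypes[entry.locus] = list(entry.original)
                    break
        else:
            raise ValueError(f"cannot invert manifest entry {entry.kind!r}")
    return ds


# --- MPS fixtures ------------------------------------------------------------

def _build_sequence(spec: LocusSpec, whole: int, partial: int) -> str:
    motif = next(b.motif for b in spec.repeat_structure if b.counted)
    return spec.flank_5 + motif * whole + motif[:partial] + spec.flank_3


def generate_mps_fixture(
    model: PopulationModel, catalog: Optional[LocusCatalog] = None
) -> tuple[list[MPSAlleleSequence], Dataset]:
    """Sequenced-allele fixture plus the matching declared CE table.

    Only model loci with a configured repeat structure are emitted.  Each
    allele's sequence is flank5 + motif repeats (+ partial prefix) + flank3
    and its declared CE value is the generating designation, so a clean
    fixture round-trips with zero findings.
    """
    catalog = catalog or default_catalog()
    structured = [l for l in model.loci if (catalog.get(l) or LocusSpec("?")).repeat_structure]
    if not structured:
        raise ValueError("model contains no loci with repeat structures")
    sub_model = PopulationModel(
        loci={l: model.loci[l] for l in structured},
        n_individuals=model.n_individuals,
        seed=model.seed,
        include_sex_marker=False,
        population_name=model.population_name,
        region=model.region,
        kit=model.kit,
    )
    ce = generate_clean_dataset(sub_model, catalog)
    ce.method = "MPS"
    sequences = []
    for rec in ce.records:
        for locus in ce.loci:
            spec = catalog.get(locus)
            for idx, designation in enumerate(rec.genotypes[locus], start=1):
                d = parse_numeric_lenient(designation, spec)
                sequences.append(
                    MPSAlleleSequence(
                        sample_id=rec.sample_id,
                        locus=locus,
                        allele_index=idx,
                        sequence=_build_sequence(spec, d.whole_repeats, d.partial_bases),
                        declared_ce_allele=designation,
                    )
                )
    return sequences, ce


def corrupt_mps(
    sequences: Sequence[MPSAlleleSequence],
    kind: str,
    count: int,
    seed: int,
    catalog: Optional[LocusCatalog] = None,
) -> tuple[list[MPSAlleleSequence], list[int]]:
    """Corrupt ``count`` distinct fixture alleles; returns (copy, indices).

    Kinds: ``substitution`` (one base changed inside the repeat tract,
    breaking the structure parse), ``reverse_complement`` (orientation
    error), ``flank_deletion`` (one repeat-unit deletion in the 5' flank
    with the declared CE kept length-consistent — an expected FR
    discrepancy), ``misdeclared_ce`` (declared CE off by one repeat).
    """
    from Bio.Seq import reverse_complement

    catalog = catalog or default_catalog()
    rng = np.random.default_rng(seed)
    out = [copy.deepcopy(s) for s in sequences]
    idx = [int(i) for i in rng.choice(len(out), size=count, replace=False)]
    for i in idx:
        s = out[i]
        spec = catalog.get(s.locus)
        unit = spec.repeat_unit_length
        if kind == "substitution":
            pos = len(spec.flank_5) + unit + 1  # inside the second motif copy
            old = s.sequence[pos]
            new = {"A": "C", "C": "G", "G": "T", "T": "A"}[old]
            s.sequence = s.sequence[:pos] + new + s.sequence[pos + 1:]
        elif kind == "reverse_complement":
            s.sequence = reverse_complement(s.sequence)
        elif kind == "flank_deletion":
            s.sequence = s.sequence[unit:]  # delete one unit off the 5' end
            d = parse_numeric_lenient(s.declared_ce_allele, spec)
            total = d.whole_repeats * unit + d.partial_bases - unit
            whole, partial = divmod(total, unit)
            s.declared_ce_allele = f"{whole}.{partial}" if partial else str(whole)
        elif kind == "misdeclared_ce":
            d = parse_numeric_lenient(s.declared_ce_allele, spec)
            s.declared_ce_allele = (
                f"{d.whole_repeats + 1}.{d.partial_bases}"
                if d.partial_bases
                else str(d.whole_repeats + 1)
            )
        else:
            raise ValueError(f"unknown MPS corruption {kind!r}")
    return out, idx
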