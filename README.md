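# strqc

Quality control for forensic autosomal STR population datasets.

Forensic DNA laboratories estimate match probabilities from population
allele-frequency databases of short tandem repeat (STR) loci.  Those
databases are only as good as the genotype tables laboratories submit to
them, and submitted tables recurrently contain duplicated profiles,
transcription errors, malformed allele designations, shuffled rows and
swapped locus columns.  `strqc` implements a centralized-database-style
quality-control pipeline for such submissions: rule-based detectors for an
error taxonomy of twelve capillary-electrophoresis (CE) categories plus
sequence-specific checks for massively parallel sequencing (MPS) data, a
fixed decision rule that accepts or rejects a dataset, and allele-frequency
tables with the conventional minimum-frequency floor.  It is aimed at
population-genetics labs preparing submissions and at database curators
auditing them.

## What it checks and decides

**CE error categories** (each detector returns located findings, never
exceptions): identical genotypes (duplicate profiles agreeing at more than
15 co-typed loci, unordered allele pairs, within and across datasets);
non-ascending allele pairs (`12|6` instead of `6|12`); allele designations
outside the forensic grammar (`9+`, `−9`, `18.9`, `9,3`, `OL`, amelogenin
`Y|Y`); implausible allele calls needing raw-data adjudication; incomplete
genotypes (missing pairs, `0|0`); wrong locus names (with edit-distance
suggestions; alias spellings like `HUMVWA`/`vWA` are accepted); aneuploid
cells; "QC killers" (missing raw data, shuffled genotypes); reused sample
identifiers; metadata mismatches; whole-column locus swaps; and microvariant
alleles lost to rounding (`9.3` reported as `9`).

**Decision rule.** Let `e_k` be confirmed error occurrences in category
`k`, `E = Σ e_k`, and `C = #{k : e_k > 0}`.  A dataset is rejected,
independent of its size, iff

    killer  ∨  E > 7  ∨  max_k e_k > 5  ∨  (C ≥ 3 ∧ E > 5)  ∨  C > 3

Unconfirmed suspect findings block acceptance (status `PENDING`) until
adjudicated.  A passing dataset receives a unique, content-idempotent
accession number.

**Frequencies.** For locus *L* typed in `n_L` complete diploid genotypes,
allele *i* with count `c_i` has raw frequency `p_i = c_i / 2n_L` and
floored frequency `max(p_i, 5/2n_L)` — the casework minimum-frequency
bound.  `2n_L` is adapted per locus for incomplete and tri-allelic cells.
Observed and bias-corrected expected heterozygosity
`(2n/(2n−1))(1 − Σp_i²)` are reported per locus.

**MPS checks.** Sequenced alleles are parsed against per-locus repeat
structures between fixed flank anchors, orientation is resolved (reverse
reporting is a finding), and the sequence-based repeat count is translated
to the length-based CE designation and compared with the submitter's
declared value; a mismatch exactly explained by a flanking-region indel is
classified as an expected discrepancy, not an error.

## Worked example

```python
from strqc import default_catalog, run_qc
from strqc.synthdata import (ErrorInjectionPlan, Injection,
                             default_population_model, generate_clean_dataset,
                             inject_errors)
from strqc.frequencies import compute_frequencies

catalog = default_catalog()
model = default_population_model(n_individuals=500, seed=42)
clean = generate_clean_dataset(model, catalog)

plan = ErrorInjectionPlan(
    [Injection("NON_ASCENDING", 3), Injection("ALLELE_NOMENCLATURE", 2)],
    seed=7,
)
corrupted, manifest = inject_errors(clean, plan, catalog)

result = run_qc(corrupted, catalog)
print("verdict:", result.verdict.status)
print("total errors:", result.counts.total,
      "categories:", result.counts.categories_present)
for f in result.findings[:3]:
    print(f"  [{f.category.value}] {f.sample_ids[0]} @ {f.locus}: {f.message}")
```

prints

```
verdict: PASS
total errors: 5 categories: 2
  [ALLELE_NOMENCLATURE] S0386 @ TH01: '18.9': partial-ge-repeat-unit
  [ALLELE_NOMENCLATURE] S0435 @ D8S1179: '0': zero
  [NON_ASCENDING] S0342 @ vWA: alleles 18|15 not in ascending order
```

Five confirmed errors across two categories stay within every rejection
bound (≤ 7 total, ≤ 5 per category, fewer than three categories), so the
dataset passes despite the findings.  Frequencies for the clean dataset:

```python
table = compute_frequencies(clean, catalog, verdict=None)
print(table.to_frame().query("locus == 'TH01'").to_string(index=False))
```

```
locus allele  count  alleles_sampled   raw  floored  floor_applied
 TH01      6    239             1000 0.239    0.239          False
 TH01      7    162             1000 0.162    0.162          False
 TH01      8    116             1000 0.116    0.116          False
 TH01      9    132             1000 0.132    0.132          False
 TH01    9.3    291             1000 0.291    0.291          False
 TH01     10     60             1000 0.060    0.060          False
```

With 500 individuals all counts exceed five copies, so no floor is
applied; a singleton allele would instead be reported at 5/1000 = 0.005.

## Command line

```sh
strqc simulate --out-dir fixture --seed 3 --n 200        # synthetic submission
strqc qc --input fixture/genotypes.csv --metadata fixture/metadata.yaml
strqc freq --input fixture/genotypes.csv --metadata fixture/metadata.yaml
strqc mps-check --sequences seqs.fasta --metadata metadata.yaml
```

Exit codes: 0 = PASS, 1 = REJECT, 2 = PENDING, 3 = configuration or I/O
error.  Reports are written in plain text and as schema-versioned JSON.

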