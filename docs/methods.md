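# Methods

## Scope and model of the data

`strqc` treats a population-dataset submission as an ordered genotype
table: one row per individual, a sample identifier, and per locus an
ordered list of allele designation strings exactly as submitted.  All
parsing is string-first; nothing is coerced to numbers at read time,
because several error classes (placeholder codes, column shifts, `12.0`
vs `12`, shuffled rows) are only observable on the verbatim text and its
order.  Numeric interpretation happens in one place, the allele-designation
grammar of the locus catalog.

An allele designation is `w` or `w.b`: `w` whole repeats of the locus
repeat unit (u bases, typically 4) plus `b` extra bases, `0 < b < u`.  The
total fragment-length contribution is `w·u + b`, which also defines the
ascending-order comparison (so `9.3` sorts between `9` and `10` on a
tetranucleotide).

### Two-tier plausibility

The grammar distinguishes malformed from implausible from merely suspect:

* grammar violations (signs, commas, letters, `b ≥ u`, zero) are
  nomenclature errors;
* a whole-repeat count above **twice the locus range maximum** is treated
  as a nomenclature error too ("highly implausible"; e.g. `115`, `1314`
  under any realistic range);
* anything well-formed inside that extended window but outside the
  configured allele range (e.g. `44` under a range of 5–25) parses as a
  valid number and becomes an *allele-call suspect*, which requires
  raw-data adjudication before it counts toward a verdict.

The factor two is a design choice: it must admit alleles plausibly caused
by transcription slips near the range while excluding three-digit
absurdities; the boundary between "rare" and "implausible" is ultimately
per-locus configuration (`allele_range`).  The designations `1` and `99`
are reserved: historically used both as software placeholders and as
codes for rare off-ladder alleles, they are accepted (as placeholders,
producing no finding) only behind an explicit per-submission flag, and are
invalid otherwise.

### Locus names

Lookup is insensitive to case, spaces and hyphens, and aliases
(`HUMVWA`/`VWA`/`vWA`, `Penta D`/`PentaD`) resolve without a finding.  A
name that matches no catalog entry is an error; suggestions are ranked by
Damerau–Levenshtein distance ≤ 2 (implemented in-package; transpositions
matter for dragging/typo errors like `SEE33`).  An exact match is never
fuzzy-merged into a neighbour (`D2S441` stays distinct from `D2S411`).  A
header whose names mostly parse as genotypes is reported once as a
missing header row rather than as per-name errors.

## Detectors

Each detector is a pure function from a dataset (plus catalog/config) to a
list of findings; running it twice gives identical output, and malformed
input yields findings, not exceptions.  Non-obvious rules:

* **Identical genotypes** — two profiles are duplicates iff the number of
  co-typed loci with equal unordered allele pairs is **strictly greater
  than 15** and no co-typed locus disagrees.  The disagreement veto is a
  conservative reconstruction: partial matches (relatives) are out of
  scope.  Groups are connected components of the match relation; a group
  of c profiles counts c − 1 occurrences.  Comparison uses unordered
  pairs, so non-ascending cells cannot mask duplicates.
* **Aneuploidy** — cells with one or ≥ 3 alleles; tri-allelic cells are
  marked for exclusion from frequency counting.  A locus non-diploid in
  *every* typed record escalates to a single locus-scope finding (one
  systematic cause, one occurrence) instead of per-cell findings.
* **Locus swap** — heuristic: for a locus pair (A, B), the fraction of
  records whose A-column alleles fall outside A's range but inside B's,
  and symmetrically; both fractions ≥ 0.8 over ≥ 20 assessable records
  flag the pair.  Swap detection parses leniently (grammar only, no
  plausibility window), since transposed alleles are expected to be
  implausible for the column they sit in.  Loci with heavily overlapping
  ranges are a documented blind spot of any range-based rule.
* **Lost intermediates** — a locus configured with expected microvariants
  (default catalog: TH01 `9.3` at a minimum population frequency of 0.15)
  and ≥ 100 typed individuals is flagged when *zero* partial-repeat
  alleles are observed although the expected frequency implies ≥ 5
  copies.  This is a conspicuity (unconfirmed suspect), not an error,
  until adjudicated.
* **Killers** — attestation-based: raw data unavailable or genotypes not
  submitted in original order.  How shuffling could be detected from the
  table alone is not specifiable; beyond the attestation, an optional
  audit compares submitted genotypes against a supplied raw-data
  reference table by sample id and reports discordant records as killers.
* **0|0 cells** are counted once, as incomplete genotypes, not
  additionally as two zero-designation nomenclature errors.

## Decision rule

Counts are *confirmed occurrences* (cell-scope findings count 1, an
identical-profile group of c counts c − 1, dataset- and locus-scope
findings count 1).  Occurrences rather than error types: with twelve
categories and a per-category cap of five, a type-count reading of "more
than seven errors" would be unreachable before the other rules fire.
Rejection, applied independent of dataset size:

* any killer;
* total > 7;
* any single category > 5;
* total > 5 with **three or more** categories present;
* more than three categories present.

The three-or-more reading of the combined rule is deliberate: read as
"> 3" it would be implied by the final rule and redundant.  Unconfirmed
suspects put the verdict in `PENDING` (accession withheld) until
adjudications — `(sample, locus, confirmed_error | verified_correct)` —
resolve them.  MPS verdicts exclude findings confined to the declared
CE-translation table; those are still reported because they frequently
point at problems in the sequence data itself.

Accessions are `STRQC` + six-digit sequence + weighted modulo-36 check
character, issued from an append-only ledger keyed by a content hash, so
re-submitting identical content re-issues the same accession.  The format
is artifact-specific (no public format exists to follow).

## Frequencies

Per locus, only complete diploid cells with two well-formed numeric
designations count; homozygotes contribute two copies to one allele;
tri-allelic and incomplete cells are excluded and `2n_L` is reduced
accordingly (failing to adapt `2n` is itself a known error source in
submitted datasets).  Raw frequencies sum to one per locus to 1e−12.
Floored frequencies `max(p, 5/2n_L)` are reported in a separate column and
deliberately **not renormalized**: the floor is a casework lower bound,
and renormalizing would destroy the sum-to-one property of the raw
column.  `floor_applied` is exactly `count < 5`.  Sex-marker columns are
never frequency-databased.  Expected heterozygosity uses the small-sample
correction `(2n/(2n−1))(1 − Σp²)`.

## MPS parsing

A repeat structure is an ordered list of motif blocks (each with count
bounds and a `counted` flag) between reference 5'/3' flanks.  Parsing is
greedy and anchored, not alignment-based: the 10 bases of flank adjacent
to the repeat region on each side serve as anchors; between them each
block's motif is matched left-to-right maximizing its count, and up to
u − 1 trailing bases matching a prefix of the final counted motif become
the partial.  Greedy anchored matching is adequate for validating
submitted allele strings — any sequence it cannot explain is exactly what
the check should flag.  Consequences and conventions:

* flank length deviations outside the anchors are recorded as a signed
  FR-indel offset; an indel *inside* an anchor makes the sequence an
  erroneous-sequence finding (accepted limitation);
* a sequence with no 5' (or 3') flank at all, beginning (ending) in ≥ 2
  motif copies, is classified separately as *insufficient flanking
  region*, since QC cannot assess what is not there;
* orientation: forward parse first, then the reverse complement; success
  only on the reverse strand is a finding (non-compliant reporting
  direction) but the parse is still used;
* CE translation: whole repeats = Σ counted block counts, partial =
  leftover bases.  The *length-equivalent* designation folds the FR
  offset into the arithmetic; a declared CE value matching the
  length-equivalent (offset ≠ 0) is an expected discrepancy
  (informational), any other mismatch is a counting error.  Isometric
  same-length alleles are reported by length equivalence only; sequence
  nomenclature strings are never emitted.

The default catalog ships simplified single-motif structures for TH01 and
D5S818 with synthetic (non-genomic) flank sequences — enough to exercise
every MPS code path without redistributing reference sequence data; real
deployments should configure real structures per locus.

## Synthetic data

The generator emulates a typical population submission: 100–1000
individuals (default 500), genotypes drawn independently per locus under
Hardy–Weinberg proportions from configured spectra, pairs written
ascending, sequential sample ids, metadata consistent with content.  The
default spectra cover 21 common forensic loci with plausible
European-like frequencies (two-decimal values summing to one, microvariants
included so partial-repeat ordering is exercised); the default model uses
the first eight loci plus amelogenin, and duplicate-detection tests use 21
loci so the >15-locus rule is reachable.  A single root seed is fanned out
per injection operator, so any corruption is reproducible in isolation.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage and substructure (loci are independent;
no inbreeding coefficient), mutation and null alleles, kit-specific
artifacts (stutter, pull-up), relatedness between sampled individuals,
population-specific spectra, and the messy formatting diversity of real
spreadsheets beyond the two declared dialects.

Each injection operator reproduces one category's real-world mechanism
(verbatim record duplication under fresh ids, order swaps or clerical
digit drops, invalid designation strings actually seen in submissions,
out-of-range substitutions, blanked or `0|0` cells, header misspellings,
allele drops/additions, attestation falsification or row permutation, id
reuse, metadata perturbation, whole-column transposition, rounding away
all microvariants at a locus).  The ground-truth manifest records every
change with its original value; applying it in reverse restores the clean
dataset exactly, which the tests assert.

## Problem sizes and tolerances in the test suite

Detector recall/precision runs 100 seeded fixtures of 100–1000
individuals at eight autosomal loci; duplicate-oracle agreement uses
200-record, 21-locus fixtures; the decision oracle enumerates 10⁴ random
tallies; MPS round-trips 100 fixture alleles; spectrum recovery at
n = 1000 checks every allele count against central 99% binomial bands.
Frequency-sum assertions use 1e−12; heterozygosity two-path comparisons
1e−12; the large-n heterozygosity limit 2e−3.

## Known limitations

* The two CE table dialects are a reconstruction; no public submission
  template exists.  Auto-detection is refused to avoid silent misparses.
* The duplicate rule's disagreement veto means a copied profile with one
  subsequently corrupted locus is not reported as a duplicate (it will
  usually surface through other categories).
* Range-based swap detection cannot see swaps between loci with
  coinciding allele ranges.
* Shuffled genotypes are only detectable via attestation or a raw-data
  reference; the table alone carries no signal.
* Statistical population-genetics tests (HWE departure, F-statistics,
  match probabilities) are intentionally out of scope: the pipeline
  audits data integrity, not population genetics.
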