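"""Generator determinism, sampling fidelity, injection ground truth and
end-to-end soundness of the corruption -> detection -> decision chain."""

import pytest

from strqc import default_catalog
from strqc.ce_checks import ErrorCategory
from strqc.pipeline import run_qc
from strqc.synthdata import (
    DEFAULT_SPECTRA,
    ErrorInjectionPlan,
    Injection,
    default_population_model,
    generate_clean_dataset,
    inject_errors,
    restore_clean,
)


@pytest.fixture(scope="module")
def catalog():
    return default_catalog()


class TestGenerator:
    def test_seed_determinism(self, catalog):
        a = generate_clean_dataset(default_population_model(100, seed=4), catalog)
        b = generate_clean_dataset(default_population_model(100, seed=4), catalog)
        assert a == b
        c = generate_clean_dataset(default_population_model(100, seed=5), catalog)
        assert a != c

    def test_spectra_respected_within_binomial_bounds(self, catalog):
        from scipy.stats import binom

        ds = generate_clean_dataset(default_population_model(1000, seed=2), catalog)
        counts = {}
        for rec in ds.records:
            for a in rec.genotypes["TH01"]:
                counts[a] = counts.get(a, 0) + 1
        two_n = 2 * len(ds.records)
        for allele, p in DEFAULT_SPECTRA["TH01"].items():
            lo = binom.ppf(0.005, two_n, p)
            hi = binom.ppf(0.995, two_n, p)
            assert lo <= counts.get(allele, 0) <= hi

    def test_alleles_written_ascending(self, catalog):
        ds = generate_clean_dataset(default_population_model(200, seed=6), catalog)
        for rec in ds.records:
            for locus, alleles in rec.genotypes.items():
                spec = catalog.get(locus)
                if spec.is_sex_marker:
                    continue
                values = [spec.designation_value(a) for a in alleles]
                assert values == sorted(values)

    def test_metadata_consistent_with_content(self, catalog):
        ds = generate_clean_dataset(default_population_model(150, seed=1), catalog)
        assert ds.metadata.declared_sample_size == len(ds.records)
        assert ds.metadata.declared_loci == ds.loci
        ids = [r.sample_id for r in ds.records]
        assert len(set(ids)) == len(ids)

    def test_clean_dataset_passes_qc_with_zero_findings(self, catalog):
        ds = generate_clean_dataset(default_population_model(300, seed=11), catalog)
        result = run_qc(ds, catalog)
        assert result.findings == []
        assert result.verdict.status == "PASS"
        assert result.verdict.accession

    def test_spectrum_must_sum_to_one(self):
        from strqc.synthdata import PopulationModel

        with pytest.raises(ValueError, match="sums to"):
            PopulationModel(loci={"X": {"8": 0.5, "9": 0.4}})


class TestInjection:
    def test_empty_plan_is_identity(self, catalog):
        clean = generate_clean_dataset(default_population_model(100, seed=3), catalog)
        corrupted, manifest = inject_errors(clean, ErrorInjectionPlan(), catalog)
        assert corrupted == clean and manifest.entries == []

    def test_manifest_inverse_restores_clean(self, catalog):
        clean = generate_clean_dataset(default_population_model(150, seed=7), catalog)
        plan = ErrorInjectionPlan(
            injections=[
                Injection("LOCUS_NOMENCLATURE", 1),
                Injection("IDENTICAL_GENOTYPES", 1, {"group_size": 3}),
                Injection("NON_ASCENDING", 3),
                Injection("ALLELE_NOMENCLATURE", 2),
                Injection("ALLELE_CALL_SUSPECT", 2),
                Injection("INCOMPLETE_GENOTYPE", 2),
                Injection("ANEUPLOIDY", 2),
                Injection("DUPLICATE_IDENTIFIER", 1),
                Injection("INFO_MISMATCH", 1),
                Injection("LOCUS_SWAP", 1),
                Injection("LOST_INTERMEDIATE", 1),
                Injection("QC_KILLER", 1),
            ],
            seed=13,
        )
        corrupted, manifest = inject_errors(clean, plan, catalog)
        assert corrupted != clean
        assert restore_clean(corrupted, manifest) == clean

    def test_injection_is_seed_deterministic(self, catalog):
        clean = generate_clean_dataset(default_population_model(120, seed=9), catalog)
        plan = ErrorInjectionPlan([Injection("NON_ASCENDING", 4)], seed=21)
        a, ma = inject_errors(clean, plan, catalog)
        b, mb = inject_errors(clean, plan, catalog)
        assert a == b and ma == mb

    def test_duplicate_group_occurrence_counting(self, catalog):
        from strqc.ce_checks import check_identical_genotypes
        from strqc.decision import tally

        clean = generate_clean_dataset(
            default_population_model(80, seed=2, n_loci=21), catalog
        )
        plan = ErrorInjectionPlan(
            [Injection("IDENTICAL_GENOTYPES", 1, {"group_size": 3})], seed=4
        )
        corrupted, _ = inject_errors(clean, plan, catalog)
        counts = tally(check_identical_genotypes(corrupted))
        assert counts.per_category["IDENTICAL_GENOTYPES"] == 2

    def test_clerical_digit_drop_variant(self, catalog):
        clean = generate_clean_dataset(default_population_model(200, seed=5), catalog)
        plan = ErrorInjectionPlan(
            [Injection("NON_ASCENDING", 2, {"clerical": True})], seed=8
        )
        corrupted, manifest = inject_errors(clean, plan, catalog)
        for entry in manifest.entries:
            orig, corr = entry.original, entry.corrupted
            assert corr[0] == orig[0] and corr[1] == orig[1][1:]

    def test_rounded_microvariants_vanish(self, catalog):
        clean = generate_clean_dataset(default_population_model(500, seed=6), catalog)
        plan = ErrorInjectionPlan([Injection("LOST_INTERMEDIATE", 1)], seed=2)
        corrupted, manifest = inject_errors(clean, plan, catalog)
        locus = manifest.entries[0].locus
        for rec in corrupted.records:
            assert all("." not in a for a in rec.genotypes[locus])


class TestEndToEndSoundness:
    """Plans violating a rejection threshold end in REJECT; plans within
    all bounds end in PASS (suspects pre-adjudicated as confirmed)."""

    @staticmethod
    def _verdict(catalog, injections, seed=31):
        clean = generate_clean_dataset(
            default_population_model(300, seed=seed), catalog
        )
        corrupted, manifest = inject_errors(
            clean, ErrorInjectionPlan(list(injections), seed=seed), catalog
        )
        adjudications = [
            (s, l, "confirmed_error")
            for s, l in manifest.cells("ALLELE_CALL_SUSPECT")
        ]
        return run_qc(corrupted, catalog, adjudications=adjudications).verdict

    def test_within_all_bounds_passes(self, catalog):
        verdict = self._verdict(
            catalog,
            [Injection("NON_ASCENDING", 5), Injection("ALLELE_NOMENCLATURE", 2)],
        )
        assert verdict.status == "PASS"

    def test_total_over_seven_rejects(self, catalog):
        verdict = self._verdict(
            catalog,
            [Injection("NON_ASCENDING", 5), Injection("ALLELE_NOMENCLATURE", 3)],
        )
        assert verdict.status == "REJECT"
        assert "total>7" in verdict.triggered_rules

    def test_single_category_over_five_rejects(self, catalog):
        verdict = self._verdict(catalog, [Injection("NON_ASCENDING", 6)])
        assert verdict.status == "REJECT"
        assert "category>5" in verdict.triggered_rules

    def test_killer_rejects_clean_content(self, catalog):
        verdict = self._verdict(catalog, [Injection("QC_KILLER", 1)])
        assert verdict.status == "REJECT"
        assert "qc-killer" in verdict.triggered_rules
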