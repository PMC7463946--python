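"""Unit tests for the twelve CE error detectors."""

import pytest

from strqc.catalog import LocusCatalog, LocusSpec
from strqc.ce_checks import (
    ErrorCategory,
    apply_adjudications,
    check_allele_nomenclature,
    check_allele_order,
    check_allele_plausibility,
    check_completeness,
    check_identical_genotypes,
    check_identifiers,
    check_killers,
    check_locus_names,
    check_locus_swap,
    check_lost_intermediates,
    check_metadata_match,
    check_ploidy,
    check_raw_concordance,
)
from strqc.synthdata import default_population_model, generate_clean_dataset

from conftest import make_dataset


def _loci_names(k):
    return [f"L{i:02d}" for i in range(k)]


def _wide_catalog(k):
    return LocusCatalog(
        LocusSpec(name, repeat_unit_length=4, allele_range=(3, 50))
        for name in _loci_names(k)
    )


def _profile(loci, base=10):
    return {l: [str(base + i), str(base + i + 1)] for i, l in enumerate(loci)}


class TestIdenticalGenotypes:
    def test_flagged_above_boundary_with_missing_loci(self):
        loci = _loci_names(21)
        g = _profile(loci)
        g2 = {l: (a if i < 16 else []) for i, (l, a) in enumerate(g.items())}
        ds = make_dataset([("A", g), ("B", g2)], loci)
        found = check_identical_genotypes(ds)
        assert len(found) == 1 and found[0].occurrences == 1

    def test_not_flagged_at_exactly_boundary(self):
        loci = _loci_names(21)
        g = _profile(loci)
        g2 = {l: (a if i < 15 else []) for i, (l, a) in enumerate(g.items())}
        ds = make_dataset([("A", g), ("B", g2)], loci)
        assert check_identical_genotypes(ds) == []

    def test_any_cotyped_disagreement_vetoes(self):
        loci = _loci_names(21)
        g = _profile(loci)
        g2 = dict(g)
        g2[loci[-1]] = ["40", "41"]  # 20 agreeing loci, one conflict
        ds = make_dataset([("A", g), ("B", g2)], loci)
        assert check_identical_genotypes(ds) == []

    def test_group_of_six_counts_five_occurrences(self):
        loci = _loci_names(16)
        g = _profile(loci)
        ds = make_dataset([(f"S{i}", g) for i in range(6)], loci)
        found = check_identical_genotypes(ds)
        assert len(found) == 1 and found[0].occurrences == 5

    def test_allele_order_does_not_mask_duplicates(self):
        # comparison is on unordered pairs
        loci = _loci_names(16)
        g = _profile(loci)
        swapped = {l: list(reversed(a)) for l, a in g.items()}
        ds = make_dataset([("A", g), ("B", swapped)], loci)
        assert len(check_identical_genotypes(ds)) == 1

    def test_cross_dataset_pool_match(self):
        loci = _loci_names(16)
        g = _profile(loci)
        ds = make_dataset([("A", g)], loci)
        ext = make_dataset([("Z", g)], loci, population_name="other")
        found = check_identical_genotypes(ds, pool=[ext])
        assert len(found) == 1 and found[0].scope == "dataset"

    def test_agrees_with_brute_force_oracle(self):
        from strqc.synthdata import ErrorInjectionPlan, Injection, inject_errors

        model = default_population_model(n_individuals=120, seed=42, n_loci=21)
        clean = generate_clean_dataset(model)
        plan = ErrorInjectionPlan(
            injections=[Injection("IDENTICAL_GENOTYPES", 2, {"group_size": 3})],
            seed=9,
        )
        ds, _ = inject_errors(clean, plan)
        found = check_identical_genotypes(ds)

        # oracle: direct all-pairs comparison + component grouping
        profiles = []
        for rec in ds.records:
            prof = {}
            for locus in ds.loci:
                a = rec.genotypes.get(locus, [])
                if len(a) == 2 and a != ["0", "0"]:
                    prof[locus] = tuple(sorted(a))
            profiles.append(prof)
        n = len(profiles)
        adj = {i: set() for i in range(n)}
        for i in range(n):
            for j in range(i + 1, n):
                shared = [
                    l for l in profiles[i]
                    if l in profiles[j] and profiles[i][l] == profiles[j][l]
                ]
                conflict = any(
                    l in profiles[j] and profiles[i][l] != profiles[j][l]
                    for l in profiles[i]
                )
                if len(shared) > 15 and not conflict:
                    adj[i].add(j)
                    adj[j].add(i)
        seen, components = set(), []
        for i in range(n):
            if i in seen or not adj[i]:
                continue
            stack, comp = [i], set()
            while stack:
                k = stack.pop()
                if k in comp:
                    continue
                comp.add(k)
                stack.extend(adj[k] - comp)
            seen |= comp
            components.append(comp)
        oracle_occurrences = sorted(len(c) - 1 for c in components)
        assert sorted(f.occurrences for f in found) == oracle_occurrences
        oracle_ids = {ds.records[i].sample_id for c in components for i in c}
        assert {s for f in found for s in f.sample_ids} == oracle_ids


class TestAlleleOrder:
    def test_descending_pair_flagged(self, toy_catalog):
        ds = make_dataset([("S1", {"TOYA": ["12", "6"]})], ["TOYA"])
        found = check_allele_order(ds, toy_catalog)
        assert [f.category for f in found] == [ErrorCategory.NON_ASCENDING]

    def test_ascending_and_homozygous_pass(self, toy_catalog):
        ds = make_dataset(
            [("S1", {"TOYA": ["6", "12"]}), ("S2", {"TOYA": ["8", "8"]})], ["TOYA"]
        )
        assert check_allele_order(ds, toy_catalog) == []

    def test_microvariant_base_length_ordering(self, toy_catalog):
        ds = make_dataset([("S1", {"TOYA": ["9.3", "9"]})], ["TOYA"])
        assert len(check_allele_order(ds, toy_catalog)) == 1
        ds = make_dataset([("S1", {"TOYA": ["9", "9.3"]})], ["TOYA"])
        assert check_allele_order(ds, toy_catalog) == []


class TestAlleleNomenclature:
    def test_invalid_designation_flagged(self, toy_catalog):
        ds = make_dataset([("S1", {"TOYA": ["9+", "10"]})], ["TOYA"])
        found = check_allele_nomenclature(ds, toy_catalog)
        assert len(found) == 1
        assert found[0].category is ErrorCategory.ALLELE_NOMENCLATURE

    def test_amelogenin_yy_flagged(self, toy_catalog):
        ds = make_dataset([("S1", {"AMEL": ["Y", "Y"]})], ["AMEL"])
        found = check_allele_nomenclature(ds, toy_catalog)
        assert len(found) == 1 and "Y|Y" in found[0].message

    def test_placeholder_accepted_only_with_flag(self, toy_catalog):
        ds = make_dataset([("S1", {"TOYA": ["8", "99"]})], ["TOYA"])
        assert len(check_allele_nomenclature(ds, toy_catalog)) == 1
        assert (
            check_allele_nomenclature(ds, toy_catalog, accept_rare_placeholders=True)
            == []
        )


class TestAllelePlausibility:
    def test_out_of_range_is_suspect(self):
        cat = LocusCatalog([LocusSpec("L", allele_range=(5, 25))])
        ds = make_dataset([("S1", {"L": ["12", "44"]})], ["L"])
        found = check_allele_plausibility(ds, cat)
        assert len(found) == 1 and not found[0].confirmed

    def test_in_range_and_observed_passes(self):
        cat = LocusCatalog(
            [LocusSpec("L", allele_range=(5, 25),
                       observed_alleles=frozenset({"11", "12"}))]
        )
        ds = make_dataset([("S1", {"L": ["11", "12"]})], ["L"])
        assert check_allele_plausibility(ds, cat) == []

    def test_unobserved_allele_is_suspect(self):
        cat = LocusCatalog(
            [LocusSpec("L", allele_range=(5, 25),
                       observed_alleles=frozenset({"11", "12"}))]
        )
        ds = make_dataset([("S1", {"L": ["11", "13"]})], ["L"])
        assert len(check_allele_plausibility(ds, cat)) == 1

    def test_adjudication_confirms_or_clears(self):
        cat = LocusCatalog([LocusSpec("L", allele_range=(5, 25))])
        ds = make_dataset(
            [("S1", {"L": ["12", "44"]}), ("S2", {"L": ["12", "44"]})], ["L"]
        )
        found = check_allele_plausibility(ds, cat)
        apply_adjudications(
            found,
            [("S1", "L", "confirmed_error"), ("S2", "L", "verified_correct")],
        )
        by_sample = {f.sample_ids[0]: f for f in found}
        assert by_sample["S1"].confirmed and by_sample["S1"].resolved
        assert not by_sample["S2"].confirmed and by_sample["S2"].resolved


class TestCompleteness:
    def test_zero_zero_and_blank_flagged(self, toy_catalog):
        ds = make_dataset(
            [("S1", {"TOYA": ["0", "0"]}), ("S2", {"TOYA": []}),
             ("S3", {"TOYA": ["7", "8"]})],
            ["TOYA"],
        )
        found = check_completeness(ds, toy_catalog)
        assert len(found) == 2
        assert {f.sample_ids[0] for f in found} == {"S1", "S2"}


class TestLocusNames:
    def test_unknown_name_with_suggestion(self, catalog):
        ds = make_dataset([("S1", {"TH02": ["6", "7"]})], ["TH02"])
        found = check_locus_names(ds, catalog)
        assert len(found) == 1
        assert "TH01" in found[0].extra["suggestions"]

    def test_alias_variant_passes(self, catalog):
        ds = make_dataset([("S1", {"Penta D": ["9", "10"]})], ["Penta D"])
        assert check_locus_names(ds, catalog) == []

    def test_missing_header_row_is_dataset_scope(self, catalog):
        # a shifted table: the "locus names" are actually genotypes
        ds = make_dataset(
            [("S1", {"14|15": ["14", "15"], "9|9.3": ["9", "9.3"]})],
            ["14|15", "9|9.3"],
        )
        found = check_locus_names(ds, catalog)
        assert len(found) == 1 and found[0].scope == "dataset"


class TestPloidy:
    def test_single_and_triallelic_cells(self, toy_catalog):
        ds = make_dataset(
            [("S1", {"TOYA": ["7"]}), ("S2", {"TOYA": ["7", "8", "9"]}),
             ("S3", {"TOYA": ["7", "8"]})],
            ["TOYA"],
        )
        found = check_ploidy(ds)
        assert len(found) == 2
        tri = next(f for f in found if f.sample_ids == ["S2"])
        assert tri.extra.get("exclude_from_frequencies")
        single = next(f for f in found if f.sample_ids == ["S1"])
        assert not single.extra.get("exclude_from_frequencies")

    def test_consistently_haploid_locus_escalates(self):
        ds = make_dataset(
            [(f"S{i}", {"L": ["7"]}) for i in range(5)], ["L"]
        )
        found = check_ploidy(ds)
        assert len(found) == 1 and found[0].scope == "locus"


class TestKillers:
    def test_attestations(self):
        ds = make_dataset(
            [("S1", {"L": ["7", "8"]})], ["L"], raw_data_available=False
        )
        found = check_killers(ds)
        assert len(found) == 1 and found[0].category is ErrorCategory.QC_KILLER
        ds2 = make_dataset(
            [("S1", {"L": ["7", "8"]})], ["L"], genotypes_unshuffled=False
        )
        assert len(check_killers(ds2)) == 1

    def test_raw_concordance_audit(self):
        ds = make_dataset([("S1", {"vWA": ["14", "16"]})], ["vWA"])
        raw = make_dataset([("S1", {"vWA": ["15", "16"]})], ["vWA"])
        found = check_raw_concordance(ds, raw)
        assert len(found) == 1 and "vWA" in found[0].extra["discordant_loci"]
        assert check_raw_concordance(ds, None) == []

    def test_concordant_raw_reference_is_silent(self):
        ds = make_dataset([("S1", {"vWA": ["14", "16"]})], ["vWA"])
        raw = make_dataset([("S1", {"vWA": ["16", "14"]})], ["vWA"])
        assert check_raw_concordance(ds, raw) == []


class TestIdentifiers:
    def test_same_id_different_genotypes(self):
        ds = make_dataset(
            [("S7", {"L": ["7", "8"]}), ("S7", {"L": ["9", "10"]})], ["L"]
        )
        found = check_identifiers(ds)
        assert len(found) == 1
        assert found[0].category is ErrorCategory.DUPLICATE_IDENTIFIER

    def test_same_id_identical_genotypes_routed_to_duplicates(self):
        ds = make_dataset(
            [("S7", {"L": ["7", "8"]}), ("S7", {"L": ["8", "7"]})], ["L"]
        )
        assert check_identifiers(ds) == []

    def test_unique_ids_silent(self):
        ds = make_dataset(
            [("A", {"L": ["7", "8"]}), ("B", {"L": ["7", "8"]})], ["L"]
        )
        assert check_identifiers(ds) == []


class TestMetadataMatch:
    def test_sample_size_deviation(self):
        ds = make_dataset(
            [("S1", {"L": ["7", "8"]}), ("S2", {"L": ["7", "8"]})],
            ["L"], declared_n=500,
        )
        found = check_metadata_match(ds)
        assert len(found) == 1 and "500" in found[0].message

    def test_declared_locus_missing(self, catalog):
        ds = make_dataset([("S1", {"vWA": ["14", "16"]})], ["vWA"])
        ds.metadata.declared_loci = ["vWA", "SE33"]
        found = check_metadata_match(ds, catalog)
        assert len(found) == 1 and "SE33" in found[0].message

    def test_whitelisted_missing_locus_ignored(self, catalog):
        ds = make_dataset([("S1", {"vWA": ["14", "16"]})], ["vWA"])
        ds.metadata.declared_loci = ["vWA", "SE33"]
        assert (
            check_metadata_match(ds, catalog, missing_locus_whitelist=["SE33"]) == []
        )

    def test_exact_match_silent(self, catalog):
        ds = make_dataset([("S1", {"vWA": ["14", "16"]})], ["vWA"])
        assert check_metadata_match(ds, catalog) == []


class TestLocusSwap:
    @staticmethod
    def _swap_fixture(toy_catalog, swapped, n=100):
        import numpy as np

        rng = np.random.default_rng(0)
        rows = []
        for i in range(n):
            a = sorted(rng.integers(6, 12, size=2))
            b = sorted(rng.integers(17, 26, size=2))
            ga, gb = ([str(x) for x in b], [str(x) for x in a]) if swapped else (
                [str(x) for x in a], [str(x) for x in b]
            )
            rows.append((f"S{i}", {"TOYA": ga, "TOYB": gb}))
        return make_dataset(rows, ["TOYA", "TOYB"])

    def test_transposed_columns_detected(self, toy_catalog):
        ds = self._swap_fixture(toy_catalog, swapped=True)
        found = check_locus_swap(ds, toy_catalog)
        assert len(found) == 1
        assert set(found[0].extra["loci"]) == {"TOYA", "TOYB"}

    def test_untouched_fixture_silent(self, toy_catalog):
        ds = self._swap_fixture(toy_catalog, swapped=False)
        assert check_locus_swap(ds, toy_catalog) == []

    def test_below_min_samples_silent(self, toy_catalog):
        ds = self._swap_fixture(toy_catalog, swapped=True, n=10)
        assert check_locus_swap(ds, toy_catalog) == []


class TestLostIntermediates:
    @staticmethod
    def _catalog():
        return LocusCatalog(
            [
                LocusSpec(
                    "T", repeat_unit_length=4, allele_range=(3, 14),
                    expected_intermediates=(("9.3", 0.30),),
                ),
                LocusSpec("P", repeat_unit_length=4, allele_range=(3, 20)),
            ]
        )

    def test_rounded_microvariants_flagged(self):
        cat = self._catalog()
        rows = [(f"S{i}", {"T": ["9", "9"], "P": ["9", "9.3"]}) for i in range(150)]
        ds = make_dataset(rows, ["T", "P"])
        found = check_lost_intermediates(ds, cat)
        assert len(found) == 1
        assert found[0].locus == "T" and not found[0].confirmed

    def test_intermediates_present_silent(self):
        cat = self._catalog()
        rows = [(f"S{i}", {"T": ["9", "9.3"]}) for i in range(150)]
        ds = make_dataset(rows, ["T"])
        assert check_lost_intermediates(ds, cat) == []

    def test_small_sample_not_flagged(self):
        cat = self._catalog()
        rows = [(f"S{i}", {"T": ["9", "9"]}) for i in range(50)]
        ds = make_dataset(rows, ["T"])
        assert check_lost_intermediates(ds, cat) == []


def test_detectors_are_pure(toy_catalog):
    """Running a detector twice on the same input yields identical findings."""
    ds = make_dataset(
        [("S1", {"TOYA": ["12", "6"], "TOYB": ["18", "9+"]}),
         ("S1", {"TOYA": ["6", "7"], "TOYB": ["18", "19"]})],
        ["TOYA", "TOYB"],
    )
    for check in (
        lambda d: check_allele_order(d, toy_catalog),
        lambda d: check_allele_nomenclature(d, toy_catalog),
        lambda d: check_ploidy(d),
        lambda d: check_identifiers(d),
    ):
        assert check(ds) == check(ds)
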