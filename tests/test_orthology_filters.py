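"""Decontamination and occupancy filters: contracts, oracles, invariants."""

import numpy as np
import pytest

import klebkit as kk
from klebkit.io_formats import HitTable, KEEP_CATEGORY
from klebkit.orthology_filters import FilterError, Orthogroup, TaxonomyMap


def hit_table(records, categories):
    return HitTable.from_records(records, categories, max_hits=10)


CATS = {
    "nuc": KEEP_CATEGORY,
    "bac": "bacteria",
    "pla": "plastid",
    "fun": "fungi",
}


class TestBestHitDecontaminate:
    def test_contaminant_top_hit_removed_and_routed(self):
        hits = hit_table([("s1", "bac", 120.0, 1e-12), ("s1", "nuc", 90.0, 1e-9)], CATS)
        res = kk.best_hit_decontaminate({"s1": "MKV"}, hits)
        assert res.kept == {}
        assert res.removed["bacteria"] == {"s1": "MKV"}

    def test_nuclear_best_hit_kept(self):
        hits = hit_table([("s1", "nuc", 120.0, 1e-12), ("s1", "bac", 90.0, 1e-9)], CATS)
        res = kk.best_hit_decontaminate({"s1": "MKV"}, hits)
        assert res.kept == {"s1": "MKV"}

    def test_top_bitscore_tie_with_contaminant_removed(self):
        hits = hit_table([("s1", "nuc", 100.0, 1e-12), ("s1", "pla", 100.0, 1e-12)], CATS)
        res = kk.best_hit_decontaminate({"s1": "MKV"}, hits)
        assert res.kept == {}
        assert "s1" in res.removed["plastid"]

    def test_no_hit_follows_flag(self):
        hits = hit_table([("s1", "nuc", 100.0, 1e-12)], CATS)
        seqs = {"s1": "MKV", "orphan": "AAA"}
        res = kk.best_hit_decontaminate(seqs, hits, keep_no_hit=True)
        assert "orphan" in res.kept
        res = kk.best_hit_decontaminate(seqs, hits, keep_no_hit=False)
        assert "orphan" in res.removed["no_hit"]

    def test_hit_for_unknown_sequence_is_error(self):
        hits = hit_table([("ghost", "nuc", 100.0, 1e-12)], CATS)
        with pytest.raises(FilterError, match="ghost"):
            kk.best_hit_decontaminate({"s1": "MKV"}, hits)

    def test_report_partitions_input(self):
        hits = hit_table(
            [("s1", "nuc", 100.0, 1e-9), ("s2", "bac", 100.0, 1e-9)], CATS
        )
        res = kk.best_hit_decontaminate({"s1": "A", "s2": "C", "s3": "D"}, hits)
        r = res.report
        assert r.n_kept + r.n_removed == r.n_input == 3

    def test_noise_free_synthetic_assembly_recovered_exactly(self):
        seqs, hits, truth = kk.sim_contaminated_assembly(
            400, seed=77, fractions={"bacteria": 0.1, "fungi": 0.1}, noise_sd=0.0
        )
        res = kk.best_hit_decontaminate(seqs, hits)
        errors = 0
        for sid, cat in truth.categories.items():
            if cat == KEEP_CATEGORY:
                errors += sid not in res.kept
            else:
                errors += sid not in res.removed.get(cat, {})
        assert errors == 0


def random_orthogroups(rng, n, taxa):
    out = []
    for i in range(n):
        size = int(rng.integers(1, 12))
        members = tuple(
            (taxa[int(rng.integers(len(taxa)))], f"og{i}_s{j}") for j in range(size)
        )
        out.append(Orthogroup(id=f"og{i}", members=members))
    return out


class TestOccupancyFilters:
    taxonomy = TaxonomyMap(
        groups={f"tax{i}": f"grp{i % 5}" for i in range(15)}
    )

    def test_insufficient_group_coverage_removed(self):
        og = Orthogroup(id="x", members=(("tax0", "a"), ("tax1", "b")))
        kept, _ = kk.filter_by_group_occupancy([og], self.taxonomy, min_groups=3)
        assert kept == []
        kept, _ = kk.filter_by_group_occupancy([og], self.taxonomy, min_groups=2)
        assert kept == [og]

    def test_min_groups_zero_keeps_all(self, rng):
        ogs = random_orthogroups(rng, 20, [f"tax{i}" for i in range(15)])
        kept, _ = kk.filter_by_group_occupancy(ogs, self.taxonomy, min_groups=0)
        assert kept == ogs

    def test_unmapped_taxon_named_in_error(self):
        og = Orthogroup(id="x", members=(("martian", "a"),))
        with pytest.raises(FilterError, match="martian"):
            kk.filter_by_group_occupancy([og], self.taxonomy, min_groups=1)

    def test_agrees_with_bruteforce_and_is_monotone_idempotent(self, rng):
        taxa = [f"tax{i}" for i in range(15)]
        ogs = random_orthogroups(rng, 100, taxa)
        for min_groups in range(0, 6):
            kept, report = kk.filter_by_group_occupancy(
                ogs, self.taxonomy, min_groups
            )
            brute = [
                og
                for og in ogs
                if len({self.taxonomy.groups[t] for t, _ in og.members}) >= min_groups
            ]
            assert kept == brute
            assert report.n_kept == len(brute)
            # idempotent
            again, _ = kk.filter_by_group_occupancy(kept, self.taxonomy, min_groups)
            assert again == kept
        # monotone in min_groups
        previous = None
        for min_groups in range(0, 6):
            kept, _ = kk.filter_by_group_occupancy(ogs, self.taxonomy, min_groups)
            ids = {og.id for og in kept}
            if previous is not None:
                assert ids <= previous
            previous = ids

    def test_taxon_count_filter_counts_distinct_taxa(self, rng):
        og = Orthogroup(
            id="x", members=tuple((f"tax{i % 20}", f"s{i}") for i in range(40))
        )
        kept, _ = kk.filter_by_taxon_count([og], min_taxa=21)
        assert kept == []
        kept, _ = kk.filter_by_taxon_count([og], min_taxa=20)
        assert kept == [og]
        empty = Orthogroup(id="e", members=())
        kept, _ = kk.filter_by_taxon_count([empty], min_taxa=1)
        assert kept == []

    def test_pruned_group_filter_semantics(self):
        tax = TaxonomyMap(
            groups={
                "Chlamy": "chlorophytes",
                "Chara": "non_kleb_streptophytes",
                "Knitens": "klebsormidium",
                "Entransia": "other_klebsormidiophyceae",
            }
        )
        og = Orthogroup(id="x", members=(("Knitens", "a"), ("Entransia", "b")))
        kept, _ = kk.filter_pruned_by_groups([og], tax, min_groups=2)
        assert kept == [og]
        full = Orthogroup(
            id="y",
            members=(("Chlamy", "a"), ("Chara", "b"), ("Knitens", "c"), ("Entransia", "d")),
        )
        kept, _ = kk.filter_pruned_by_groups([full], tax, min_groups=4)
        assert kept == [full]


class TestCombineLocusSets:
    def aln(self, seq):
        return kk.Alignment(rows={"A": seq})

    def test_disjoint_sets_union(self):
        a = {f"a{i}": self.aln("MK") for i in range(420)}
        b = {f"b{i}": self.aln("MK") for i in range(425)}
        assert len(kk.combine_locus_sets(a, b)) == 845

    def test_identical_duplicate_merged_silently(self):
        a = {"x": self.aln("MK")}
        b = {"x": self.aln("MK")}
        assert len(kk.combine_locus_sets(a, b)) == 1

    def test_differing_collision_errors_or_renames(self):
        a = {"x": self.aln("MK")}
        b = {"x": self.aln("VA")}
        with pytest.raises(FilterError, match="x"):
            kk.combine_locus_sets(a, b)
        combined = kk.combine_locus_sets(a, b, on_collision="rename")
        assert set(combined) == {"x", "x__b"}


class TestRenameForPruner:
    def test_format_and_exact_reversal(self):
        aln = kk.Alignment(rows={"Kniten_g1234": "MKV"}, aligned=False)
        taxon_map = {"Kniten": "Klebsormidium_nitens"}
        renamed, _, mapping = kk.rename_for_pruner({"og1": aln}, taxon_map)
        assert list(renamed["og1"].rows) == ["Klebsormidium_nitens@g1234"]
        restored = {mapping[l]: s for l, s in renamed["og1"].rows.items()}
        assert restored == aln.rows

    def test_delimiter_inside_taxon_rejected(self):
        aln = kk.Alignment(rows={"Bad_g1": "MK"}, aligned=False)
        with pytest.raises(FilterError, match="delimiter"):
            kk.rename_for_pruner({"og1": aln}, {"Bad": "Evil@taxon"})


def test_bundled_taxonomies_load_with_expected_group_counts():
    assert kk.load_bundled_taxonomy("groups14").n_groups == 14
    assert kk.load_bundled_taxonomy("groups4").n_groups == 4
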