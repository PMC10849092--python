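"""Trimming and concatenation: thresholds, round trips, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import klebkit as kk
from klebkit.io_formats import Alignment, FormatError
from klebkit.matrix_builder import occupancy_report, slice_locus, trim_gappy_columns


def random_alignment(rng, n_rows=10, n_cols=30, gap_p=0.3, name="x"):
    chars = np.array(list("ACDEFGHIKLMNPQRSTVWYX-?"))
    weights = np.full(23, (1 - gap_p) / 21)
    weights[-2:] = gap_p / 2
    arr = rng.choice(chars, size=(n_rows, n_cols), p=weights)
    return Alignment(
        rows={f"t{i:02d}": "".join(row) for i, row in enumerate(arr)}, name=name
    )


class TestTrim:
    def test_tie_at_threshold_retained(self):
        # column 0: 3 of 4 gaps = 0.75 exactly -> kept at threshold 0.75
        aln = Alignment(rows={"a": "-K", "b": "-K", "c": "-K", "d": "MK"})
        res = trim_gappy_columns(aln, 0.75)
        assert res.n_removed == 0
        res = trim_gappy_columns(aln, 0.74)
        assert res.n_removed == 1
        assert res.alignment.rows["a"] == "K"

    def test_x_counts_as_residue_not_gap(self):
        aln = Alignment(rows={"a": "X", "b": "X", "c": "-", "d": "?"})
        assert trim_gappy_columns(aln, 0.5).n_removed == 0  # gap fraction = 0.5
        assert trim_gappy_columns(aln, 0.49).n_removed == 1

    def test_gap_free_alignment_unchanged(self, rng):
        aln = random_alignment(rng, gap_p=0.0)
        res = trim_gappy_columns(aln, 0.75)
        assert res.n_removed == 0 and res.alignment.rows == aln.rows

    def test_matches_bruteforce_column_scan(self, rng):
        for _ in range(50):
            aln = random_alignment(rng, gap_p=float(rng.uniform(0.2, 0.9)))
            threshold = float(rng.uniform(0.0, 1.0))
            res = trim_gappy_columns(aln, threshold)
            arr = aln.to_char_array()
            expected_keep = [
                j
                for j in range(arr.shape[1])
                if np.isin(arr[:, j], ["-", "?"]).mean() <= threshold
            ]
            assert res.kept_columns.tolist() == expected_keep
            assert res.n_removed == arr.shape[1] - len(expected_keep)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        threshold=st.floats(0.0, 1.0),
        tighter=st.floats(0.0, 1.0),
        seed=st.integers(0, 1000),
    )
    def test_idempotent_and_monotone(self, threshold, tighter, seed):
        aln = random_alignment(np.random.default_rng(seed), gap_p=0.5)
        once = trim_gappy_columns(aln, threshold).alignment
        twice = trim_gappy_columns(once, threshold).alignment
        assert twice.rows == once.rows
        # trimming at a looser threshold after a tighter one changes nothing
        if tighter <= threshold:
            tight_first = trim_gappy_columns(aln, tighter).alignment
            then_loose = trim_gappy_columns(tight_first, threshold).alignment
            assert then_loose.rows == tight_first.rows
        # post-condition: no surviving column exceeds the threshold
        if once.rows and once.length:
            arr = once.to_char_array()
            assert np.isin(arr, ["-", "?"]).mean(axis=0).max() <= threshold

    def test_unaligned_input_rejected(self):
        aln = Alignment(rows={"a": "MK", "b": "MKV"}, aligned=False)
        with pytest.raises(FormatError):
            trim_gappy_columns(aln, 0.5)


class TestConcatenate:
    def test_single_locus_identity(self):
        locus = Alignment(rows={"A": "MKVLA", "B": "MRVLA"}, name="g1")
        sm = kk.concatenate_loci({"g1": locus})
        assert sm.alignment.rows == locus.rows
        assert sm.partitions.parts == (("g1", 1, 5),)

    def test_disjoint_taxa_gap_filled(self):
        loci = {
            "g1": Alignment(rows={"A": "MKVLA", "B": "MRVLA"}),
            "g2": Alignment(rows={"C": "WWYYFFH"}),
        }
        sm = kk.concatenate_loci(loci)
        assert sm.length == 12 and sm.alignment.n_rows == 3
        assert sm.alignment.rows["A"] == "MKVLA" + "-" * 7
        assert sm.alignment.rows["C"] == "-" * 5 + "WWYYFFH"
        assert list(sm.alignment.rows) == sorted(sm.alignment.rows)

    def test_concat_then_slice_is_identity(self, rng):
        tree = kk.sim_tree(8, seed=12, depth=0.5)
        loci, _ = kk.sim_loci(
            tree, 20, seed=13, length_range=(20, 80), occupancy=0.7, gap_rate=0.2
        )
        sm = kk.concatenate_loci(loci)
        assert sm.length == sum(a.length for a in loci.values())
        for name, original in loci.items():
            assert slice_locus(sm, name).rows == original.rows

    def test_duplicate_taxon_within_locus_rejected(self):
        with pytest.raises(FormatError):
            Alignment.from_pairs([("A", "MK"), ("A", "VA")])

    def test_taxon_outside_universe_rejected(self):
        locus = Alignment(rows={"A": "MK", "Z": "VA"})
        with pytest.raises(FormatError, match="Z"):
            kk.concatenate_loci({"g1": locus}, taxon_universe=["A", "B"])


class TestOccupancy:
    def test_full_matrix_is_fully_occupied(self):
        sm = kk.concatenate_loci({"g1": Alignment(rows={"A": "MK", "B": "VA"})})
        rep = occupancy_report(sm)
        assert rep.overall == 1.0
        assert (rep.per_taxon == 1.0).all() and (rep.per_locus == 1.0).all()

    def test_taxon_absent_from_half_the_loci(self):
        loci = {
            "g1": Alignment(rows={"A": "MKVL", "B": "MKVL"}),
            "g2": Alignment(rows={"B": "WYFH"}),
        }
        rep = occupancy_report(kk.concatenate_loci(loci))
        assert rep.per_taxon["A"] == 0.5
        assert rep.per_taxon["B"] == 1.0

    def test_matches_direct_count_on_random_matrices(self, rng):
        tree = kk.sim_tree(10, seed=3, depth=0.5)
        loci, _ = kk.sim_loci(
            tree, 15, seed=5, length_range=(10, 40), occupancy=0.6, gap_rate=0.3
        )
        sm = kk.concatenate_loci(loci)
        rep = occupancy_report(sm)
        arr = sm.alignment.to_char_array()
        nongap = ~np.isin(arr, ["-", "?"])
        assert rep.overall == pytest.approx(nongap.mean())
        for i, taxon in enumerate(sm.taxa):
            assert rep.per_taxon[taxon] == pytest.approx(nongap[i].mean())
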