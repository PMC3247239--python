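import random

import dendropy
import numpy as np
import pytest

from promoscan.phylo import (PromoterAlignment, alignment_coordinate_maps,
                             cross_species_presence, filter_conserved_sites,
                             ortholog_region_merge, read_promoter_alignments,
                             subtree_branch_length, tree_length)
from promoscan.simulate import DEFAULT_TREE


class TestCoordinateMaps:
    def test_gap_skip(self):
        aln = PromoterAlignment("p", {"m": "AC-GT", "h": "ACCGT"}, "m")
        maps = alignment_coordinate_maps(aln)
        assert maps["m"]["col_of_pos"][2] == 3  # the G
        assert maps["m"]["pos_of_col"][2] == -1  # gap column
        assert maps["h"]["col_of_pos"].tolist() == [0, 1, 2, 3, 4]

    def test_gapless_row_is_identity(self):
        aln = PromoterAlignment("p", {"m": "ACGTACGT"}, "m")
        m = alignment_coordinate_maps(aln)["m"]
        assert m["col_of_pos"].tolist() == list(range(8))
        assert m["pos_of_col"].tolist() == list(range(8))

    def test_round_trip_on_random_gapped_rows(self):
        rng = random.Random(13)
        for _ in range(20):
            n = rng.randrange(5, 40)
            row = "".join(rng.choice("ACGT-") for _ in range(n))
            if row.replace("-", "") == "":
                continue
            aln = PromoterAlignment("p", {"m": row}, "m")
            m = alignment_coordinate_maps(aln)["m"]
            for pos, col in enumerate(m["col_of_pos"]):
                assert m["pos_of_col"][col] == pos

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            PromoterAlignment("p", {"m": "ACGT", "h": "ACG"}, "m")

    def test_maf_reader_round_trip(self, tmp_path):
        maf = tmp_path / "aln.maf"
        maf.write_text(
            "##maf version=1\n"
            "a score=0\n"
            "s mouse.p1 0 4 + 4 ACGT\n"
            "s human.p1 0 3 + 3 AC-T\n"
            "\n")
        alns = read_promoter_alignments(maf)
        assert len(alns) == 1
        assert alns[0].promoter_id == "p1"
        assert alns[0].reference == "mouse"
        assert alns[0].rows["human"] == "AC-T"


class TestCrossSpeciesPresence:
    def _maps(self):
        aln = PromoterAlignment("p", {"mouse": "A" * 100, "human": "A" * 100,
                                      "rat": "A" * 100}, "mouse")
        return alignment_coordinate_maps(aln)

    def test_exact_overlap_supported_at_zero_slide(self):
        maps = self._maps()
        sup = cross_species_presence([(10, 31)], {"human": [(10, 31)]}, maps,
                                     slide_w=0, reference="mouse")
        assert sup == [{"mouse", "human"}]

    def test_displacement_needs_slide(self):
        maps = self._maps()
        for slide, expected in [(50, {"mouse", "human"}), (0, {"mouse"})]:
            sup = cross_species_presence([(10, 31)], {"human": [(61, 82)]}, maps,
                                         slide_w=slide, reference="mouse")
            assert sup == [expected]  # displaced 30 columns

    def test_absent_species_contributes_no_support(self):
        maps = self._maps()
        sup = cross_species_presence([(10, 31)], {"dog": [(10, 31)]}, maps,
                                     slide_w=50, reference="mouse")
        assert sup == [{"mouse"}]

    def test_matches_pairwise_distance_oracle(self):
        rng = random.Random(3)
        maps = self._maps()
        for _ in range(30):
            ref = [(s := rng.randrange(0, 80), s + rng.randrange(3, 20))]
            others = {"human": [(s2 := rng.randrange(0, 80),
                                 s2 + rng.randrange(3, 20))
                                for _ in range(rng.randrange(0, 3))]}
            w = rng.choice([0, 10, 50])
            sup = cross_species_presence(ref, others, maps, w, "mouse")[0]
            rs, re = ref[0]
            expect = {"mouse"}
            for os_, oe in others["human"]:
                sep = max(os_ - re, rs - oe)
                if (sep < 0) if w == 0 else (sep <= w):
                    expect.add("human")
            assert sup == expect

    def test_support_grows_with_slide(self):
        rng = random.Random(5)
        maps = self._maps()
        ref = [(20, 41)]
        others = {"human": [(rng.randrange(0, 80), rng.randrange(81, 100))],
                  "rat": [(0, 10)]}
        prev = None
        for w in (0, 10, 50):
            sup = cross_species_presence(ref, others, maps, w, "mouse")[0]
            if prev is not None:
                assert prev <= sup
            prev = sup


class TestSubtreeLength:
    def test_two_leaf_tree_sums_pendant_branches(self):
        assert subtree_branch_length("(a:0.10,b:0.05);", {"a", "b"}) == \
            pytest.approx(0.15)

    def test_singleton_is_zero(self):
        assert subtree_branch_length(DEFAULT_TREE, {"mouse"}) == 0.0

    def test_reference_scale_worked_values(self):
        # the bundled synthetic tree reproduces the rodent/primate scale
        assert subtree_branch_length(DEFAULT_TREE, {"mouse", "rat"}) == \
            pytest.approx(0.161)
        assert subtree_branch_length(DEFAULT_TREE, {"mouse", "human"}) == \
            pytest.approx(0.453)
        assert subtree_branch_length(DEFAULT_TREE, {"mouse", "rat", "human"}) == \
            pytest.approx(0.537)

    def test_unknown_species_named_in_error(self):
        with pytest.raises(KeyError, match="unicorn"):
            subtree_branch_length(DEFAULT_TREE, {"mouse", "unicorn"})

    def test_pair_lengths_match_patristic_distance_oracle(self):
        rng = random.Random(7)
        for rep in range(5):
            t = _random_tree(rng, n_leaves=rng.randrange(4, 21))
            pdm = t.phylogenetic_distance_matrix()
            taxa = list(t.taxon_namespace)
            for _ in range(10):
                a, b = rng.sample(taxa, 2)
                mine = subtree_branch_length(t, {a.label, b.label})
                assert mine == pytest.approx(pdm.patristic_distance(a, b))

    def test_monotone_under_subset_inclusion(self):
        rng = random.Random(11)
        t = _random_tree(rng, n_leaves=12)
        labels = [tx.label for tx in t.taxon_namespace]
        subset = set(rng.sample(labels, 3))
        prev = subtree_branch_length(t, subset)
        for extra in labels:
            if extra in subset:
                continue
            subset.add(extra)
            cur = subtree_branch_length(t, subset)
            assert cur >= prev - 1e-12
            prev = cur

    def test_total_tree_length_bounds_any_subtree(self):
        rng = random.Random(19)
        t = _random_tree(rng, n_leaves=10)
        labels = [tx.label for tx in t.taxon_namespace]
        full = tree_length(t)
        assert subtree_branch_length(t, set(labels)) <= full + 1e-12


class TestFilterConservedSites:
    def test_reference_only_support_dropped(self):
        sites = [(("p1", 0, 21), {"mouse"})]
        kept, counts, frac = filter_conserved_sites(sites, DEFAULT_TREE, 0.17)
        assert kept == [] and counts == {"p1": 0} and frac == 0.0

    def test_hand_filtered_three_species_set(self):
        sites = [(("p1", 0, 21), {"mouse", "rat"}),           # 0.161 < 0.17
                 (("p1", 50, 71), {"mouse", "human"}),        # 0.453 >= 0.17
                 (("p2", 10, 31), {"mouse", "rat", "human"}),  # 0.537
                 (("p3", 10, 31), {"mouse"})]
        kept, counts, frac = filter_conserved_sites(sites, DEFAULT_TREE, 0.17)
        assert [s[0] for s in kept] == ["p1", "p2"]
        assert counts == {"p1": 1, "p2": 1, "p3": 0}
        assert frac == pytest.approx(2 / 3)

    def test_counts_monotone_in_threshold(self):
        rng = random.Random(2)
        species = ["mouse", "rat", "human", "dog"]
        sites = [((f"p{i}", 0, 21),
                  {"mouse"} | set(rng.sample(species[1:], rng.randrange(0, 4))))
                 for i in range(30)]
        prev = None
        for thr in (0.17, 0.5, 1.5):
            kept, _, _ = filter_conserved_sites(sites, DEFAULT_TREE, thr)
            if prev is not None:
                assert len(kept) <= prev
            prev = len(kept)


class TestOrthologRegionMerge:
    def test_offset_plus_regions_keep_left_window(self):
        regions = [("chr1", 0, 4000, "+"), ("chr1", 1000, 5000, "+")]
        assert ortholog_region_merge(regions) == [("chr1", 0, 4000, "+")]

    def test_minus_strand_keeps_right_window(self):
        regions = [("chr1", 0, 4000, "-"), ("chr1", 1000, 5000, "-")]
        assert ortholog_region_merge(regions) == [("chr1", 1000, 5000, "-")]

    def test_disjoint_regions_unchanged(self):
        regions = [("chr1", 0, 4000, "+"), ("chr1", 9000, 13000, "+"),
                   ("chr2", 0, 4000, "+")]
        assert ortholog_region_merge(regions) == sorted(regions)

    def test_strands_do_not_merge_with_each_other(self):
        regions = [("chr1", 0, 4000, "+"), ("chr1", 1000, 5000, "-")]
        assert len(ortholog_region_merge(regions)) == 2

    def test_matches_sweep_line_oracle(self):
        rng = random.Random(17)
        width = 4000
        for _ in range(20):
            regions = [("chr1", s := rng.randrange(0, 50_000) , s + width, "+")
                       for _ in range(rng.randrange(1, 12))]
            got = ortholog_region_merge(regions)
            # oracle: union the intervals, then take the leftmost window
            ivs = sorted((s, e) for _, s, e, _ in regions)
            runs, cur = [], list(ivs[0])
            for s, e in ivs[1:]:
                if s < cur[1]:
                    cur[1] = max(cur[1], e)
                else:
                    runs.append(cur)
                    cur = [s, e]
            runs.append(cur)
            expected = [("chr1", s, s + width, "+") for s, _ in runs]
            assert got == expected

    def test_malformed_bed_reports_line(self, tmp_path):
        bad = tmp_path / "r.bed"
        bad.write_text("chr1\t0\t4000\tx\t0\t+\nchr1\toops\n")
        with pytest.raises(ValueError, match="line 2"):
            ortholog_region_merge(str(bad))


def _random_tree(rng, n_leaves):
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_leaves)])
    t = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_leaves, taxon_namespace=taxa,
        rng=random.Random(rng.randrange(10**6)))
    for e in t.preorder_edge_iter():
        if e.length is None:
            e.length = 0.0
    return t
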