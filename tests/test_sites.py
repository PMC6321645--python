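"""SNP calling thresholds, genome anchoring and non-redundant merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wheatbsa.sites import AnchorResult, anchor_sites, call_snps, merge_nonredundant, site_keys


def counts(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "transcript_id", "transcript_pos",
                 "ref_base", "alt_base", "depth", "alt_depth"],
    )


class TestCallSnps:
    @pytest.mark.parametrize(
        "depth,alt,called",
        [
            (10, 1, True),    # both boundaries inclusive: 1/10 = 0.1 at depth 10
            (10, 0, False),   # fraction below 0.1
            (9, 9, False),    # depth below the floor even at fraction 1
            (0, 0, False),    # zero depth never called
            (1000, 100, True),
            (1000, 99, False),
        ],
    )
    def test_threshold_boundaries(self, depth, alt, called):
        table = counts([(".", 0, "tx", 50, "A", "G", depth, alt)])
        assert (len(call_snps(table)) == 1) is called

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            call_snps(counts([(".", 0, "tx", 50, "A", "G", 10, -1)]))
        with pytest.raises(ValueError):
            call_snps(counts([(".", 0, "tx", 50, "A", "G", 5, 6)]))

    @given(
        st.lists(
            st.tuples(st.integers(0, 60), st.integers(0, 60)).map(
                lambda t: (max(t), min(t))
            ),
            max_size=30,
        ),
        st.integers(5, 20),
        st.floats(0.05, 0.5),
    )
    def test_monotone_in_thresholds(self, pairs, min_depth, min_frac):
        table = counts(
            [(".", 0, f"tx{i}", 50, "A", "G", d, k) for i, (d, k) in enumerate(pairs)]
        )
        loose = set(call_snps(table, min_frac, min_depth)["transcript_id"])
        tighter_depth = set(call_snps(table, min_frac, min_depth + 5)["transcript_id"])
        tighter_frac = set(call_snps(table, min(min_frac + 0.1, 1.0), min_depth)["transcript_id"])
        assert tighter_depth <= loose
        assert tighter_frac <= loose


ANCHORS = pd.DataFrame(
    {
        "transcript_id": ["t1", "t1", "t2", "t3"],
        "transcript_pos": [100, 150, 60, 60],
        "chrom": ["2D", "2D", "2D", "2D"],
        "pos": [81_800_099, 81_800_149, 5_000, 5_000],
        "strand": ["+", "+", "-", "-"],
    }
)


class TestAnchorSites:
    def test_plus_strand_arithmetic(self):
        sites = counts([(".", 0, "t1", 100, "A", "G", 20, 10)])
        res = anchor_sites(sites, ANCHORS)
        assert len(res.anchored) == 1
        row = res.anchored.iloc[0]
        assert (row["chrom"], row["pos"]) == ("2D", 81_800_099)
        assert row["ref_base"] == "A" and row["alt_base"] == "G"

    def test_minus_strand_complements_bases(self):
        sites = counts([(".", 0, "t2", 60, "C", "T", 20, 10)])
        res = anchor_sites(sites, ANCHORS)
        row = res.anchored.iloc[0]
        assert row["ref_base"] == "G" and row["alt_base"] == "A"

    def test_partition_of_input(self):
        sites = counts(
            [
                (".", 0, "t1", 100, "A", "G", 20, 10),
                (".", 0, "t9", 10, "C", "T", 20, 10),   # no anchor entry
            ]
        )
        res = anchor_sites(sites, ANCHORS)
        assert len(res.anchored) + len(res.unanchored) == len(sites)
        assert (res.unanchored["reason"] == "no_anchor").all()
        assert res.anchored_fraction == 0.5

    def test_conflicting_reference_bases_excluded(self):
        # t2:60 and t3:60 both anchor to 2D:5000 but imply different genome
        # reference bases -> both excluded as conflicts
        sites = counts(
            [
                (".", 0, "t2", 60, "C", "T", 20, 10),
                (".", 0, "t3", 60, "A", "T", 20, 10),
            ]
        )
        res = anchor_sites(sites, ANCHORS)
        assert len(res.anchored) == 0
        assert sorted(res.unanchored["reason"]) == ["conflict", "conflict"]


def anchored(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref_base", "alt_base"])


class TestMergeNonredundant:
    def test_union_of_overlapping_sets(self):
        s1 = anchored([("2D", p, "A", "G") for p in range(1, 11)])
        s2 = anchored([("2D", p, "A", "G") for p in range(6, 16)])
        nr = merge_nonredundant([s1, s2], ["x", "y"])
        assert len(nr) == 15
        both = nr[(nr["pos"] >= 6) & (nr["pos"] <= 10)]
        assert (both["n_pairs"] == 2).all()
        assert (both["provenance"] == "x,y").all()

    def test_idempotent_and_commutative(self):
        s1 = anchored([("1D", 5, "A", "C"), ("2D", 9, "G", "T")])
        s2 = anchored([("2D", 9, "G", "T"), ("3D", 1, "A", "T")])
        ab = merge_nonredundant([s1, s2], ["a", "b"])
        ba = merge_nonredundant([s2, s1], ["b", "a"])
        pd.testing.assert_frame_equal(ab, ba)
        twice = merge_nonredundant([s1, s1], ["a", "a"])
        assert site_keys(twice) == site_keys(merge_nonredundant([s1], ["a"]))

    def test_multiallelic_flagged_not_dropped(self):
        s1 = anchored([("2D", 9, "G", "T")])
        s2 = anchored([("2D", 9, "G", "A")])
        nr = merge_nonredundant([s1, s2])
        assert len(nr) == 1
        assert bool(nr["multiallelic"][0])
        assert nr["alt_base"][0] == "A,T"
        # orientation swap of the same biallelic pair is NOT multiallelic
        s3 = anchored([("2D", 9, "T", "G")])
        nr2 = merge_nonredundant([s1, s3])
        assert not bool(nr2["multiallelic"][0])

    @given(
        st.lists(
            st.lists(
                st.tuples(st.sampled_from(["1D", "2D"]), st.integers(1, 30)),
                max_size=15,
            ),
            min_size=1,
            max_size=4,
        )
    )
    def test_union_size_matches_bruteforce(self, keysets):
        frames = [anchored([(c, p, "A", "G") for c, p in ks]) for ks in keysets]
        nr = merge_nonredundant(frames)
        brute = {(c, p) for ks in keysets for c, p in ks}
        assert site_keys(nr) == brute
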