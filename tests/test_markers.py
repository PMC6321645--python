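"""Region filtering, candidate selection, restriction digestion and dCAPS
design."""

import re

import numpy as np
import pandas as pd
import pytest

from wheatbsa.markers import (
    DEFAULT_ENZYMES,
    IUPAC,
    DcapsCandidate,
    Enzyme,
    RegionFilter,
    design_dcaps,
    filter_region,
    in_silico_digest,
    revcomp,
    select_candidates,
)

HINFI = next(e for e in DEFAULT_ENZYMES if e.name == "HinfI")
HPAII = next(e for e in DEFAULT_ENZYMES if e.name == "HpaII")


def records(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "category", "avg_delta"])


class TestRegionFilter:
    DF = records(
        [
            ("2D", 99, "D_SPECIFIC", 0.6),
            ("2D", 100, "D_SPECIFIC", 0.5425),
            ("2D", 150, "HOMOEOLOGOUS", 0.0),
            ("2D", 200, "UNCLASSIFIED", -0.4025),
            ("2D", 201, "D_SPECIFIC", 0.9),
            ("1D", 150, "D_SPECIFIC", 0.8),
        ]
    )

    def test_closed_interval_and_counts(self):
        summary = filter_region(self.DF, RegionFilter("2D", 100, 200))
        assert summary.n_sites == 3  # both boundary positions included
        assert summary.category_counts == {
            "D_SPECIFIC": 1, "HOMOEOLOGOUS": 1, "UNCLASSIFIED": 1,
        }
        assert summary.delta_min == -0.4025
        assert summary.delta_max == 0.5425

    def test_idempotent(self):
        region = RegionFilter("2D", 100, 200)
        once = filter_region(self.DF, region)
        twice = filter_region(once.subset, region)
        pd.testing.assert_frame_equal(once.subset, twice.subset)

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            RegionFilter("2D", 200, 100)

    def test_empty_region_is_not_an_error(self):
        assert filter_region(self.DF, RegionFilter("7D", 1, 10)).n_sites == 0


class TestSelectCandidates:
    def test_strict_threshold(self):
        df = records(
            [
                ("2D", 1, "D_SPECIFIC", 0.54),
                ("2D", 2, "D_SPECIFIC", 0.40),
                ("2D", 3, "D_SPECIFIC", 0.38),   # exactly at the threshold: excluded
                ("2D", 4, "D_SPECIFIC", 0.10),
                ("2D", 5, "HOMOEOLOGOUS", 0.99),  # wrong category
            ]
        )
        sel = select_candidates(df, min_delta=0.38)
        assert sel["pos"].tolist() == [1, 2]  # sorted by avg_delta descending

    def test_monotone_in_threshold(self):
        df = records([("2D", i, "D_SPECIFIC", d) for i, d in enumerate([0.1, 0.3, 0.5, 0.7])])
        ns = [len(select_candidates(df, m)) for m in (0.0, 0.2, 0.4, 0.6, 0.8)]
        assert ns == sorted(ns, reverse=True)


def brute_force_digest(seq, enzyme):
    """Quadratic oracle: test every substring against the IUPAC pattern on
    both strands, collect cut positions, diff them into fragments."""
    L = len(enzyme.site)
    patterns = {enzyme.site: enzyme.cut_offset}
    if revcomp(enzyme.site) != enzyme.site:  # palindromes are one physical site
        patterns[revcomp(enzyme.site)] = L - enzyme.cut_offset
    cuts = set()
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        for pat, off in patterns.items():
            if all(b in IUPAC[p] for b, p in zip(window, pat)):
                cuts.add(i + off)
    cuts = sorted(c for c in cuts if 0 < c < len(seq))
    bounds = [0] + cuts + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


class TestDigest:
    def test_single_site_conservation(self):
        seq = "AAAGACTCAAA"  # one HinfI site (GANTC) at offset 3
        frags = in_silico_digest(seq, HINFI)
        assert len(frags) == 2
        assert sum(frags) == len(seq)
        assert frags == [4, 7]  # G^ANTC cuts after the G

    def test_no_site_single_fragment(self):
        assert in_silico_digest("AAAAAAAA", HPAII) == [8]

    def test_bottom_strand_site_is_cut(self):
        # GAGTC top is not GANTC; its reverse complement GACTC is
        seq = "TTTGAGTCTTT"
        assert len(in_silico_digest(seq, HINFI)) == 2

    @pytest.mark.parametrize("enzyme", DEFAULT_ENZYMES, ids=lambda e: e.name)
    def test_matches_bruteforce_oracle_on_random_sequences(self, enzyme):
        rng = np.random.default_rng(17)
        for _ in range(40):
            n = int(rng.integers(10, 120))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            assert in_silico_digest(seq, enzyme) == brute_force_digest(seq, enzyme)

    def test_enzyme_validation(self):
        with pytest.raises(ValueError):
            Enzyme("bad", "CCG")       # too short
        with pytest.raises(ValueError):
            Enzyme("bad", "CCXG")      # not IUPAC


class TestDesignDcaps:
    def test_natural_caps_preferred(self):
        # the G allele creates a natural HpaII site (CCGG) -> CAPS, 0 mismatches
        rng = np.random.default_rng(3)
        left = "ATTATAGATTACGATCAGGATCAATCC"
        right = "GTTACAGCTAGGATCGATCGTAGACTA"
        seq = left + "G" + right
        cands = design_dcaps(seq, len(left), "G", "A", enzymes=(HPAII,))
        assert cands, "expected a CAPS assay"
        assert cands[0].n_introduced_mismatches == 0
        assert cands[0].discriminates()

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            design_dcaps("ACGT" * 30, 60, "A", "A")

    def test_invalid_sequence_rejected(self):
        with pytest.raises(ValueError):
            design_dcaps("ACGTN" * 24, 60, "A", "G")

    def test_all_candidates_discriminate_and_conserve_length(self):
        """The defining dCAPS property, checked through the digestion oracle
        over a batch of random SNP flanks."""
        rng = np.random.default_rng(23)
        n_designed = 0
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=121))
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            cands = design_dcaps(seq, 60, ref, alt)
            for c in cands:
                n_designed += 1
                assert sorted(c.fragments["ref"]) != sorted(c.fragments["alt"])
                for allele in ("ref", "alt"):
                    assert sum(c.fragments[allele]) == c.amplicon_length
                assert c.n_introduced_mismatches <= 1
                assert 18 <= len(c.forward_primer) <= 26
                assert 18 <= len(c.reverse_primer) <= 26
        assert n_designed >= 5  # the search succeeds for a sizeable share of SNPs

    def test_primer_matches_template_except_introduced_mismatches(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=121))
            cands = design_dcaps(seq, 60, "A", "G") or design_dcaps(seq, 60, "C", "T")
            for c in cands[:3]:
                template = seq if c.strand == "+" else revcomp(seq)
                snp = 60 if c.strand == "+" else 60
                window = template[snp - len(c.forward_primer) : snp]
                diffs = [i for i, (a, b) in enumerate(zip(c.forward_primer, window)) if a != b]
                assert len(diffs) == c.n_introduced_mismatches
                # never the 3'-terminal base
                assert all(d < len(c.forward_primer) - 1 for d in diffs)
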