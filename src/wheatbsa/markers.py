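"""Candidate-region filtering and dCAPS marker design.

After the ΔSNP-index scan localizes the target, SNPs inside the physical
candidate interval are filtered by category and effect size and converted
into PCR-scoreable assays.  A CAPS marker exploits a restriction site
naturally created/destroyed by the SNP; a dCAPS marker introduces up to
``max_mismatches`` deliberate mismatches near the 3' end of one primer so
that the amplicon of exactly one allele completes an enzyme recognition
site.  Every candidate emitted here is validated by in-silico digestion of
both allelic amplicons — the defining dCAPS property is that their fragment
patterns differ.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IUPAC",
    "Enzyme",
    "DEFAULT_ENZYMES",
    "RegionFilter",
    "RegionSummary",
    "filter_region",
    "select_candidates",
    "in_silico_digest",
    "design_dcaps",
    "DcapsCandidate",
    "revcomp",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}


def revcomp(seq: str) -> str:
    try:
        return "".join(_COMP[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r}") from None


def _check_plain(seq: str) -> str:
    seq = seq.upper()
    if not seq or any(b not in "ACGT" for b in seq):
        raise ValueError("sequence must be plain unambiguous A/C/G/T")
    return seq


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: name, IUPAC recognition site, and the cut offset
    (bases from the 5' end of the recognition site to the cut on the top
    strand; e.g. G^ANTC for HinfI gives offset 1)."""

    name: str
    site: str
    cut_offset: int = 1

    def __post_init__(self):
        site = self.site.upper()
        if len(site) < 4:
            raise ValueError("recognition site must be at least 4 bases")
        if any(b not in IUPAC for b in site):
            raise ValueError(f"invalid IUPAC site {site!r}")
        object.__setattr__(self, "site", site)


#: enzymes used for the published markers, extensible by the caller
DEFAULT_ENZYMES = (
    Enzyme("StyI", "CCWWGG", 1),
    Enzyme("HpaII", "CCGG", 1),
    Enzyme("HinfI", "GANTC", 1),
)


# ---------------------------------------------------------------------------
# region filtering and candidate selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionFilter:
    """A closed 1-based physical interval on one chromosome."""

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")

    def contains(self, chrom, pos) -> np.ndarray:
        return (np.asarray(chrom) == self.chrom) & (
            (np.asarray(pos) >= self.start_bp) & (np.asarray(pos) <= self.end_bp)
        )


@dataclass
class RegionSummary:
    subset: pd.DataFrame
    category_counts: dict
    delta_min: float
    delta_max: float
    region: RegionFilter

    @property
    def n_sites(self) -> int:
        return len(self.subset)


def filter_region(classified_records: pd.DataFrame, region: RegionFilter) -> RegionSummary:
    """Restrict classified ΔSNP-index records to the candidate interval.

    Returns the subset (both interval ends included), counts per category and
    the range of ``avg_delta`` inside the interval.
    """
    mask = region.contains(classified_records["chrom"].to_numpy(),
                           classified_records["pos"].to_numpy())
    subset = classified_records.loc[mask].reset_index(drop=True)
    counts = subset["category"].value_counts().to_dict() if "category" in subset else {}
    if "avg_delta" in subset.columns and subset["avg_delta"].notna().any():
        dmin = float(subset["avg_delta"].min())
        dmax = float(subset["avg_delta"].max())
    else:
        dmin = dmax = float("nan")
    return RegionSummary(subset, counts, dmin, dmax, region)


def select_candidates(
    subset: pd.DataFrame,
    min_delta: float = 0.38,
    category: str = "D_SPECIFIC",
) -> pd.DataFrame:
    """Rank marker-candidate SNPs: the given category with ``avg_delta``
    strictly greater than ``min_delta``, sorted by ``avg_delta`` descending."""
    sel = subset
    if category is not None and "category" in sel.columns:
        sel = sel[sel["category"] == category]
    sel = sel[sel["avg_delta"] > min_delta]
    return sel.sort_values("avg_delta", ascending=False, kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# in-silico digestion
# ---------------------------------------------------------------------------

def _iupac_regex(site: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[b]}]" for b in site))


def _match_starts(seq: str, pattern: re.Pattern, length: int) -> list:
    # overlapping matches via lookahead-free manual scan
    return [i for i in range(len(seq) - length + 1) if pattern.match(seq, i, i + length)]


def in_silico_digest(amplicon_seq: str, enzyme: Enzyme) -> list:
    """Fragment lengths after complete digestion.

    Recognition sites are located on both strands (a bottom-strand site at
    top-strand start i cuts at i + len(site) - cut_offset); overlapping sites
    all cut.  Fragments are returned 5'->3' and always sum to the amplicon
    length; an amplicon with no site yields a single full-length fragment.
    """
    seq = _check_plain(amplicon_seq)
    fwd = enzyme.site
    rev = revcomp(enzyme.site)
    length = len(fwd)
    cuts = set()
    for start in _match_starts(seq, _iupac_regex(fwd), length):
        cuts.add(start + enzyme.cut_offset)
    if rev != fwd:
        for start in _match_starts(seq, _iupac_regex(rev), length):
            cuts.add(start + length - enzyme.cut_offset)
    cuts = sorted(c for c in cuts if 0 < c < len(seq))
    bounds = [0] + cuts + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


# ---------------------------------------------------------------------------
# dCAPS design
# ---------------------------------------------------------------------------

@dataclass
class DcapsCandidate:
    """One validated (d)CAPS assay for a SNP.

    ``n_introduced_mismatches`` = 0 means a natural CAPS assay.  ``strand``
    records which strand of the supplied flank the discriminating primer was
    designed on.  ``fragments`` maps allele ("ref"/"alt") to the fragment
    lengths of its digested amplicon.
    """

    enzyme: str
    forward_primer: str
    reverse_primer: str
    n_introduced_mismatches: int
    cut_allele: str
    amplicon_length: int
    fragments: dict
    strand: str
    site_key: str = ""
    marker_name: str = ""

    def discriminates(self) -> bool:
        return sorted(self.fragments["ref"]) != sorted(self.fragments["alt"])


def _gc_ok(primer: str, bounds) -> bool:
    gc = sum(b in "GC" for b in primer) / len(primer)
    return bounds[0] <= gc <= bounds[1]


def _pick_reverse_primer(seq: str, start_min: int, primer_len_range, gc_bounds):
    """Reverse primer from the 3' end of the available template (maximal
    amplicon); relax GC bounds rather than fail."""
    for relax in (0.0, 0.1, 0.5):
        bounds = (gc_bounds[0] - relax, gc_bounds[1] + relax)
        for rl in range(primer_len_range[0], primer_len_range[1] + 1):
            rend = len(seq)
            if rend - rl < start_min:
                continue
            primer = revcomp(seq[rend - rl : rend])
            if _gc_ok(primer, bounds):
                return primer, rend
    return None, None


def design_dcaps(
    flank_seq: str,
    snp_offset: int,
    ref_allele: str,
    alt_allele: str,
    enzymes=DEFAULT_ENZYMES,
    max_mismatches: int = 1,
    primer_len_range=(18, 26),
    gc_bounds=(0.40, 0.60),
):
    """Design allele-discriminating (d)CAPS assays for one SNP.

    ``flank_seq`` carries the SNP at 0-based ``snp_offset`` (the base shown
    there is ignored; ``ref_allele``/``alt_allele`` define the two versions).
    Both strands and every placement of each enzyme's recognition window over
    the SNP are searched; up to ``max_mismatches`` bases of the discriminating
    primer (3' half only, never the 3'-terminal base, never the SNP itself)
    are changed so the window is completed by exactly one allele.  Natural
    CAPS solutions (0 mismatches) are preferred and need no primer overlap.

    Every returned candidate has been validated by :func:`in_silico_digest`:
    the two allelic amplicons give different fragment patterns.  An empty
    list means no assay exists for the given enzymes.
    """
    ref_allele = ref_allele.upper()
    alt_allele = alt_allele.upper()
    if ref_allele == alt_allele:
        raise ValueError("alleles must differ")
    for a in (ref_allele, alt_allele):
        if a not in "ACGT" or len(a) != 1:
            raise ValueError(f"allele must be one unambiguous base, got {a!r}")
    seq = _check_plain(flank_seq)
    if not 0 <= snp_offset < len(seq):
        raise ValueError("snp_offset outside flank sequence")

    candidates = []
    for strand in ("+", "-"):
        if strand == "+":
            s, off, ra, aa = seq, snp_offset, ref_allele, alt_allele
        else:
            s, off = revcomp(seq), len(seq) - 1 - snp_offset
            ra, aa = revcomp(ref_allele), revcomp(alt_allele)
        for enzyme in enzymes:
            patterns = {enzyme.site, revcomp(enzyme.site)}
            for pat in sorted(patterns):
                candidates.extend(
                    _design_one_strand(
                        s, off, ra, aa, enzyme, pat, max_mismatches,
                        primer_len_range, gc_bounds, strand,
                    )
                )
    # prefer natural CAPS, then fewer mismatches, then longer amplicons
    candidates.sort(key=lambda c: (c.n_introduced_mismatches, -c.amplicon_length, c.enzyme))
    # de-duplicate identical assays
    seen, unique = set(), []
    for c in candidates:
        key = (c.forward_primer, c.reverse_primer, c.enzyme)
        if key not in seen:
            seen.add(key)
            unique.append(c)
    return unique


def _design_one_strand(
    seq, snp, ref_a, alt_a, enzyme, pattern, max_mismatches,
    primer_len_range, gc_bounds, strand,
):
    out = []
    pat_len = len(pattern)
    classes = [IUPAC[b] for b in pattern]
    for ws in range(max(0, snp - pat_len + 1), snp + 1):
        if ws + pat_len > len(seq):
            continue
        k_snp = snp - ws
        for cut_allele, cut_base, other_base in (("ref", ref_a, alt_a), ("alt", alt_a, ref_a)):
            if cut_base not in classes[k_snp] or other_base in classes[k_snp]:
                continue  # the SNP itself must complete the site for one allele only
            window = list(seq[ws : ws + pat_len])
            window[k_snp] = cut_base
            need = [
                ws + k
                for k in range(pat_len)
                if k != k_snp and window[k] not in classes[k]
            ]
            if len(need) > max_mismatches:
                continue
            for plen in range(primer_len_range[0], primer_len_range[1] + 1):
                p_start, p_end = snp - plen, snp - 1  # primer ends just before the SNP
                if p_start < 0:
                    continue
                if need:
                    half = snp - (plen + 1) // 2  # 3' half of the primer
                    if not all(half <= pos <= p_end - 1 for pos in need):
                        continue
                primer = list(seq[p_start : snp])
                for pos in need:
                    # choose a base satisfying the pattern class at that window slot
                    primer[pos - p_start] = IUPAC[pattern[pos - ws]][0]
                primer_s = "".join(primer)
                if not _gc_ok(primer_s, gc_bounds):
                    continue
                rev_primer, rend = _pick_reverse_primer(
                    seq, snp + 1, primer_len_range, gc_bounds
                )
                if rev_primer is None:
                    continue
                frags = {}
                for label, allele in (("ref", ref_a), ("alt", alt_a)):
                    amp = primer_s + allele + seq[snp + 1 : rend]
                    frags[label] = in_silico_digest(amp, enzyme)
                cand = DcapsCandidate(
                    enzyme=enzyme.name,
                    forward_primer=primer_s,
                    reverse_primer=rev_primer,
                    n_introduced_mismatches=len(need),
                    cut_allele=cut_allele if strand == "+" else cut_allele,
                    amplicon_length=len(primer_s) + 1 + (rend - snp - 1),
                    fragments=frags,
                    strand=strand,
                )
                if cand.discriminates():
                    out.append(cand)
                break  # shortest workable primer per window placement
    return out


def candidate_report(candidates, names=None) -> pd.DataFrame:
    """Tabular marker report: name, primers 5'->3', enzyme, fragments per
    allele — one row per assay."""
    rows = []
    for i, c in enumerate(candidates):
        name = c.marker_name or (names[i] if names else f"bsa{i + 1}")
        rows.append(
            {
                "marker": name,
                "site": c.site_key,
                "forward_primer": c.forward_primer,
                "reverse_primer": c.reverse_primer,
                "enzyme": c.enzyme,
                "mismatches": c.n_introduced_mismatches,
                "cut_allele": c.cut_allele,
                "amplicon_length": c.amplicon_length,
                "fragments_ref": ",".join(map(str, c.fragments["ref"])),
                "fragments_alt": ",".join(map(str, c.fragments["alt"])),
            }
        )
    return pd.DataFrame(rows)
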