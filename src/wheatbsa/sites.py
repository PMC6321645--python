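"""SNP-site calling, transcript-to-genome anchoring and non-redundant merging.

The real pipeline calls SNPs from alignments against two parental
transcriptomes, anchors the transcript-coordinate sites to the diploid genome
and integrates the eight bulk x reference alignment pairs into a single
non-redundant (NR) site set keyed by genome coordinate.  This module performs
those steps on the tab-separated count-table dialect.

Thresholds emulate the variant caller used upstream: a site is called when its
depth is at least ``min_depth`` (10) and its alternate-allele fraction at least
``min_alt_fraction`` (0.1); both boundaries are inclusive.  Coordinates are
1-based and fully closed; strand is handled by reverse complement during
anchoring.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "call_snps",
    "anchor_sites",
    "AnchorResult",
    "merge_nonredundant",
    "site_keys",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

COUNT_COLUMNS = [
    "chrom", "pos", "transcript_id", "transcript_pos",
    "ref_base", "alt_base", "depth", "alt_depth",
]


def _validate_counts(table: pd.DataFrame) -> None:
    d = table["depth"].to_numpy()
    k = table["alt_depth"].to_numpy()
    if (d < 0).any() or (k < 0).any():
        raise ValueError("negative read counts")
    if (k > d).any():
        raise ValueError("alt_depth exceeds depth")


def call_snps(
    table: pd.DataFrame,
    min_alt_fraction: float = 0.1,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Call SNP sites from one count table.

    A site is called iff depth >= ``min_depth`` and alt_depth / depth >=
    ``min_alt_fraction`` (boundary inclusive on both).  Returns the called
    rows (transcript coordinates) unchanged.  Zero-depth rows are never
    called.
    """
    _validate_counts(table)
    d = table["depth"].to_numpy()
    k = table["alt_depth"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(d > 0, k / np.maximum(d, 1), 0.0)
    keep = (d >= min_depth) & (frac >= min_alt_fraction)
    return table.loc[keep].reset_index(drop=True)


class AnchorResult(NamedTuple):
    """Outcome of anchoring: genome-coordinate sites, plus the sites that
    could not be anchored (``reason`` column: ``no_anchor`` for missing anchor
    entries, ``conflict`` for anchor collisions with inconsistent reference
    bases)."""

    anchored: pd.DataFrame
    unanchored: pd.DataFrame

    @property
    def anchored_fraction(self) -> float:
        n = len(self.anchored) + len(self.unanchored)
        return len(self.anchored) / n if n else float("nan")


def anchor_sites(sites: pd.DataFrame, anchors: pd.DataFrame) -> AnchorResult:
    """Anchor transcript-coordinate sites to the genome.

    ``anchors`` maps (transcript_id, transcript_pos) -> (chrom, pos, strand).
    Bases of sites on minus-strand transcripts are reverse-complemented into
    genome orientation.  Sites without an anchor entry are returned separately;
    anchor collisions — two transcript positions resolving to the same genome
    position with inconsistent genome-orientation reference bases — are
    excluded from the anchored set and reported with reason ``conflict``.
    """
    merged = sites.merge(
        anchors.rename(columns={"chrom": "g_chrom", "pos": "g_pos"}),
        on=["transcript_id", "transcript_pos"],
        how="left",
        validate="many_to_one",
    )
    missing = merged["g_chrom"].isna()
    unanchored = sites.loc[missing.to_numpy()].copy()
    unanchored["reason"] = "no_anchor"

    ok = merged.loc[~missing].copy()
    minus = (ok["strand"] == "-").to_numpy()
    for col in ("ref_base", "alt_base"):
        if col in ok.columns:
            vals = ok[col].to_numpy(dtype=object)
            comp = np.array([_COMPLEMENT.get(v, v) for v in vals], dtype=object)
            ok[col] = np.where(minus, comp, vals)
    ok["chrom"] = ok["g_chrom"]
    ok["pos"] = ok["g_pos"].astype(np.int64)
    ok = ok.drop(columns=["g_chrom", "g_pos"])

    if "ref_base" in ok.columns and len(ok):
        nref = ok.groupby(["chrom", "pos"])["ref_base"].transform("nunique")
        conflict = (nref > 1).to_numpy()
    else:
        conflict = np.zeros(len(ok), dtype=bool)
    conflicted = ok.loc[conflict, list(sites.columns)].copy()
    conflicted["reason"] = "conflict"
    anchored = ok.loc[~conflict].reset_index(drop=True)
    unanchored = pd.concat([unanchored, conflicted], ignore_index=True)
    return AnchorResult(anchored=anchored, unanchored=unanchored)


def site_keys(df: pd.DataFrame) -> set:
    """The genome keys {(chrom, pos), ...} of a site table."""
    return set(zip(df["chrom"].tolist(), df["pos"].astype(int).tolist()))


def merge_nonredundant(
    anchored_sets: Iterable[pd.DataFrame],
    pair_names: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Integrate anchored site sets into one non-redundant set.

    Sites are keyed by (chrom, pos); the union is taken and per-site
    provenance (which input sets called the site) is retained as a sorted
    tuple of pair names plus an 8-bit-style count.  When the alleles observed
    at one key span more than two distinct bases the site is kept and flagged
    ``multiallelic`` with all alternates recorded.

    The operation is commutative, associative and idempotent in the keyed
    sense (provenance aside, merging a merge changes nothing).
    """
    anchored_sets = list(anchored_sets)
    if pair_names is None:
        pair_names = [f"pair{i}" for i in range(len(anchored_sets))]
    pair_names = list(pair_names)

    rows: dict = {}
    for name, df in zip(pair_names, anchored_sets):
        if not len(df):
            continue
        for chrom, pos, ref, alt in zip(
            df["chrom"], df["pos"].astype(int), df.get("ref_base", "."), df.get("alt_base", ".")
        ):
            key = (chrom, pos)
            rec = rows.get(key)
            if rec is None:
                rec = rows[key] = {"refs": set(), "alts": set(), "pairs": set()}
            if ref != ".":
                rec["refs"].add(ref)
            if alt != ".":
                rec["alts"].add(alt)
            rec["pairs"].add(name)

    out = []
    for (chrom, pos), rec in rows.items():
        alleles = rec["refs"] | rec["alts"]
        out.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref_base": ",".join(sorted(rec["refs"])) or ".",
                "alt_base": ",".join(sorted(rec["alts"])) or ".",
                "multiallelic": len(alleles) > 2,
                "n_pairs": len(rec["pairs"]),
                "provenance": ",".join(sorted(rec["pairs"])),
            }
        )
    nr = pd.DataFrame(
        out,
        columns=["chrom", "pos", "ref_base", "alt_base", "multiallelic", "n_pairs", "provenance"],
    )
    if len(nr):
        nr = nr.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        nr["pos"] = nr["pos"].astype(np.int64)
    return nr
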