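"""Bulked-segregant statistics: SNP-index, ΔSNP-index and the Steel–Dwass
all-pairs rank test.

The SNP-index at a site is the fraction of aligned reads carrying the
alternate allele; it is treated as *missing* (not zero) when the depth falls
below the calling floor.  Because indices are computed against two different
parental references, each index is first polarized to the donor-parent
(carrier-parent) allele frequency before bulks are contrasted — unpolarized
averaging across references would systematically cancel the signal.  The
ΔSNP-index is the polarized carrier-bulk index minus the non-carrier-bulk
index; at each site the four available pair values (two sibling populations x
two references) are averaged, with the number of informative pairs recorded.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import sites as _sites
from .classify import CATEGORY_LABELS
from .simulate import BULK_NAMES, PARENT_A, PARENT_B

__all__ = [
    "snp_index",
    "polarize",
    "delta_snp_index",
    "average_delta",
    "build_delta_table",
    "steel_dwass",
    "chromosome_tracks",
    "PAIRS",
]

#: the eight alignment pairs: bulk x reference parent
PAIRS = tuple((bulk, ref) for bulk in BULK_NAMES for ref in (PARENT_A, PARENT_B))

#: the four contrasting-bulk comparisons: sibling population x reference
POPULATIONS = ("SP1", "SP2")


def snp_index(depth, alt_depth, min_depth: int = 10):
    """Alternate-allele read fraction; NaN (missing) below the depth floor.

    Scalar or array.  Raises if alt_depth exceeds depth or counts are
    negative.
    """
    d = np.asarray(depth, dtype=float)
    k = np.asarray(alt_depth, dtype=float)
    if (k > d).any() or (d < 0).any() or (k < 0).any():
        raise ValueError("require 0 <= alt_depth <= depth")
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(d >= min_depth, k / np.maximum(d, 1), np.nan)
    return float(idx) if np.isscalar(depth) else idx


def polarize(index, reference_parent: str, donor_parent: str = PARENT_B):
    """Convert a SNP-index into the donor-parent allele frequency.

    Against the non-donor reference the alternate allele *is* the donor
    allele, so the index passes through; against the donor reference the
    alternate is the non-donor allele and the index is complemented.
    Missing values (NaN) pass through.
    """
    for label in (reference_parent, donor_parent):
        if label not in (PARENT_A, PARENT_B):
            raise ValueError(f"unknown parent label {label!r}")
    if reference_parent == donor_parent:
        return 1.0 - index
    return index


def delta_snp_index(carrier_index, noncarrier_index):
    """Carrier-bulk minus non-carrier-bulk polarized index; missing if either
    input is missing (NaN propagates)."""
    return carrier_index - noncarrier_index


def average_delta(values) -> tuple:
    """Mean over the available (non-missing) ΔSNP-index values.

    Returns (avg, n_informative); avg is NaN when no value is available.
    """
    arr = np.asarray(values, dtype=float)
    ok = ~np.isnan(arr)
    n = int(ok.sum())
    return (float(arr[ok].mean()) if n else float("nan")), n


def build_delta_table(
    count_tables: dict,
    anchors: pd.DataFrame,
    nr_sites: pd.DataFrame | None = None,
    donor_parent: str = PARENT_B,
    min_depth: int = 10,
    exclude_multiallelic: bool = True,
) -> pd.DataFrame:
    """Per-site ΔSNP-index records from the eight alignment-pair count tables.

    ``count_tables`` maps (bulk, reference_parent) -> count table (transcript
    coordinates; anchored here).  When ``nr_sites`` is given, records are
    restricted to the non-redundant set (multiallelic sites dropped by default
    since the SNP-index is defined for a single alternate allele).

    Returns one row per genome site with columns ``idx_<bulk>.<ref>`` (eight
    polarized indices), ``delta_<pop>.<ref>`` (four ΔSNP-index values),
    ``avg_delta`` and ``n_informative``.
    """
    wide = None
    for (bulk, ref), table in count_tables.items():
        anch = _sites.anchor_sites(table, anchors).anchored
        idx = snp_index(anch["depth"].to_numpy(), anch["alt_depth"].to_numpy(), min_depth)
        col = pd.DataFrame(
            {
                "chrom": anch["chrom"].to_numpy(),
                "pos": anch["pos"].to_numpy(),
                f"idx_{bulk}.{ref}": polarize(idx, ref, donor_parent),
            }
        )
        wide = col if wide is None else wide.merge(col, on=["chrom", "pos"], how="outer")
    if wide is None:
        raise ValueError("no count tables supplied")

    if nr_sites is not None:
        keep = nr_sites
        if exclude_multiallelic and "multiallelic" in keep.columns:
            keep = keep[~keep["multiallelic"]]
        wide = wide.merge(keep[["chrom", "pos"]], on=["chrom", "pos"], how="inner")

    deltas = []
    for pop in POPULATIONS:
        for ref in (PARENT_A, PARENT_B):
            c = wide.get(f"idx_carrier-{pop}.{ref}")
            n = wide.get(f"idx_noncarrier-{pop}.{ref}")
            name = f"delta_{pop}.{ref}"
            if c is None or n is None:
                wide[name] = np.nan
            else:
                wide[name] = delta_snp_index(c.to_numpy(), n.to_numpy())
            deltas.append(name)

    dmat = wide[deltas].to_numpy()
    n_inf = (~np.isnan(dmat)).sum(axis=1)
    sums = np.nansum(dmat, axis=1)  # all-missing rows sum to 0 but are masked below
    wide["avg_delta"] = np.where(n_inf > 0, sums / np.maximum(n_inf, 1), np.nan)
    wide["n_informative"] = n_inf
    return wide.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Steel–Dwass all-pairs comparison
# ---------------------------------------------------------------------------

def _pair_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected standardized rank-sum statistic for one pair, ranked over
    the two samples jointly (midranks)."""
    m, n = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    big_n = m + n
    w = ranks[:m].sum()
    expect = m * (big_n + 1) / 2.0
    var = m * n / (big_n * (big_n - 1.0)) * ((ranks - (big_n + 1) / 2.0) ** 2).sum()
    if var == 0:
        return 0.0
    return (w - expect) / np.sqrt(var)


def _pair_statistic_permutations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|statistic| under every reassignment of the pooled values (exact null)."""
    m = len(x)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    big_n = len(pooled)
    expect = m * (big_n + 1) / 2.0
    var = m * (big_n - m) / (big_n * (big_n - 1.0)) * ((ranks - (big_n + 1) / 2.0) ** 2).sum()
    if var == 0:
        return np.zeros(1)
    sums = [ranks[list(c)].sum() for c in itertools.combinations(range(big_n), m)]
    out = (np.asarray(sums) - expect) / np.sqrt(var)
    return np.abs(out)


def steel_dwass(
    groups,
    labels=None,
    method: str = "asymptotic",
) -> pd.DataFrame:
    """Steel–Dwass all-pairs nonparametric multiple comparison.

    For every pair of groups the two samples are ranked jointly (midranks,
    tie-corrected variance) and the standardized rank-sum statistic ``t`` is
    referred to the studentized-range distribution with ``k`` groups and
    infinite degrees of freedom via q = sqrt(2)|t|.

    ``method="exact"`` replaces the asymptotic tail with a full enumeration of
    the pairwise rank statistic (feasible for <= 8 values per group); with two
    groups this is the exact two-sided rank-sum test, while for k > 2 the
    asymptotic mode additionally adjusts for the k(k-1)/2 comparisons and is
    deliberately conservative relative to the unadjusted enumeration.

    Groups with fewer than 2 values are excluded with a warning; fewer than
    two usable groups is an error.  Returns a DataFrame with one row per pair.
    """
    import warnings

    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    labels = list(labels)
    usable = [i for i, g in enumerate(groups) if len(g) >= 2]
    if len(usable) < len(groups):
        dropped = [labels[i] for i in range(len(groups)) if i not in usable]
        warnings.warn(f"excluding groups with fewer than 2 values: {dropped}", stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need at least two groups with >= 2 values")
    k = len(usable)

    rows = []
    for a, b in itertools.combinations(usable, 2):
        t = _pair_statistic(groups[a], groups[b])
        if method == "asymptotic":
            p = float(sps.studentized_range.sf(np.sqrt(2.0) * abs(t), k, np.inf))
        elif method == "exact":
            if max(len(groups[a]), len(groups[b])) > 8:
                raise ValueError("exact mode supports at most 8 values per group")
            null = _pair_statistic_permutations(groups[a], groups[b])
            p = float((null >= abs(t) - 1e-12).mean())
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(
            {
                "group1": labels[a],
                "group2": labels[b],
                "n1": len(groups[a]),
                "n2": len(groups[b]),
                "statistic": t,
                "p_value": min(p, 1.0),
                "method": method,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plot-ready tracks
# ---------------------------------------------------------------------------

def chromosome_tracks(records: pd.DataFrame, classified: pd.DataFrame) -> pd.DataFrame:
    """Join ΔSNP-index records with site categories into a plot-ready table:
    one row per site with a non-missing average, sorted by (chrom, pos), the
    category shown with its display label (Aet / Ldn / Unknown)."""
    merged = records.merge(
        classified[["chrom", "pos", "category"]], on=["chrom", "pos"], how="inner"
    )
    merged = merged[~merged["avg_delta"].isna()]
    out = merged[["chrom", "pos", "avg_delta", "category"]].copy()
    out["category"] = out["category"].map(CATEGORY_LABELS).fillna(out["category"])
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
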