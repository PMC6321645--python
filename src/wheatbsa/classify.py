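"""Classification of non-redundant SNP sites in an allopolyploid background.

A SNP called from hexaploid-bulk reads aligned to a diploid (D-genome)
parental transcriptome can be either a true allelic variant segregating on
the D genome or a fixed homoeologous difference against the A/B subgenomes.
Two evidence sets separate them:

* sites also present in the pairwise comparison of the two D-genome parents
  represent D-genome-specific allelic variation (``D_SPECIFIC``);
* sites also called from reads of the tetraploid AB parent represent
  homoeologous polymorphism (``HOMOEOLOGOUS``);
* sites in neither evidence set remain ``UNCLASSIFIED``.

Sites carrying both kinds of evidence are resolved by a configurable
precedence (default: homoeologous, because tetraploid-read support at a site
cannot be distinguished from homoeologous signal); both flags are always
preserved.  Evidence is keyed by genome coordinate (chrom, pos) only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import sites as _sites

__all__ = [
    "CATEGORIES",
    "CATEGORY_LABELS",
    "build_evidence_sets",
    "classify",
    "tabulate_by_chromosome",
]

CATEGORIES = ("D_SPECIFIC", "HOMOEOLOGOUS", "UNCLASSIFIED")

#: display labels used in track tables and figures
CATEGORY_LABELS = {"D_SPECIFIC": "Aet", "HOMOEOLOGOUS": "Ldn", "UNCLASSIFIED": "Unknown"}


def build_evidence_sets(
    pairwise_sites: pd.DataFrame,
    tetraploid_tables: dict,
    anchors: pd.DataFrame,
    min_alt_fraction: float = 0.1,
    min_depth: int = 10,
):
    """Assemble the two genome-keyed evidence sets.

    ``pairwise_sites`` is the parental-pairwise SNP list in transcript
    coordinates (anchored here); ``tetraploid_tables`` maps reference-parent
    name -> tetraploid count table, each of which is SNP-called and anchored,
    then unioned across references.  Returns (pairwise_keys, tetraploid_keys)
    as sets of (chrom, pos).
    """
    pw_anch = _sites.anchor_sites(pairwise_sites, anchors)
    pairwise_keys = _sites.site_keys(pw_anch.anchored)

    tetraploid_keys: set = set()
    for _ref, table in sorted(tetraploid_tables.items()):
        called = _sites.call_snps(table, min_alt_fraction, min_depth)
        anch = _sites.anchor_sites(called, anchors)
        tetraploid_keys |= _sites.site_keys(anch.anchored)

    if not pairwise_keys and not tetraploid_keys:
        warnings.warn(
            "both evidence sets are empty; every site will be UNCLASSIFIED",
            stacklevel=2,
        )
    return pairwise_keys, tetraploid_keys


def classify(
    nr_sites: pd.DataFrame,
    pairwise_keys: set,
    tetraploid_keys: set,
    precedence: str = "tetraploid",
) -> pd.DataFrame:
    """Assign each NR site one category from the two evidence flags.

    in pairwise only -> D_SPECIFIC; in tetraploid only -> HOMOEOLOGOUS;
    in neither -> UNCLASSIFIED; in both -> HOMOEOLOGOUS when ``precedence`` is
    ``"tetraploid"`` (default) or D_SPECIFIC when ``"pairwise"``.  The result
    carries both boolean flags alongside the category and is independent of
    input order.
    """
    if precedence not in ("tetraploid", "pairwise"):
        raise ValueError(f"unknown precedence {precedence!r}")
    keys = list(zip(nr_sites["chrom"].tolist(), nr_sites["pos"].astype(int).tolist()))
    in_pw = np.fromiter((k in pairwise_keys for k in keys), dtype=bool, count=len(keys))
    in_tet = np.fromiter((k in tetraploid_keys for k in keys), dtype=bool, count=len(keys))

    if precedence == "tetraploid":
        category = np.where(in_tet, "HOMOEOLOGOUS", np.where(in_pw, "D_SPECIFIC", "UNCLASSIFIED"))
    else:
        category = np.where(in_pw, "D_SPECIFIC", np.where(in_tet, "HOMOEOLOGOUS", "UNCLASSIFIED"))

    out = nr_sites.copy()
    out["in_parental_pairwise"] = in_pw
    out["in_tetraploid"] = in_tet
    out["category"] = category
    return out


def tabulate_by_chromosome(classified: pd.DataFrame) -> pd.DataFrame:
    """Counts per chromosome x category with row and column totals.

    Rows are chromosomes (sorted) plus a ``Total`` row; columns are the three
    categories plus a ``Total`` column.  An empty input yields an all-zero
    one-row table.
    """
    if len(classified):
        tab = (
            classified.pivot_table(
                index="chrom", columns="category", aggfunc="size", fill_value=0
            )
            .reindex(columns=list(CATEGORIES), fill_value=0)
            .sort_index()
        )
    else:
        tab = pd.DataFrame(columns=list(CATEGORIES), dtype=int)
    tab.columns.name = None
    tab["Total"] = tab.sum(axis=1)
    total_row = tab.sum(axis=0)
    tab.loc["Total"] = total_row
    return tab.astype(int)
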