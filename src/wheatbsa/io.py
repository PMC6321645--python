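"""Readers and writers for every artifact the pipeline touches.

All tabular artifacts are tab-separated text with a header row; gzip is
accepted transparently (by file suffix) on both read and write.  FASTA uses
2-line records.  Ground truth and configuration are JSON/YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_count_table", "write_count_table",
    "read_anchor_table", "write_anchor_table",
    "read_pairwise_list", "write_pairwise_list",
    "read_flank_fasta", "write_flank_fasta",
    "read_truth", "write_truth",
    "read_table", "write_table",
    "write_sites_vcf",
]

def _open_text(path, mode="r"):
    path = Path(path)
    if path.suffix == ".gz":
        import gzip

        return gzip.open(path, mode + "t")
    return open(path, mode)


_COUNT_DTYPES = {
    "chrom": str, "pos": np.int64, "transcript_id": str, "transcript_pos": np.int64,
    "ref_base": str, "alt_base": str, "depth": np.int64, "alt_depth": np.int64,
}


class FormatError(ValueError):
    """Malformed input file (carries file name and, where known, line number)."""


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path, dtypes=None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=dtypes)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return df


def write_count_table(table: pd.DataFrame, path) -> Path:
    return write_table(table[list(_COUNT_DTYPES)], path)


def read_count_table(path) -> pd.DataFrame:
    df = read_table(path, dtypes=_COUNT_DTYPES)
    missing = set(_COUNT_DTYPES) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[df["alt_depth"] > df["depth"]]
    if len(bad):
        raise FormatError(f"{path}: line {bad[0] + 2}: alt_depth exceeds depth")
    return df


def write_anchor_table(anchors: pd.DataFrame, path) -> Path:
    return write_table(anchors[["transcript_id", "transcript_pos", "chrom", "pos", "strand"]], path)


def read_anchor_table(path) -> pd.DataFrame:
    df = read_table(path, dtypes={"transcript_id": str, "transcript_pos": np.int64,
                                  "chrom": str, "pos": np.int64, "strand": str})
    bad = df.index[~df["strand"].isin(["+", "-"])]
    if len(bad):
        raise FormatError(f"{path}: line {bad[0] + 2}: strand must be + or -")
    return df


def write_pairwise_list(sites: pd.DataFrame, path) -> Path:
    return write_table(sites[["transcript_id", "transcript_pos", "ref_base", "alt_base"]], path)


def read_pairwise_list(path) -> pd.DataFrame:
    return read_table(path, dtypes={"transcript_id": str, "transcript_pos": np.int64,
                                    "ref_base": str, "alt_base": str})


def write_flank_fasta(records, path) -> Path:
    path = Path(path)
    seqrecs = [
        SeqRecord(Seq(r["seq"]), id=r["id"], description=r.get("description", ""))
        for r in records
    ]
    with _open_text(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta-2line")
    return path


def read_flank_fasta(path) -> list:
    out = []
    with _open_text(path) as fh:
        recs = list(SeqIO.parse(fh, "fasta"))
    for rec in recs:
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        out.append({"id": rec.id, "description": desc, "seq": str(rec.seq)})
    return out


def write_truth(truth, genome, path) -> Path:
    """Serialize the shareable part of the ground truth (bulk membership,
    per-site truth and allele frequencies, causal locus, seed).  Individual
    haplotypes are simulation-internal and are not serialized."""
    path = Path(path)
    site_truth = truth.site_truth.copy()
    freq = truth.true_allele_freq
    payload = {
        "seed": truth.seed,
        "causal": {"chrom": genome.causal[0], "pos": int(genome.causal[1])},
        "chromosomes": [[c, int(l)] for c, l in genome.chromosomes],
        "bulk_membership": truth.bulk_membership.to_dict(orient="list"),
        "site_truth": {
            c: (site_truth[c].astype(float).tolist()
                if site_truth[c].dtype.kind in "fc"
                else site_truth[c].tolist())
            for c in site_truth.columns
        },
        "true_allele_freq": {c: freq[c].astype(float).round(10).tolist() for c in freq.columns},
    }
    with _open_text(path, "w") as fh:
        json.dump(payload, fh)
    return path


def read_truth(path) -> dict:
    with _open_text(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    payload["bulk_membership"] = pd.DataFrame(payload["bulk_membership"])
    payload["site_truth"] = pd.DataFrame(payload["site_truth"])
    payload["true_allele_freq"] = pd.DataFrame(payload["true_allele_freq"])
    return payload


def write_sites_vcf(nr_sites: pd.DataFrame, path, classified: pd.DataFrame | None = None) -> Path:
    """Export the NR site set in a minimal VCF dialect.

    INFO carries the provenance mask (``PROV``), pair count (``NP``), the
    multiallelic flag and, when a classified table is supplied, the category
    (``CLASS``).  This is an export format for interoperability, not a
    round-trip container.
    """
    path = Path(path)
    df = nr_sites
    if classified is not None:
        df = df.merge(classified[["chrom", "pos", "category"]], on=["chrom", "pos"], how="left")
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=PROV,Number=1,Type=String,Description="Alignment pairs calling the site">',
        '##INFO=<ID=NP,Number=1,Type=Integer,Description="Number of alignment pairs">',
        '##INFO=<ID=MULTI,Number=0,Type=Flag,Description="More than two alleles observed">',
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="Site category">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for _, row in df.iterrows():
        ref = str(row["ref_base"]).split(",")[0]
        alt = str(row["alt_base"])
        info = [f"PROV={row['provenance'].replace(';', '|')}", f"NP={row['n_pairs']}"]
        if row.get("multiallelic", False):
            info.append("MULTI")
        if classified is not None and isinstance(row.get("category"), str):
            info.append(f"CLASS={row['category']}")
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t.\t{ref}\t{alt}\t.\tPASS\t{';'.join(info)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
    return path
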