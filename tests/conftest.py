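"""Shared fixtures: a full default-scale pipeline run (computed once per
session) and small hand-built genomes/truth objects for unit tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from wheatbsa.config import PipelineConfig
from wheatbsa.simulate import BULK_NAMES, GenomeModel, SimTruth

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One complete pipeline run at the default study conditions (7
    chromosomes, causal locus on 2D, four bulks of ten, negative-binomial
    depth).  Shared by the classification, localization and linkage tests."""
    from wheatbsa.pipeline import run_all

    outdir = tmp_path_factory.mktemp("default-run")
    return run_all(PipelineConfig(seed=1), outdir)


def make_genome(site_spec, causal, chromosomes):
    """Hand-built GenomeModel.  ``site_spec`` is a list of tuples
    (chrom, pos, parent_a, parent_b); kind is inferred from allele equality."""
    rows = []
    for i, (chrom, pos, a, b) in enumerate(site_spec):
        rows.append(
            {
                "chrom": chrom, "pos": pos,
                "kind": "allelic" if a != b else "homoeolog",
                "parent_a": a, "parent_b": b,
                "transcript_id": f"tx_{chrom}_{i:05d}", "transcript_pos": 50,
                "strand": "+",
            }
        )
    sites = pd.DataFrame(rows)
    return GenomeModel(list(chromosomes), sites, causal)


def make_truth(genome, freqs_by_bulk):
    """Minimal SimTruth carrying only per-bulk true allele frequencies."""
    freq = pd.DataFrame({b: np.asarray(f, dtype=float) for b, f in freqs_by_bulk.items()})
    for b in BULK_NAMES:
        if b not in freq.columns:
            freq[b] = 0.5
    return SimTruth(
        bulk_membership=pd.DataFrame(columns=["bulk", "individual", "causal_genotype"]),
        true_allele_freq=freq,
        site_truth=genome.sites[["chrom", "pos", "kind"]].copy(),
        individuals={},
        seed=0,
    )


@pytest.fixture
def toy_genome():
    """Two chromosomes; three allelic sites; causal locus at the first site."""
    return make_genome(
        [
            ("2D", 100_000, "A", "G"),
            ("2D", 500_000, "C", "T"),
            ("5D", 300_000, "G", "T"),
        ],
        causal=("2D", 100_000),
        chromosomes=[("2D", 1_000_000), ("5D", 1_000_000)],
    )
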