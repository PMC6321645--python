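"""End-to-end orchestration: simulate → call → classify → index → select →
design → map.

Each stage is a thin composition of the module functions, with record-count
bookkeeping at every step.  ``run_all`` executes the whole chain on a
:class:`~wheatbsa.config.PipelineConfig` and writes the artifacts and a text
report into the output directory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import build_evidence_sets as _build_evidence_sets, classify as _classify_sites, tabulate_by_chromosome as _tabulate
from . import io as wio
from . import linkage as _linkage
from . import markers as _markers
from . import sites as _sites
from . import stats as _stats
from .config import PipelineConfig
from .report import StageLog, mean_called_sites
from .simulate import BULK_NAMES, PARENT_A, PARENT_B, emit_fixture_bundle

__all__ = ["run_all", "analyse_bundle", "PipelineResult"]


@dataclass
class PipelineResult:
    nr_sites: pd.DataFrame
    classified: pd.DataFrame
    delta: pd.DataFrame
    tracks: pd.DataFrame
    steel_dwass: pd.DataFrame
    region_summary: object
    candidates: pd.DataFrame
    markers: list
    marker_map: pd.DataFrame
    log: StageLog
    call_totals: dict = field(default_factory=dict)
    truth: object = None
    genome: object = None


def analyse_bundle(
    count_tables: dict,
    tetraploid_tables: dict,
    anchors: pd.DataFrame,
    pairwise: pd.DataFrame,
    cfg: PipelineConfig,
    log: StageLog | None = None,
) -> dict:
    """Run calling, anchoring, merging, classification and ΔSNP-index on
    already-loaded tables; returns a dict of intermediate frames."""
    log = log if log is not None else StageLog()

    called, anchored_sets, names, totals = [], [], [], {}
    for (bulk, ref), table in count_tables.items():
        c = _sites.call_snps(table, cfg.min_alt_fraction, cfg.min_depth)
        log.add(f"call[{bulk}.{ref}]", len(table), len(c), "depth/fraction thresholds")
        totals[(bulk, ref)] = len(c)
        anch = _sites.anchor_sites(c, anchors)
        log.add(f"anchor[{bulk}.{ref}]", len(c), len(anch.anchored),
                f"{len(anch.unanchored)} unanchored/conflict")
        called.append(c)
        anchored_sets.append(anch.anchored)
        names.append(f"{bulk}.{ref}")

    nr = _sites.merge_nonredundant(anchored_sets, names)
    log.add("merge_nonredundant", sum(len(a) for a in anchored_sets), len(nr), "union by (chrom,pos)")

    pw_keys, tet_keys = _build_evidence_sets(
        pairwise, tetraploid_tables, anchors, cfg.min_alt_fraction, cfg.min_depth
    )
    classified = _classify_sites(nr, pw_keys, tet_keys)
    log.add("classify", len(nr), len(classified), f"pairwise={len(pw_keys)} tetraploid={len(tet_keys)}")

    delta = _stats.build_delta_table(
        count_tables, anchors, nr, cfg.donor_parent, cfg.min_depth
    )
    log.add("delta_index", len(nr), len(delta), "multiallelic excluded" )
    tracks = _stats.chromosome_tracks(delta, classified)
    return {
        "nr": nr, "classified": classified, "delta": delta, "tracks": tracks,
        "call_totals": totals, "log": log,
    }


def run_all(cfg: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute the full synthetic-experiment pipeline.

    Simulates the fixture bundle, reads it back through the documented
    formats (so the readers are on the critical path), analyses it, designs
    up to ``cfg.max_markers`` dCAPS assays for the top candidates, genotypes
    a fresh F2 mapping population at the designed markers plus the causal
    locus, and writes a map report.
    """
    cfg.validate()
    outdir = Path(outdir if outdir is not None else cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = StageLog()

    paths, (genome, hom, truth) = emit_fixture_bundle(cfg.simulation, outdir / "bundle", cfg.seed)
    log.add("simulate", genome.n_sites, genome.n_sites, "fixture bundle written")

    count_tables = {
        (bulk, ref): wio.read_count_table(paths[("counts", bulk, ref)])
        for bulk in BULK_NAMES
        for ref in (PARENT_A, PARENT_B)
    }
    tetraploid_tables = {
        ref: wio.read_count_table(paths[("tetraploid", ref)]) for ref in (PARENT_A, PARENT_B)
    }
    anchors = wio.read_anchor_table(paths["anchors"])
    pairwise = wio.read_pairwise_list(paths["pairwise"])
    flanks = {r["id"]: r for r in wio.read_flank_fasta(paths["flanks"])}

    frames = analyse_bundle(count_tables, tetraploid_tables, anchors, pairwise, cfg, log)
    nr, classified, delta, tracks = (
        frames["nr"], frames["classified"], frames["delta"], frames["tracks"],
    )

    # localization: Steel–Dwass over D-specific ΔSNP-index values per chromosome
    dsp = tracks[tracks["category"] == "Aet"]
    chrom_names = [c for c, _ in genome.chromosomes]
    groups = [dsp.loc[dsp["chrom"] == c, "avg_delta"].to_numpy() for c in chrom_names]
    usable = [(c, g) for c, g in zip(chrom_names, groups) if len(g) >= 2]
    sd = _stats.steel_dwass([g for _, g in usable], [c for c, _ in usable])

    # candidate region and marker design
    merged = delta.merge(classified[["chrom", "pos", "category"]], on=["chrom", "pos"])
    region = cfg.resolved_region()
    summary = _markers.filter_region(merged, region)
    candidates = _markers.select_candidates(summary.subset, cfg.min_delta)
    log.add("select_candidates", summary.n_sites, len(candidates),
            f"category=D_SPECIFIC avg_delta>{cfg.min_delta}")

    designed = []
    for _, row in candidates.iterrows():
        key = f"{row['chrom']}:{int(row['pos'])}"
        rec = flanks.get(key)
        if rec is None:
            continue
        meta = dict(kv.split("=") for kv in rec["description"].split())
        assays = _markers.design_dcaps(
            rec["seq"], int(meta["offset"]), meta["ref"], meta["alt"]
        )
        if assays:
            best = assays[0]
            best.site_key = key
            best.marker_name = f"bsa{len(designed) + 1}"
            designed.append(best)
        if len(designed) >= cfg.max_markers:
            break
    log.add("design_dcaps", len(candidates), len(designed), "validated by in-silico digestion")

    # linkage validation on a fresh F2 mapping population
    positions = [(m.site_key.split(":")[0], int(m.site_key.split(":")[1])) for m in designed]
    map_rows = []
    if positions:
        all_pos = positions + [genome.causal]
        f2 = _linkage.simulate_f2_genotypes(
            genome, all_pos, cfg.n_mapping_individuals,
            cfg.simulation.pedigree.crossover_mean, seed=np.random.SeedSequence([cfg.seed, 99]),
        )
        causal_col = f"{genome.causal[0]}:{genome.causal[1]}"
        for marker, (chrom, pos) in zip(designed, positions):
            col = f"{chrom}:{pos}"
            rf, lod = _linkage.two_point_rf(f2[col], f2[causal_col])
            map_rows.append(
                {
                    "marker": marker.marker_name, "chrom": chrom, "pos": pos,
                    "rf": rf, "lod": lod,
                    "cM_kosambi": _linkage.map_distance(min(rf, 0.499999), "kosambi"),
                }
            )
    marker_map = pd.DataFrame(map_rows)

    # artifacts
    wio.write_table(tracks, outdir / "tracks.tsv")
    wio.write_table(classified, outdir / "classified_sites.tsv")
    wio.write_table(delta, outdir / "delta_index.tsv")
    wio.write_table(sd, outdir / "steel_dwass.tsv")
    wio.write_sites_vcf(nr, outdir / "nr_sites.vcf", classified)
    wio.write_table(_markers.candidate_report(designed), outdir / "markers.tsv")
    if len(marker_map):
        wio.write_table(marker_map, outdir / "marker_map.tsv")
    tab = _tabulate(classified)
    tab.to_csv(outdir / "classification_by_chromosome.tsv", sep="\t")

    if cfg.figures:
        from . import plots

        plots.plot_delta_tracks(tracks, outdir / "tracks.png")
        plots.plot_chromosome_boxes(
            [g for _, g in usable], [c for c, _ in usable], outdir / "steel_dwass.png"
        )

    ku_totals = [frames["call_totals"][(b, PARENT_A)] for b in BULK_NAMES]
    report_lines = [
        f"seed: {cfg.seed}",
        f"sites simulated: {genome.n_sites}",
        f"non-redundant sites: {len(nr)}",
        f"mean called per bulk ({PARENT_A}): {mean_called_sites(ku_totals)}",
        "",
        tab.to_string(),
        "",
        f"candidate region {region.chrom}:{region.start_bp}-{region.end_bp}: "
        f"{summary.n_sites} sites {summary.category_counts} "
        f"delta range [{summary.delta_min:.4f}, {summary.delta_max:.4f}]",
        f"markers designed: {[m.marker_name for m in designed]}",
        "",
        log.as_text(),
    ]
    (outdir / "report.txt").write_text("\n".join(report_lines) + "\n")

    return PipelineResult(
        nr_sites=nr, classified=classified, delta=delta, tracks=tracks,
        steel_dwass=sd, region_summary=summary, candidates=candidates,
        markers=designed, marker_map=marker_map, log=log,
        call_totals=frames["call_totals"], truth=truth, genome=genome,
    )
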