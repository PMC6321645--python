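"""Synthetic-data generator for RNA-seq bulked segregant analysis (BSA) of a
synthetic hexaploid wheat cross.

The generator emulates the genetic and sampling structure that the downstream
analysis assumes, together with full ground truth, so that every stage of the
pipeline can be tested without sequencing data:

* two diploid D-genome parents ("parentA", the non-carrier reference analog,
  and "parentB", the donor of the selected allele) differing at SNP sites on
  up to seven chromosomes;
* a fixed tetraploid AB background whose homoeologous transcripts contaminate
  the read pool at a per-site rate ``rho`` and carry a fixed homoeologous base;
* selfing from the F1 with heterozygote selection at the causal locus through
  an intermediate generation, then two sibling F5 populations from two
  independent F4 heterozygotes, from each of which one bulk of
  carrier-homozygotes and one bulk of non-carriers is drawn;
* sequencing-depth sampling (negative binomial by default) with homoeologous
  contamination, yielding per-site total and alternate-allele read counts for
  each bulk x parental-reference alignment pair, plus pure-homoeolog count
  tables for the tetraploid (Langdon-analog) sample.

Coordinates are 1-based base pairs.  All randomness flows through
:class:`numpy.random.Generator` objects derived from an integer seed, so a
given seed reproduces byte-identical fixture bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PARENT_A",
    "PARENT_B",
    "BULK_NAMES",
    "GenomeConfig",
    "HomoeologConfig",
    "PedigreeConfig",
    "DepthModel",
    "SimulationConfig",
    "GenomeModel",
    "HomoeologModel",
    "SimTruth",
    "ConfigurationError",
    "SimulationError",
    "as_rng",
    "simulate_parents",
    "add_homoeology",
    "simulate_pedigree",
    "expected_homozygosity",
    "simulate_selfing_series",
    "sample_allele_counts",
    "simulate_tetraploid_counts",
    "emit_fixture_bundle",
]

PARENT_A = "parentA"  #: non-donor parent (KU-2075 analog), wild-type allele source
PARENT_B = "parentB"  #: donor parent (KU-2025 analog), carries the selected allele

#: bulk names: carrier/non-carrier x sibling population
BULK_NAMES = ("carrier-SP1", "noncarrier-SP1", "carrier-SP2", "noncarrier-SP2")

_BASES = np.array(["A", "C", "G", "T"])


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class SimulationError(RuntimeError):
    """The pedigree simulation could not satisfy a selection requirement."""


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GenomeConfig:
    """Layout of the simulated D genome.

    ``allelic_sites_per_chromosome`` may be an int (same count everywhere) or a
    mapping chromosome-name -> count; likewise ``homoeolog_sites_per_chromosome``.
    Defaults give 3,000 observable transcript sites per chromosome of which
    ~5.7% are parent-divergent, mirroring the composition of a real bulk call
    set in an allopolyploid background.
    """

    chromosomes: tuple = tuple((f"{i}D", 150_000_000) for i in range(1, 8))
    allelic_sites_per_chromosome: object = 170
    homoeolog_sites_per_chromosome: object = 2830
    causal_chrom: str = "2D"
    causal_pos: int = 82_500_000

    def n_allelic(self, chrom: str) -> int:
        return _per_chrom(self.allelic_sites_per_chromosome, chrom)

    def n_homoeolog(self, chrom: str) -> int:
        return _per_chrom(self.homoeolog_sites_per_chromosome, chrom)

    def validate(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if not 1 <= len(names) <= 7:
            raise ConfigurationError("expected between 1 and 7 chromosomes")
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ConfigurationError(f"chromosome {name} has non-positive length")
        if self.causal_chrom not in names:
            raise ConfigurationError(f"causal chromosome {self.causal_chrom!r} not in genome")
        if self.n_allelic(self.causal_chrom) < 1:
            raise ConfigurationError("causal chromosome must carry at least one allelic SNP site")
        length = dict(self.chromosomes)[self.causal_chrom]
        if not 1 <= self.causal_pos <= length:
            raise ConfigurationError("causal position outside its chromosome")


def _per_chrom(value, chrom: str) -> int:
    if isinstance(value, dict):
        return int(value.get(chrom, 0))
    return int(value)


@dataclass
class HomoeologConfig:
    """Homoeologous contamination model parameters.

    rho (the probability that a read at the site comes from an A/B-genome
    homoeolog) is drawn per contaminated site from Beta(rho_alpha, rho_beta),
    producing the site-to-site variability responsible for the discontinuous
    dilution of SNP-index values.  ``allelic_contact_fraction`` is the fraction
    of parent-divergent sites whose homoeolog cross-aligns at all;
    ``tetraploid_expressed_fraction`` is the fraction of contaminated sites
    detectably expressed in the tetraploid control sample.
    """

    rho_alpha: float = 2.0
    rho_beta: float = 5.0
    allelic_contact_fraction: float = 0.3
    tetraploid_expressed_fraction: float = 0.7
    third_base_fraction: float = 0.1


@dataclass
class PedigreeConfig:
    """Selfing-pedigree layout (generation 1 = F1)."""

    final_generation: int = 5
    select_het_at_causal_through: int = 4
    bulk_size: int = 10
    n_sibling_populations: int = 2
    crossover_mean: float = 1.0  # Poisson mean crossovers per chromosome per gamete
    max_tries: int = 10_000

    def validate(self) -> None:
        if self.final_generation < 2:
            raise ConfigurationError("final_generation must be >= 2")
        if self.bulk_size < 1:
            raise ConfigurationError("bulk_size must be >= 1")
        if self.n_sibling_populations < 1:
            raise ConfigurationError("need at least one sibling population")


@dataclass
class DepthModel:
    """Per-site sequencing depth: negative binomial with mean ``mean`` and
    dispersion ``dispersion`` (variance mean + mean^2/dispersion); ``dispersion
    = inf`` degenerates to Poisson."""

    mean: float = 30.0
    dispersion: float = 5.0

    def sample(self, rng: np.random.Generator, n: int, mean=None) -> np.ndarray:
        mu = np.broadcast_to(np.asarray(self.mean if mean is None else mean, dtype=float), (n,))
        if not np.isfinite(self.dispersion):
            return rng.poisson(mu)
        lam = rng.gamma(self.dispersion, mu / self.dispersion)
        return rng.poisson(lam)


@dataclass
class SimulationConfig:
    """Everything needed to generate one full fixture bundle."""

    genome: GenomeConfig = field(default_factory=GenomeConfig)
    homoeolog: HomoeologConfig = field(default_factory=HomoeologConfig)
    pedigree: PedigreeConfig = field(default_factory=PedigreeConfig)
    depth: DepthModel = field(default_factory=DepthModel)
    tetraploid_depth: DepthModel = field(default_factory=DepthModel)
    donor_parent: str = PARENT_B
    pairwise_detection: float = 0.98   # fraction of allelic sites present in the pairwise list
    unanchored_fraction: float = 0.007  # fraction of sites missing from the anchor table
    flank_length: int = 60


# ---------------------------------------------------------------------------
# domain models
# ---------------------------------------------------------------------------

@dataclass
class GenomeModel:
    """Genome-anchored site catalogue.

    ``sites`` columns: chrom, pos, kind ("allelic" | "homoeolog"), parent_a,
    parent_b, transcript_id, transcript_pos, strand.  Positions are strictly
    increasing within each chromosome; allelic sites have distinct parental
    bases, homoeolog sites identical ones.
    """

    chromosomes: list
    sites: pd.DataFrame
    causal: tuple  # (chrom, pos)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def chromosome_length(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    def sites_on(self, chrom: str) -> pd.DataFrame:
        return self.sites[self.sites["chrom"] == chrom]

    def parent_base(self, parent: str) -> np.ndarray:
        if parent == PARENT_A:
            return self.sites["parent_a"].to_numpy()
        if parent == PARENT_B:
            return self.sites["parent_b"].to_numpy()
        raise ValueError(f"unknown parent label {parent!r}")

    def equals(self, other: "GenomeModel") -> bool:
        return (
            self.chromosomes == other.chromosomes
            and self.causal == other.causal
            and self.sites.equals(other.sites)
        )


@dataclass
class HomoeologModel:
    """Per-site homoeologous-read model, aligned row-for-row with
    ``GenomeModel.sites``: contamination probability ``rho``, the base carried
    by homoeologous reads, and whether the homoeolog is detectably expressed
    in the tetraploid control sample."""

    rho: np.ndarray
    homoeolog_base: np.ndarray
    tetraploid_expressed: np.ndarray

    def __post_init__(self):
        rho = np.asarray(self.rho, dtype=float)
        if rho.size and (rho.min() < 0 or rho.max() > 1):
            raise ValueError("rho must lie in [0, 1]")
        self.rho = rho
        self.homoeolog_base = np.asarray(self.homoeolog_base)
        self.tetraploid_expressed = np.asarray(self.tetraploid_expressed, dtype=bool)

    def matches_reference(self, genome: GenomeModel, reference_parent: str) -> np.ndarray:
        """Boolean per site: homoeologous reads carry the reference-transcript base."""
        return self.homoeolog_base == genome.parent_base(reference_parent)


@dataclass
class SimTruth:
    """Ground truth for one simulated BSA experiment.

    * ``bulk_membership``: DataFrame (bulk, individual, causal_genotype) where
      the genotype is the donor-allele dosage (0/1/2) at the causal locus;
    * ``true_allele_freq``: DataFrame indexed like ``genome.sites`` with one
      column per bulk holding the donor-parent allele frequency among the
      2 x bulk_size bulk chromosomes;
    * ``site_truth``: per-site truth used to score classification — kind, rho,
      tetraploid_expressed, in_pairwise (membership in the emitted parental
      pairwise list) and the implied truth category;
    * ``individuals``: dict bulk -> list of haplotype dicts
      (chrom -> (2, n_sites_on_chrom) donor-origin arrays) plus the key
      "_causal" -> (2,) origins at the causal locus, for marker genotyping.
    """

    bulk_membership: pd.DataFrame
    true_allele_freq: pd.DataFrame
    site_truth: pd.DataFrame
    individuals: dict
    seed: int

    def bulk_frequency(self, bulk: str) -> np.ndarray:
        return self.true_allele_freq[bulk].to_numpy()


# ---------------------------------------------------------------------------
# parents & homoeology
# ---------------------------------------------------------------------------

def simulate_parents(config: GenomeConfig, seed) -> GenomeModel:
    """Draw the parent-divergent (allelic) SNP catalogue.

    Every site is biallelic with distinct parentA/parentB bases; positions are
    uniform without replacement on each chromosome and strictly increasing.
    Deterministic under a seed.
    """
    config.validate()
    rng = as_rng(seed)
    frames = []
    for chrom, length in config.chromosomes:
        n = config.n_allelic(chrom)
        if n < 0:
            raise ConfigurationError("negative site count")
        if n == 0:
            continue
        if n > length:
            raise ConfigurationError(f"more sites than base pairs on {chrom}")
        pos = np.sort(rng.choice(length, size=n, replace=False)) + 1
        a_idx = rng.integers(0, 4, size=n)
        b_idx = (a_idx + rng.integers(1, 4, size=n)) % 4  # always != a_idx
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "kind": "allelic",
                    "parent_a": _BASES[a_idx],
                    "parent_b": _BASES[b_idx],
                }
            )
        )
    sites = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "pos", "kind", "parent_a", "parent_b"])
    )
    sites = _assign_transcripts(sites, rng)
    return GenomeModel(list(config.chromosomes), sites, (config.causal_chrom, config.causal_pos))


def add_homoeology(
    genome: GenomeModel, genome_cfg: GenomeConfig, hom_cfg: HomoeologConfig, seed
):
    """Overlay the tetraploid-background model.

    Adds homoeolog-divergent sites (identical parental bases, divergent
    homoeologous base) to the catalogue and assigns every site a contamination
    rate rho, a homoeologous base, and a tetraploid-expression flag.  Returns
    the augmented :class:`GenomeModel` and the :class:`HomoeologModel`.
    """
    rng = as_rng(seed)
    frames = [genome.sites[["chrom", "pos", "kind", "parent_a", "parent_b"]]]
    for chrom, length in genome.chromosomes:
        n = genome_cfg.n_homoeolog(chrom)
        if n == 0:
            continue
        taken = set(genome.sites_on(chrom)["pos"].tolist())
        pos = rng.choice(length, size=min(n + len(taken), length), replace=False) + 1
        pos = np.sort(np.array([p for p in pos if p not in taken][:n], dtype=np.int64))
        base = _BASES[rng.integers(0, 4, size=len(pos))]
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "kind": "homoeolog",
                 "parent_a": base, "parent_b": base}
            )
        )
    sites = pd.concat(frames, ignore_index=True)
    chrom_order = {c: i for i, (c, _) in enumerate(genome.chromosomes)}
    sites = (
        sites.assign(_o=sites["chrom"].map(chrom_order))
        .sort_values(["_o", "pos"], kind="mergesort")
        .drop(columns="_o")
        .reset_index(drop=True)
    )
    sites = _assign_transcripts(sites, rng)

    n = len(sites)
    allelic = (sites["kind"] == "allelic").to_numpy()
    rho = np.zeros(n)
    contaminated = ~allelic | (rng.random(n) < hom_cfg.allelic_contact_fraction)
    rho[contaminated] = rng.beta(hom_cfg.rho_alpha, hom_cfg.rho_beta, size=int(contaminated.sum()))

    parent_a = sites["parent_a"].to_numpy()
    parent_b = sites["parent_b"].to_numpy()
    hbase = parent_a.copy()  # placeholder at uncontaminated allelic sites
    # homoeolog-divergent sites: any base other than the shared parental base
    hom = ~allelic
    shift = rng.integers(1, 4, size=n)
    base_idx = np.searchsorted(_BASES, parent_a)
    hbase[hom] = _BASES[(base_idx[hom] + shift[hom]) % 4]
    # contaminated allelic sites: homoeolog carries one parent's base, or a third base
    ca = allelic & contaminated
    third = ca & (rng.random(n) < hom_cfg.third_base_fraction)
    pick_b = ca & ~third & (rng.random(n) < 0.5)
    hbase[ca] = parent_a[ca]
    hbase[pick_b] = parent_b[pick_b]
    for i in np.flatnonzero(third):
        choices = [b for b in _BASES if b not in (parent_a[i], parent_b[i])]
        hbase[i] = choices[rng.integers(0, len(choices))]

    expressed = contaminated & (rng.random(n) < hom_cfg.tetraploid_expressed_fraction)
    model = HomoeologModel(rho=rho, homoeolog_base=hbase, tetraploid_expressed=expressed)
    return GenomeModel(genome.chromosomes, sites, genome.causal), model


def _assign_transcripts(sites: pd.DataFrame, rng: np.random.Generator,
                        sites_per_transcript: int = 8) -> pd.DataFrame:
    """Group consecutive sites into synthetic transcripts and assign
    transcript-local 1-based coordinates; transcripts get a random strand and
    minus-strand transcripts enumerate positions in reverse."""
    sites = sites.reset_index(drop=True).copy()
    tx_id = np.empty(len(sites), dtype=object)
    tx_pos = np.zeros(len(sites), dtype=np.int64)
    strand = np.empty(len(sites), dtype=object)
    for chrom, idx in sites.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        for t, start in enumerate(range(0, len(idx), sites_per_transcript)):
            block = idx[start : start + sites_per_transcript]
            name = f"tx_{chrom}_{t:05d}"
            s = "+" if rng.random() < 0.5 else "-"
            offsets = 50 + 37 * np.arange(len(block))
            if s == "-":
                offsets = offsets[::-1]
            tx_id[block] = name
            tx_pos[block] = offsets
            strand[block] = s
    sites["transcript_id"] = tx_id
    sites["transcript_pos"] = tx_pos
    sites["strand"] = strand
    return sites


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def expected_homozygosity(generation: int) -> float:
    """Per-locus probability of homozygosity after selfing from an F1
    heterozygote with no selection: 1 - (1/2)**(generation - 1).

    F1 (generation 1) is fully heterozygous; each selfing halves the expected
    heterozygosity, so an F4 individual is homozygous over 87.5% of its genome.
    """
    if generation < 1:
        raise ValueError("generation must be >= 1 (F1)")
    return 1.0 - 0.5 ** (generation - 1)


def _gamete(rng, positions: np.ndarray, length: int, hap: np.ndarray,
            crossover_mean: float) -> np.ndarray:
    """One meiotic product evaluated at ``positions`` (sorted bp).

    Crossover count is Poisson(crossover_mean) with breakpoints uniform on the
    chromosome (Haldane: no interference); the starting chromatid is random.
    ``hap`` has shape (2, len(positions)).
    """
    k = rng.poisson(crossover_mean)
    phase = rng.integers(0, 2)
    if k == 0:
        return hap[phase].copy()
    breaks = np.sort(rng.uniform(0, length, size=k))
    which = (phase + np.searchsorted(breaks, positions)) % 2
    return np.where(which == 0, hap[0], hap[1])


class _Pedigree:
    """Helper binding a genome's evaluation positions (site positions plus the
    causal locus appended per chromosome where absent)."""

    def __init__(self, genome: GenomeModel, crossover_mean: float):
        self.genome = genome
        self.crossover_mean = crossover_mean
        self.positions = {}
        self.site_slice = {}
        self.causal_index = None
        c_chrom, c_pos = genome.causal
        for chrom, length in genome.chromosomes:
            pos = genome.sites_on(chrom)["pos"].to_numpy()
            if chrom == c_chrom:
                if c_pos in pos:
                    full, causal_i = pos, int(np.searchsorted(pos, c_pos))
                else:
                    causal_i = int(np.searchsorted(pos, c_pos))
                    full = np.insert(pos, causal_i, c_pos)
                self.positions[chrom] = full
                self.site_slice[chrom] = np.setdiff1d(
                    np.arange(len(full)), [] if c_pos in pos else [causal_i]
                )
                self.causal_index = (chrom, causal_i)
            else:
                self.positions[chrom] = pos
                self.site_slice[chrom] = np.arange(len(pos))

    def f1(self) -> dict:
        ind = {
            chrom: np.vstack([np.zeros(len(p), dtype=np.uint8), np.ones(len(p), dtype=np.uint8)])
            for chrom, p in self.positions.items()
        }
        return ind

    def self_offspring(self, rng, parent: dict) -> dict:
        child = {}
        lengths = dict(self.genome.chromosomes)
        for chrom, pos in self.positions.items():
            g1 = _gamete(rng, pos, lengths[chrom], parent[chrom], self.crossover_mean)
            g2 = _gamete(rng, pos, lengths[chrom], parent[chrom], self.crossover_mean)
            child[chrom] = np.vstack([g1, g2])
        return child

    def causal_genotype(self, ind: dict) -> int:
        chrom, i = self.causal_index
        return int(ind[chrom][0, i]) + int(ind[chrom][1, i])

    def site_haplotypes(self, ind: dict) -> dict:
        """Donor-origin arrays restricted to catalogue sites, causal dropped if virtual."""
        out = {c: ind[c][:, self.site_slice[c]] for c in self.positions}
        chrom, i = self.causal_index
        out["_causal"] = ind[chrom][:, i].copy()
        return out


def _select_offspring(rng, ped: _Pedigree, parent: dict, genotype: int, max_tries: int) -> dict:
    for _ in range(max_tries):
        child = ped.self_offspring(rng, parent)
        if ped.causal_genotype(child) == genotype:
            return child
    raise SimulationError(
        f"no offspring with causal genotype {genotype} found in {max_tries} draws"
    )


def simulate_pedigree(genome: GenomeModel, cfg: PedigreeConfig, seed) -> SimTruth:
    """Run the selfing pedigree and bulk selection; return ground truth.

    From the F1, a single heterozygote (at the causal locus) is carried through
    each generation up to ``select_het_at_causal_through``; the next generation
    is founded by ``n_sibling_populations`` independent heterozygous siblings;
    from each sibling population at ``final_generation``, one bulk of
    ``bulk_size`` carrier-homozygotes and one of non-carriers is drawn.
    """
    cfg.validate()
    if cfg.select_het_at_causal_through >= cfg.final_generation:
        raise ConfigurationError("heterozygote selection must stop before the final generation")
    rng = as_rng(seed)
    seed_int = seed if isinstance(seed, (int, np.integer)) else -1
    ped = _Pedigree(genome, cfg.crossover_mean)

    parent = ped.f1()
    if cfg.select_het_at_causal_through <= 1:
        # no selection: every population descends from the F1 itself
        founders = [parent for _ in range(cfg.n_sibling_populations)]
    else:
        # single-seed descent with heterozygote selection: F2 .. F_(through-1)
        for _gen in range(2, cfg.select_het_at_causal_through):
            parent = _select_offspring(rng, ped, parent, 1, cfg.max_tries)
        # the F_through generation: independent heterozygous siblings found the populations
        founders = [
            _select_offspring(rng, ped, parent, 1, cfg.max_tries)
            for _ in range(cfg.n_sibling_populations)
        ]
    # self each founder (without selection) down to the final generation - 1
    for _gen in range(max(cfg.select_het_at_causal_through, 1) + 1, cfg.final_generation):
        founders = [ped.self_offspring(rng, f) for f in founders]

    individuals: dict = {}
    rows = []
    for p, founder in enumerate(founders, start=1):
        quotas = {2: [], 0: []}
        for _ in range(cfg.max_tries):
            child = ped.self_offspring(rng, founder)
            g = ped.causal_genotype(child)
            if g in quotas and len(quotas[g]) < cfg.bulk_size:
                quotas[g].append(child)
            if all(len(v) == cfg.bulk_size for v in quotas.values()):
                break
        else:
            raise SimulationError(
                f"could not fill bulks for population SP{p} within {cfg.max_tries} draws"
            )
        for geno, name in ((2, f"carrier-SP{p}"), (0, f"noncarrier-SP{p}")):
            members = quotas[geno]
            individuals[name] = [ped.site_haplotypes(m) for m in members]
            for i, m in enumerate(members):
                rows.append({"bulk": name, "individual": i, "causal_genotype": ped.causal_genotype(m)})

    freq = {}
    chroms = [c for c, _ in genome.chromosomes]
    for bulk, members in individuals.items():
        stacked = np.concatenate(
            [np.concatenate([m[c] for c in chroms], axis=1) for m in members], axis=0
        )
        freq[bulk] = stacked.mean(axis=0)
    true_allele_freq = pd.DataFrame(freq)

    site_truth = genome.sites[["chrom", "pos", "kind"]].copy()
    return SimTruth(
        bulk_membership=pd.DataFrame(rows),
        true_allele_freq=true_allele_freq,
        site_truth=site_truth,
        individuals=individuals,
        seed=int(seed_int),
    )


def simulate_selfing_series(n_loci: int, generation: int, n_individuals: int, seed,
                            crossover_mean: float = 1.0, n_chromosomes: int = 7):
    """Selfing without selection: fraction of homozygous loci per individual.

    Loci are spread uniformly over ``n_chromosomes`` chromosomes of unit
    length; returns an array of per-individual homozygous fractions at
    generation ``generation`` (F1 = 1).  Serves as the Monte-Carlo oracle for
    :func:`expected_homozygosity`.
    """
    if generation < 1:
        raise ValueError("generation must be >= 1")
    rng = as_rng(seed)
    per = np.array_split(np.arange(n_loci), n_chromosomes)
    positions = [np.sort(rng.uniform(0, 1, size=len(p))) for p in per]
    fractions = np.empty(n_individuals)
    for i in range(n_individuals):
        haps = [
            np.vstack([np.zeros(len(p), dtype=np.uint8), np.ones(len(p), dtype=np.uint8)])
            for p in positions
        ]
        for _gen in range(2, generation + 1):
            haps = [
                np.vstack(
                    [_gamete(rng, p, 1.0, h, crossover_mean), _gamete(rng, p, 1.0, h, crossover_mean)]
                )
                for p, h in zip(positions, haps)
            ]
        hom = [h[0] == h[1] for h in haps]
        fractions[i] = np.concatenate(hom).mean() if n_loci else np.nan
    return fractions


# ---------------------------------------------------------------------------
# read-count sampling
# ---------------------------------------------------------------------------

def _alt_base(genome: GenomeModel, homoeolog: HomoeologModel, reference_parent: str) -> np.ndarray:
    """Canonical alternate base per site for an alignment against one parental
    reference: the other parent's base at allelic sites, the homoeologous base
    at homoeolog-divergent sites."""
    a = genome.sites["parent_a"].to_numpy()
    b = genome.sites["parent_b"].to_numpy()
    allelic = (genome.sites["kind"] == "allelic").to_numpy()
    other = b if reference_parent == PARENT_A else a
    return np.where(allelic, other, homoeolog.homoeolog_base)


def sample_allele_counts(
    truth: SimTruth,
    genome: GenomeModel,
    homoeolog: HomoeologModel,
    bulk: str,
    reference_parent: str,
    depth_model: DepthModel,
    seed,
) -> pd.DataFrame:
    """Sample one bulk x reference count table.

    Each of the D reads at a site is homoeologous with probability rho (its
    base fixed by the homoeolog model), otherwise it is drawn from a bulk
    chromosome at the bulk's true donor-allele frequency.  The alternate depth
    counts reads carrying the base that differs from the reference parent's
    transcript base.  Sites with zero depth are kept (D = K = 0); downstream
    calling filters them.
    """
    if reference_parent not in (PARENT_A, PARENT_B):
        raise ValueError(f"unknown reference parent {reference_parent!r}")
    rng = as_rng(seed)
    n = genome.n_sites
    f_donor = truth.bulk_frequency(bulk)
    depth = depth_model.sample(rng, n)
    k_hom = rng.binomial(depth, homoeolog.rho)
    d_dip = depth - k_hom
    k_donor = rng.binomial(d_dip, f_donor)

    ref = genome.parent_base(reference_parent)
    alt = _alt_base(genome, homoeolog, reference_parent)
    donor_base = genome.parent_base(PARENT_B)
    nondonor_base = genome.parent_base(PARENT_A)
    k_alt = (
        k_donor * (donor_base == alt)
        + (d_dip - k_donor) * (nondonor_base == alt)
        + k_hom * (homoeolog.homoeolog_base == alt)
    )
    return _as_count_table(genome, ref, alt, depth, k_alt)


def simulate_tetraploid_counts(
    homoeolog: HomoeologModel,
    genome: GenomeModel,
    depth_model: DepthModel,
    reference_parent: str,
    seed,
) -> pd.DataFrame:
    """Count table for the tetraploid (AB-only) control sample.

    Reads are purely homoeologous: coverage exists only where the homoeolog is
    expressed and cross-aligns (rho > 0), and every read carries the
    homoeologous base, so K = D wherever that base differs from the reference
    and K = 0 where it matches.
    """
    if reference_parent not in (PARENT_A, PARENT_B):
        raise ValueError(f"unknown reference parent {reference_parent!r}")
    rng = as_rng(seed)
    n = genome.n_sites
    covered = (homoeolog.rho > 0) & homoeolog.tetraploid_expressed
    depth = np.where(covered, depth_model.sample(rng, n), 0)
    ref = genome.parent_base(reference_parent)
    alt = _alt_base(genome, homoeolog, reference_parent)
    k_alt = np.where(homoeolog.homoeolog_base != ref, depth, 0)
    return _as_count_table(genome, ref, alt, depth, k_alt)


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _as_count_table(genome, ref, alt, depth, k_alt) -> pd.DataFrame:
    """Assemble the tab-separated count-table dialect, in transcript
    orientation (bases complemented for minus-strand transcripts); genome
    coordinates are withheld ('.'/0) — anchoring restores them."""
    minus = (genome.sites["strand"] == "-").to_numpy()
    comp = np.vectorize(_COMPLEMENT.get)
    ref_t = np.where(minus, comp(ref), ref) if len(ref) else ref
    alt_t = np.where(minus, comp(alt), alt) if len(alt) else alt
    return pd.DataFrame(
        {
            "chrom": ".",
            "pos": 0,
            "transcript_id": genome.sites["transcript_id"].to_numpy(),
            "transcript_pos": genome.sites["transcript_pos"].to_numpy(),
            "ref_base": ref_t,
            "alt_base": alt_t,
            "depth": np.asarray(depth, dtype=np.int64),
            "alt_depth": np.asarray(k_alt, dtype=np.int64),
        }
    )


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def _derive_truth_categories(truth: SimTruth, homoeolog: HomoeologModel,
                             in_pairwise: np.ndarray) -> None:
    """Attach evidence-truth flags and the implied category to site_truth."""
    tet = (homoeolog.rho > 0) & homoeolog.tetraploid_expressed
    st = truth.site_truth
    st["rho"] = homoeolog.rho
    st["tetraploid_expressed"] = homoeolog.tetraploid_expressed
    st["in_pairwise"] = in_pairwise
    category = np.where(tet, "HOMOEOLOGOUS", np.where(in_pairwise, "D_SPECIFIC", "UNCLASSIFIED"))
    st["truth_category"] = category


def build_scenario(config: SimulationConfig, seed):
    """Simulate parents, homoeology and the pedigree; returns
    (genome, homoeolog_model, truth) with truth categories attached."""
    ss = np.random.SeedSequence(seed)
    s_par, s_hom, s_ped, s_pw = ss.spawn(4)
    genome = simulate_parents(config.genome, np.random.default_rng(s_par))
    genome, hom = add_homoeology(genome, config.genome, config.homoeolog,
                                 np.random.default_rng(s_hom))
    truth = simulate_pedigree(genome, config.pedigree, np.random.default_rng(s_ped))
    truth.seed = int(seed) if isinstance(seed, (int, np.integer)) else -1
    rng = np.random.default_rng(s_pw)
    allelic = (genome.sites["kind"] == "allelic").to_numpy()
    in_pairwise = allelic & (rng.random(genome.n_sites) < config.pairwise_detection)
    _derive_truth_categories(truth, hom, in_pairwise)
    return genome, hom, truth


def emit_fixture_bundle(config: SimulationConfig, outdir, seed):
    """Generate and write a complete fixture bundle; returns (paths, truth).

    Files written (all plain text, readable by :mod:`wheatbsa.io`):
    eight bulk x reference count tables, two tetraploid count tables, the
    parental pairwise SNP list, the transcript->genome anchor table (with a
    configured fraction of sites withheld), flanking sequences for marker
    design (FASTA, 2-line records) and the JSON/TSV ground truth.
    """
    from . import io as wio  # local import: io depends on nothing here
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, hom, truth = build_scenario(config, seed)
    ss = np.random.SeedSequence([int(seed), 1])
    counters = ss.spawn(12 + 2)

    paths = {}
    i = 0
    for bulk in BULK_NAMES:
        for ref in (PARENT_A, PARENT_B):
            table = sample_allele_counts(
                truth, genome, hom, bulk, ref, config.depth, np.random.default_rng(counters[i])
            )
            p = outdir / f"counts_{bulk}_{ref}.tsv"
            wio.write_count_table(table, p)
            paths[("counts", bulk, ref)] = p
            i += 1
    for ref in (PARENT_A, PARENT_B):
        table = simulate_tetraploid_counts(
            hom, genome, config.tetraploid_depth, ref, np.random.default_rng(counters[i])
        )
        p = outdir / f"counts_tetraploid_{ref}.tsv"
        wio.write_count_table(table, p)
        paths[("tetraploid", ref)] = p
        i += 1

    anchors = build_anchor_table(genome, config.unanchored_fraction,
                                 np.random.default_rng(counters[i])); i += 1
    paths["anchors"] = outdir / "anchors.tsv"
    wio.write_anchor_table(anchors, paths["anchors"])

    pairwise = pairwise_snp_list(genome, truth)
    paths["pairwise"] = outdir / "pairwise_snps.tsv"
    wio.write_pairwise_list(pairwise, paths["pairwise"])

    flanks = flank_records(genome, config.flank_length, np.random.default_rng(counters[i])); i += 1
    paths["flanks"] = outdir / "flanks.fasta"
    wio.write_flank_fasta(flanks, paths["flanks"])

    paths["truth"] = outdir / "truth.json"
    wio.write_truth(truth, genome, paths["truth"])
    return paths, (genome, hom, truth)


def build_anchor_table(genome: GenomeModel, unanchored_fraction: float,
                       rng) -> pd.DataFrame:
    """Transcript->genome anchoring table; exactly round(f * N) sites are
    withheld to emulate transcripts that fail to map."""
    rng = as_rng(rng)
    tab = genome.sites[["transcript_id", "transcript_pos", "chrom", "pos", "strand"]].copy()
    n_drop = int(round(unanchored_fraction * len(tab)))
    if n_drop:
        drop = rng.choice(len(tab), size=n_drop, replace=False)
        tab = tab.drop(index=tab.index[drop])
    return tab.reset_index(drop=True)


def pairwise_snp_list(genome: GenomeModel, truth: SimTruth) -> pd.DataFrame:
    """The parental-pairwise SNP list as a prior study would supply it:
    transcript coordinates against the parentA transcriptome."""
    mask = truth.site_truth["in_pairwise"].to_numpy()
    sub = genome.sites.loc[mask, ["transcript_id", "transcript_pos", "parent_a", "parent_b"]]
    minus = (genome.sites.loc[mask, "strand"] == "-").to_numpy()
    comp = np.vectorize(_COMPLEMENT.get)
    ref = sub["parent_a"].to_numpy()
    alt = sub["parent_b"].to_numpy()
    if len(sub):
        ref = np.where(minus, comp(ref), ref)
        alt = np.where(minus, comp(alt), alt)
    return pd.DataFrame(
        {
            "transcript_id": sub["transcript_id"].to_numpy(),
            "transcript_pos": sub["transcript_pos"].to_numpy(),
            "ref_base": ref,
            "alt_base": alt,
        }
    )


def flank_records(genome: GenomeModel, flank_length: int, rng) -> list:
    """Random flanking sequences around every allelic site (genome strand,
    parentA base shown at the SNP); metadata in the FASTA description."""
    rng = as_rng(rng)
    records = []
    allelic = genome.sites[genome.sites["kind"] == "allelic"]
    for _, row in allelic.iterrows():
        seq = rng.choice(_BASES, size=2 * flank_length + 1)
        seq[flank_length] = row["parent_a"]
        records.append(
            {
                "id": f"{row['chrom']}:{row['pos']}",
                "description": f"offset={flank_length} ref={row['parent_a']} alt={row['parent_b']}",
                "seq": "".join(seq),
            }
        )
    return records
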