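"""Genetic-map validation on simulated data.

Closes the loop on a synthetic experiment: genotype simulated individuals at
selected marker positions and at the causal locus, estimate the two-point
recombination fraction by maximum likelihood (EM over the F2 two-locus
genotype classes), and convert it to map distance with the Haldane or
Kosambi function.

Genotypes are donor-allele dosages 0/1/2 with -1 for missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import GenomeModel, SimTruth, as_rng, _gamete

__all__ = [
    "genotype_population",
    "simulate_f2_genotypes",
    "two_point_rf",
    "map_distance",
    "GENOTYPE_CODES",
]

#: dosage -> conventional two-letter code
GENOTYPE_CODES = {0: "AA", 1: "AB", 2: "BB", -1: "missing"}


def _marker_index(genome: GenomeModel, marker_positions):
    """Resolve (chrom, pos) markers to catalogue indices within chromosomes."""
    resolved = []
    for chrom, pos in marker_positions:
        if chrom not in dict(genome.chromosomes):
            raise ValueError(f"marker chromosome {chrom!r} not in genome")
        on = genome.sites_on(chrom)
        hits = np.flatnonzero(on["pos"].to_numpy() == pos)
        if len(hits) == 0:
            raise ValueError(f"no catalogued site at {chrom}:{pos}")
        resolved.append((chrom, int(hits[0])))
    return resolved


def genotype_population(
    truth: SimTruth,
    genome: GenomeModel,
    marker_positions,
    missing_rate: float = 0.0,
    seed=0,
) -> pd.DataFrame:
    """Read genotypes of every bulked individual at the given markers.

    ``marker_positions`` is a list of (chrom, pos) site coordinates or the
    string ``"causal"``.  Returns a DataFrame (one row per individual) with a
    ``bulk`` column and one dosage column per marker; a positive
    ``missing_rate`` masks genotypes to -1 at random (deterministic under
    ``seed``).
    """
    rng = as_rng(seed)
    site_markers = [m for m in marker_positions if m != "causal"]
    resolved = _marker_index(genome, site_markers)
    it = iter(resolved)
    cols = []
    for m in marker_positions:
        cols.append("causal" if m == "causal" else next(it))

    rows = []
    for bulk, members in truth.individuals.items():
        for i, member in enumerate(members):
            rec = {"bulk": bulk, "individual": i}
            for m, col in zip(marker_positions, cols):
                if col == "causal":
                    g = int(member["_causal"].sum())
                    name = "causal"
                else:
                    chrom, idx = col
                    g = int(member[chrom][:, idx].sum())
                    name = f"{m[0]}:{m[1]}"
                if missing_rate and rng.random() < missing_rate:
                    g = -1
                rec[name] = g
            rows.append(rec)
    return pd.DataFrame(rows)


def simulate_f2_genotypes(
    genome: GenomeModel,
    positions,
    n_individuals: int,
    crossover_mean: float = 1.0,
    seed=0,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate an F2 mapping population genotyped at arbitrary bp positions.

    ``positions`` is a list of (chrom, pos-bp); positions need not be
    catalogued sites.  Each F2 individual is the union of two independent F1
    gametes (Haldane crossovers, Poisson(crossover_mean) per chromosome).
    Returns a DataFrame of donor-allele dosages, one column per position.
    """
    rng = as_rng(seed)
    lengths = dict(genome.chromosomes)
    by_chrom: dict = {}
    for chrom, pos in positions:
        if chrom not in lengths:
            raise ValueError(f"position on unknown chromosome {chrom!r}")
        if not 1 <= pos <= lengths[chrom]:
            raise ValueError(f"position {chrom}:{pos} outside chromosome")
        by_chrom.setdefault(chrom, []).append(pos)
    eval_pos = {c: np.sort(np.asarray(p)) for c, p in by_chrom.items()}

    data = {f"{c}:{p}": np.empty(n_individuals, dtype=np.int8) for c, p in positions}
    for i in range(n_individuals):
        for chrom, pos_arr in eval_pos.items():
            f1 = np.vstack(
                [np.zeros(len(pos_arr), dtype=np.uint8), np.ones(len(pos_arr), dtype=np.uint8)]
            )
            g1 = _gamete(rng, pos_arr, lengths[chrom], f1, crossover_mean)
            g2 = _gamete(rng, pos_arr, lengths[chrom], f1, crossover_mean)
            dosage = g1 + g2
            for p, g in zip(pos_arr, dosage):
                data[f"{chrom}:{p}"][i] = g
    df = pd.DataFrame(data)
    if missing_rate:
        mask = rng.random(df.shape) < missing_rate
        df = df.mask(mask, -1).astype(np.int8)
    return df


# F2 two-locus: expected recombinant gametes per genotype class (EM targets);
# the double heterozygote is a phase mixture handled inside the loop.
_REC_COUNT = {
    (0, 0): 0, (0, 1): 1, (0, 2): 2,
    (1, 0): 1, (1, 2): 1,
    (2, 0): 2, (2, 1): 1, (2, 2): 0,
}


def _class_probs(r: float) -> dict:
    q = {}
    q[(0, 0)] = q[(2, 2)] = (1 - r) ** 2 / 4
    q[(0, 2)] = q[(2, 0)] = r**2 / 4
    q[(0, 1)] = q[(1, 0)] = q[(1, 2)] = q[(2, 1)] = r * (1 - r) / 2
    q[(1, 1)] = ((1 - r) ** 2 + r**2) / 2
    return q


def two_point_rf(genotypes_a, genotypes_b, design: str = "F2",
                 tol: float = 1e-10, max_iter: int = 500):
    """Maximum-likelihood recombination fraction between two codominant loci.

    Genotypes are dosage vectors (0/1/2, -1 = missing; missing pairs are
    dropped).  The estimate comes from EM over the nine F2 genotype classes:
    every class determines its recombinant-gamete count except the double
    heterozygote, whose expected count is ``2 r^2 / ((1-r)^2 + r^2)``.

    Returns ``(rf, lod)`` where ``lod`` is log10 L(rf) - log10 L(0.5).
    """
    if design != "F2":
        raise NotImplementedError("only the F2 design is implemented")
    a = np.asarray(genotypes_a)
    b = np.asarray(genotypes_b)
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    if len(a) == 0:
        raise ValueError("no complete genotype pairs")
    for g, name in ((a, "locus_a"), (b, "locus_b")):
        if len(np.unique(g)) < 2:
            raise ValueError(f"{name} is monomorphic; recombination fraction undefined")

    counts = np.zeros((3, 3))
    for ga, gb in zip(a, b):
        counts[ga, gb] += 1
    n = counts.sum()

    r = 0.25
    for _ in range(max_iter):
        if r <= 0:
            r = 1e-9
        het = 2 * r**2 / ((1 - r) ** 2 + r**2)
        rec = sum(counts[c] * k for c, k in _REC_COUNT.items()) + counts[1, 1] * het
        r_new = min(rec / (2 * n), 0.5)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new

    def loglik(rr):
        probs = _class_probs(max(rr, 1e-12))
        ll = 0.0
        for c, p in probs.items():
            if counts[c]:
                ll += counts[c] * np.log(p)
        return ll

    lod = (loglik(r) - loglik(0.5)) / np.log(10)
    return float(r), float(lod)


def rf_standard_error(genotypes_a, genotypes_b, rf: float, eps: float = 1e-4) -> float:
    """Standard error of the two-point estimate from the observed information
    (numeric second derivative of the log-likelihood at the MLE)."""
    a = np.asarray(genotypes_a)
    b = np.asarray(genotypes_b)
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    counts = np.zeros((3, 3))
    for ga, gb in zip(a, b):
        counts[ga, gb] += 1

    def loglik(rr):
        probs = _class_probs(min(max(rr, 1e-9), 0.5 - 1e-9))
        return sum(counts[c] * np.log(p) for c, p in probs.items() if counts[c])

    d2 = (loglik(rf + eps) - 2 * loglik(rf) + loglik(rf - eps)) / eps**2
    if d2 >= 0:
        return float("nan")
    return float(1.0 / np.sqrt(-d2))


def map_distance(rf: float, function: str = "kosambi") -> float:
    """Map distance in centimorgans from a recombination fraction.

    Haldane: -50 ln(1 - 2r); Kosambi: 25 ln((1 + 2r) / (1 - 2r)).  Defined for
    0 <= rf < 0.5; Kosambi <= Haldane everywhere on (0, 0.5).
    """
    if not 0 <= rf < 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5)")
    if function == "haldane":
        return float(-50.0 * np.log(1.0 - 2.0 * rf))
    if function == "kosambi":
        return float(25.0 * np.log((1.0 + 2.0 * rf) / (1.0 - 2.0 * rf)))
    raise ValueError(f"unknown mapping function {function!r}")
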