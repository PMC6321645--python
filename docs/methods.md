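# Methods

## Experimental design being modelled

Two synthetic hexaploid wheat lines share one tetraploid (AABB) parent and
differ in their diploid D-genome parent.  Crossing them yields a population
in which only the D genome segregates.  Selfing with heterozygote selection
at a causal locus through the F4, then selfing two independent F4
heterozygotes, produces two sibling F5 populations; from each, one bulk of
ten carrier-homozygotes and one bulk of ten non-carriers is pooled and
sequenced.  Reads from each bulk are aligned to the transcriptomes of both
D-genome parents, giving eight alignment pairs, plus two alignments of the
tetraploid parent's reads used as homoeolog evidence.

## Genetic model

* **Meiosis.** Haldane model: the number of crossovers per chromosome per
  gamete is Poisson with configurable mean (default 1.0, i.e. one Morgan of
  map length per chromosome), breakpoints uniform, no interference, random
  starting chromatid.  There is no genetic map to calibrate against, so the
  map-length default is a modelling choice, not an estimate.
* **Pedigree.** F1 → F2 → F3 single-seed descent selecting a causal-locus
  heterozygote at each step (selection is applied at the causal site only —
  the minimal version of selecting on a "region"); two independent F4
  heterozygous siblings found the two populations; the F5 bulks are filled by
  repeated selfing draws (carrier-homozygous vs non-carrier at the causal
  locus), with a bounded number of redraws.
* **Homozygosity.** Under selfing without selection the per-locus
  heterozygosity halves each generation: `h(g) = 1 − (1/2)^(g−1)` homozygous
  fraction at generation g (F1 = 1).  `expected_homozygosity` is this closed
  form; `simulate_selfing_series` is the Monte-Carlo oracle used to verify
  it (and the acceptance script re-runs that check at every invocation).

## Site and read model

Each catalogued transcript site is one of two kinds:

* **allelic** — the two D-genome parents carry different bases (these are
  the sites a parental pairwise comparison can know about);
* **homoeolog-divergent** — the parents agree but the A/B-subgenome
  homoeolog carries a different base.

Defaults per chromosome: 170 allelic + 2,830 homoeolog-divergent sites on
7 × 150 Mb chromosomes, causal locus at 2D:82,500,000.  The ≈5.7% allelic
share mirrors the composition a real allopolyploid bulk call set shows after
classification.  Contamination: at every homoeolog-divergent site, and at a
fraction (default 0.3) of allelic sites whose homoeolog cross-aligns, a read
is homoeolog-derived with per-site probability ρ ~ Beta(2, 5); 70% of
contaminated sites are detectably expressed in the tetraploid sample.  These
two fractions were fixed a priori so the three classification categories come
out near the published composition (≈6% / 66% / 28%); they are configurable.
Sites whose homoeolog does not cross-align have ρ = 0, which is what makes a
site classifiable as D-genome-specific at all.  The parental pairwise SNP
list contains each allelic site with probability 0.98 (prior-study detection
is imperfect); 0.7% of sites are withheld from the anchor table.

Depth is negative binomial per alignment pair (mean 30, dispersion 5;
variance μ + μ²/k), sampled independently for every pair — the real
experiment's depth per site after pooling is not published, so these are
stand-ins chosen for realistic overdispersion.  Given depth D at a site:
homoeologous reads ~ Binomial(D, ρ) carrying the homoeolog base; the
remaining reads draw a bulk chromosome at the bulk's true donor-allele
frequency.  The alternate allele against a given parental reference is the
other parent's base at allelic sites and the homoeolog base at
homoeolog-divergent sites.  The tetraploid sample's tables contain purely
homoeologous reads (zero coverage where ρ = 0 or the homoeolog is not
expressed), so K = D wherever the homoeolog base differs from the reference.

## Calling, anchoring, merging, classification

A site is called when depth ≥ 10 and alternate fraction ≥ 0.1, both
boundaries inclusive (the emulated caller's options are not documented
anywhere public; this is the package's standing interpretation and both
thresholds are configurable).  Transcript sites are anchored to genome
coordinates through the transcript→genome table, with bases
reverse-complemented on minus-strand transcripts; anchor collisions with
inconsistent reference bases are excluded and reported.  The eight anchored
call sets are merged into one non-redundant set keyed by (chrom, pos) with
per-pair provenance; a site whose observed alleles span more than two bases
is kept but flagged multiallelic and excluded from ΔSNP-index averaging
(the SNP-index is defined for one alternate allele).  An orientation swap of
the same biallelic pair across the two references is *not* multiallelic.

Classification uses genome-keyed evidence sets: presence in the parental
pairwise list ⇒ D-specific; presence in the tetraploid call set ⇒
homoeologous; neither ⇒ unclassified.  A site in both sets defaults to
homoeologous (tetraploid-read support at a site cannot be distinguished from
homoeologous signal); the precedence is configurable and both flags are
always reported.

## ΔSNP-index

Indices computed against the two different parental references point in
opposite allele orientations; averaging them raw would cancel the signal.
Every index is therefore polarized to the donor-parent allele frequency
(pass-through against the non-donor reference, complement against the donor
reference) before the carrier − non-carrier difference is taken.  At each
site the mean is over the available (non-missing) pair values, with
`n_informative` recorded; below-depth-floor indices are missing, not zero.
The alternative (treating missing as zero) is deliberately not the default.

## Steel–Dwass

For each pair of groups the two samples are ranked jointly with midranks;
the standardized rank sum uses the tie-corrected variance
`Var = mn/(N(N−1)) · Σ(r − (N+1)/2)²` and is referred to the studentized
range with k groups and infinite degrees of freedom via `q = √2·|t|`
(scipy's distribution).  An exact mode enumerates the pairwise rank
statistic for ≤ 8 values per group.  With two groups the asymptotic p-value
reduces exactly to the two-sided normal rank-sum p (verified against scipy's
Mann–Whitney implementation); with k > 2 the studentized-range reference
adjusts for all k(k−1)/2 comparisons and is therefore conservative relative
to an unadjusted pairwise enumeration — the exact mode is a per-pair tool,
not a replacement for the family-adjusted test.

## Candidate region and marker design

The published physical interval spans 1.5 Mb and contains 208 sites at real
transcriptome density (~139 sites/Mb).  The simulated genome is ~1,000×
sparser (20 sites/Mb), so the default simulated candidate region is the
causal locus ± 5.2 Mb — the width at which the expected site count matches
those 208 sites.  Candidate SNPs are D-specific sites with averaged
ΔSNP-index strictly greater than 0.38 ("higher than" read as strict), ranked
descending.

dCAPS design searches both strands and every placement of each enzyme's
recognition window over the SNP.  The SNP itself must complete the site for
exactly one allele; up to one mismatch may be introduced into the
discriminating primer, restricted to the primer's 3′ half and never at the
3′-terminal base or the SNP — standard assay-design practice.  Natural CAPS
solutions (zero mismatches) are preferred.  Primer acceptance uses simple
GC-content bounds (40–60%); no melting-temperature model is attempted.
Every emitted assay is validated by in-silico digestion: the two allelic
amplicons must give different fragment multisets.  Digestion treats the
recognition site as its own cut locus with a fixed per-enzyme offset
(StyI C^CWWGG, HpaII C^CGG, HinfI G^ANTC); an IUPAC-palindromic site is one
physical double-stranded site and cuts once.  With only the three published
enzymes and ≤ 1 mismatch, roughly a third of random SNPs are convertible —
the pipeline therefore ranks more candidates than it needs.

## Linkage validation

Markers are scored on a freshly simulated F2 population (default n = 788,
codominant genotypes).  The two-point recombination fraction is the MLE from
EM over the nine F2 genotype classes (the double heterozygote contributes
`2r²/((1−r)² + r²)` expected recombinant gametes); LOD is against r = 0.5.
Map distances default to Kosambi (conventional in wheat mapping), with
Haldane available.  Standard errors come from the observed information
(numeric curvature at the MLE).

## Problem sizes and determinism

The default study conditions — 21,000 sites, four bulks of ten, depth ~30,
788 F2 individuals — run the full pipeline in a few seconds; tests use the
same defaults, with smaller layouts only for I/O and CLI plumbing checks.
One integer seed drives every stage through `numpy.random.SeedSequence`
fan-out; identical seeds reproduce byte-identical fixture bundles.

## What passing tests do and do not show

The generator reproduces the *structure* of the experiment (pedigree,
selection, contamination, overdispersed counts, two references, imperfect
anchoring and evidence lists), not its sequence-level reality: there is no
read alignment, no assembly artefacts, no expression variation between
bulks, no indels, and contamination is a per-site mixture rather than a
read-mapping phenomenon.  Passing the localization and recovery tests shows
the statistics and bookkeeping are correct under the stated model; it does
not certify caller or aligner behaviour on real reads.  The classification
truth labels are defined by the evidence-generating mechanism, so measured
precision/recall isolates calling-threshold effects by construction.

## Known limitations

* Selection acts on a single causal site, not a region-wide haplotype.
* The tetraploid sample's expression model is a Bernoulli per site; real
  homoeolog expression varies continuously across tissues.
* No confidence intervals on ΔSNP-index under the sampling null; the
  Steel–Dwass scan is the only inferential device, as in the design the
  package follows.
* Two-point linkage only; no multipoint ordering.
* Primer thermodynamics beyond GC bounds are out of scope.
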