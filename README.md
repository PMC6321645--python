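# wheatbsa

RNA-seq bulked segregant analysis (BSA) for allopolyploid wheat, built around
the experiment that localizes a selected locus in a bi-parental cross of two
**synthetic hexaploid wheat** lines (AABB tetraploid × two different
*Aegilops tauschii* D-genome parents).  The package is aimed at people who
want to develop D-genome markers for a target region from pooled RNA-seq
allele counts — and at people who want a fully simulated, ground-truthed
version of that experiment to test such an analysis end to end.

## The problem and the statistic

In a hexaploid background, a SNP called from reads aligned to a diploid
parental transcriptome can be a true **allelic** variant segregating on the D
genome, or a fixed **homoeologous** difference against the A/B subgenomes.
The analysis separates them with two evidence sets and then scans allele
frequencies:

* **SNP-index** at a site: the fraction of reads carrying the alternate
  allele, `SNP-index = alt_depth / depth` (missing below a depth floor).
* **ΔSNP-index**: polarized carrier-bulk index minus non-carrier-bulk index.
  Near a locus the bulks were selected on, ΔSNP-index → 1; at unlinked sites
  it fluctuates around 0; at homoeologous sites the A/B-derived reads are
  identical in both bulks, so ΔSNP-index ≈ 0.
* Per site, the four available ΔSNP-index values (two sibling populations ×
  two parental references) are averaged after polarizing every index to the
  donor-parent allele frequency.
* Per-chromosome distributions of the averaged ΔSNP-index of D-genome-specific
  sites are compared with the **Steel–Dwass** all-pairs rank test
  (tie-corrected pairwise rank sums referred to the studentized range,
  `q = √2·|t|`, k groups, df = ∞; exact enumeration for small samples).
* Selected SNPs are converted into **dCAPS** assays: up to one deliberate
  mismatch near the primer 3′ end makes an enzyme recognition site that is
  completed by exactly one allele; every assay is validated by in-silico
  digestion of both allelic amplicons.

The synthetic-data module simulates the whole design: two D-genome parents
differing at SNP sites on seven chromosomes, an F1 selfed with heterozygote
selection at the causal locus through F4, two sibling F5 populations, bulks
of ten carrier-homozygotes and ten non-carriers from each, and
negative-binomial sequencing depth with per-site homoeologous contamination
(`rho ~ Beta(2, 5)`).  Ground truth (bulk genotypes, per-site allele
frequencies, site classes) is retained for every run.

## Worked example

```sh
wheatbsa run-all --seed 1 --out run1
```

runs simulate → call → classify → index → select → dcaps → map on the default
configuration and prints the run report.  Key lines from the report:

```
sites simulated: 21000
non-redundant sites: 20288

       D_SPECIFIC  HOMOEOLOGOUS  UNCLASSIFIED  Total
2D            128          1952           813   2893
...
Total         914         13555          5819  20288

candidate region 2D:77300000-87700000: 209 sites
  {'HOMOEOLOGOUS': 153, 'UNCLASSIFIED': 45, 'D_SPECIFIC': 11}
  delta range [-0.2571, 1.0000]
markers designed: ['bsa1', 'bsa2', 'bsa3', 'bsa4']
```

The 21,000 simulated transcript sites yield 20,288 non-redundant
genome-anchored SNPs, partitioned into D-genome-specific / homoeologous /
unclassified classes.  The Steel–Dwass scan (written to `steel_dwass.tsv`)
shows every comparison between chromosome 2D (which carries the causal
locus) and the other six chromosomes at p < 0.001.  Inside the candidate
region, eleven D-specific SNPs exceed the ΔSNP-index threshold of 0.38; four
are converted into restriction assays, e.g.

```
marker  site          enzyme  mismatches  fragments_ref  fragments_alt
bsa1    2D:82467086   StyI    1           15,65          80
bsa2    2D:82558410   HinfI   1           20,63          83
```

(`bsa1`: the reference-allele amplicon is cut into 15 + 65 bp, the
alternate allele stays uncut at 80 bp).  Genotyping a fresh simulated F2
population of 788 individuals places every designed marker within 1.3 cM
(Kosambi) of the causal locus (`marker_map.tsv`):

```
marker  pos        rf        cM_kosambi
bsa1    82467086   2.5e-25   0.00
bsa2    82558410   6.3e-04   0.06
bsa3    82707045   1.9e-03   0.19
bsa4    80396079   1.2e-02   1.21
```

The same steps are available as a library (`wheatbsa.simulate`,
`wheatbsa.sites`, `wheatbsa.classify`, `wheatbsa.stats`, `wheatbsa.markers`,
`wheatbsa.linkage`) and as individual subcommands (`simulate`, `call`,
`classify`, `select`, `dcaps`, `map`).

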