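# Methods

## Genetic model of the simulator

The generator emulates an F2 bulk-segregant design for a dominant nuclear
restorer locus in a CMS background. The seed parent (CMS line, genotype
rf/rf at the restorer locus, reference allele at every marker) is crossed to
the restorer line (Rf/Rf, alternate allele at every marker); the F1 is
selfed. Because every F2 inherits sterile cytoplasm from its mother, the
phenotype is determined entirely by the nuclear locus: Rf/Rf and Rf/rf are
fertile, rf/rf sterile. The sterile bulk is drawn from rf/rf individuals
only; the restorer bulk from Rf/– individuals, a 1:2 mixture of Rf/Rf and
Rf/rf. Hence at the causal site the expected alternate-allele frequency is 0
in the sterile pool and 2/3 in the restorer pool.

Meioses follow a no-interference model: the crossover count per chromosome
is Poisson with mean `recomb_rate` (default 2 crossovers/chromosome, a
typical plant value), positions uniform. At physical distance d on a
chromosome of length L this gives Haldane's recombination fraction
r = (1 − e^(−2λ))/2 with λ = `recomb_rate`·d/L. Conditioning the pooled
chromosomes on phenotype yields the expected frequencies recorded as truth:

    sterile pool:   E[f_alt] = r
    restorer pool:  E[f_alt] = (2/3)(1 − r) + (1/3)r = 2/3 − r/3

(Among fertile F2, 2/3 of chromosomes carry Rf at the causal site; a
chromosome carrying Rf there carries the alternate marker allele with
probability 1 − r, a rf chromosome with probability r.) The expected pool
difference |RP − SP| = 2/3 − 4r/3 decays monotonically from 2/3 at the locus
to 0 for unlinked sites, which is the linkage-decay property the tests
check on expected (not sampled) values.

Read sampling: per sample per site the total depth is negative-binomial
(mean `mean_depth` = 50, size `depth_dispersion` = 5, i.e. realistically
overdispersed RNA-seq site coverage); each read carries the alternate allele
with the bulk's true frequency, computed from the actually sampled bulk
individuals. Sequencing error is off by default (`error_rate` = 0) so that
the truth stays analytically checkable; when enabled, each read is miscalled
to a uniform other base. Parents are pure homozygotes at every marker, which
isolates pipeline behaviour from marker-informativeness confounds;
non-informative and defective markers for filter tests are constructed
directly in the test suite.

Study-design defaults — 3 chromosomes × 2000 SNPs on 20 Mb, 200 F2, 20
plants per bulk, 50× depth — are the conditions used for the replicated
recovery experiments. Bulk sizes in real designs of this kind are rarely
published; 20 per bulk is a common choice and is configurable. Note the
sterile class is only ~1/4 of F2, so a sterile bulk of size b needs
comfortably more than 4b F2 individuals.

## Expression model

Counts are negative-binomial (mean `expr_mean` = 500, size
`expr_dispersion` = 10) per gene per sample. The gene spanning the causal
position has its mean multiplied by `causal_gene_fold` (default 10) in the
restorer samples (R1, RP) and set to `causal_sterile_frac`·`expr_mean`
(default 0, i.e. truly absent) in the sterile samples (8A, SP). Two knobs
are needed because the two interesting regimes differ: the
restorer-specific presence/absence signature (fold high, sterile fraction
0) and the null control in which the causal gene blends into the background
(fold 1, sterile fraction 1). FPKM is computed as counts·10⁹/(length·library
size) with the library size taken as the per-sample total count of the
table.

What the generator does **not** model: real RNA-seq features such as
isoforms and splice structure (expression is count-level only), expression
variation among biological replicates (one library per accession, as in the
emulated design), allele-specific expression within pools, mapping bias,
genotyping error in parents, and marker ascertainment. Passing recovery
tests therefore demonstrate the statistical machinery under an idealized
informative-marker design, not robustness to alignment artefacts or
non-informative markers (the filter suite covers the latter separately with
constructed cases).

## Filtering conventions

- **Cluster rule**: a 35 bp window starting at position p covers
  [p, p+34]; any window containing more than 3 SNPs removes all its member
  SNPs. Anchoring candidate windows at SNP positions is exhaustive, since an
  offending window can be shifted left until its edge hits a SNP; the test
  oracle nevertheless scans every start position.
- **Quality rule**: QUAL standardized by the combined read depth across all
  four samples (the quality-by-depth convention), strict `> 2.0`;
  zero-depth sites cannot be standardized and are removed.
- **"Degenerate" SNPs** are read as multi-allelic sites.
- **Min-support** (≥3 reads) applies per sample: the ED statistic needs
  defined frequencies in both pools, and symmetric treatment of parents
  keeps the consistency filters meaningful.
- **Consistency rules**: a pool homozygous for the allele its own parent
  lacks is discrepant (removed); pools *fixed for the same allele* are
  consistent-type (removed). Sites heterozygous in both pools are kept —
  they are the allele-frequency background of the scan and dominate the
  retained set in a real F2 design; removing them would leave the smoother
  and the genome-wide threshold without a background distribution.
- Genotype classes from pooled depths use alt-fraction cutoffs ≤0.1 /
  ≥0.9 (configurable), robust at depth ≥ 10.
- Coordinates are 1-based inclusive throughout, as in VCF; BED output is
  converted to 0-based half-open on write.

## Association scan

Per-site order of operations: base frequencies → ED → ED⁵ → sliding median
→ threshold. The fitting window is the focal SNP plus up to 50 SNPs on each
side (101 values), truncated — not padded — at chromosome ends; truncation
keeps every fitted value a median of observed data at the cost of higher
variance near ends. The threshold is the genome-wide median + 3·SD of
fitted values with the sample SD (ddof = 1) by default; the population
convention is available via `sd_ddof=0`. Threshold comparison is strict.
Interval calling merges above-threshold runs separated by at most
`gap_snps` below-threshold sites (default 0: no merging); ranking is by
peak fitted value, ties broken by length then coordinate for deterministic
output.

## Candidate screening

Differential expression is a declared |log2FC| ≥ 1 rule on FPKM, with no
dispersion modelling — the pipeline needs a self-contained, testable
classifier, not a replication of count-model DEG packages; the cutoff is
configurable. A gene expressed in the restorer member of a comparison but
with zero FPKM in the denominator has an undefined fold change; it is
flagged (never reported as ±∞) and counted as upregulated, since
restorer-only expression is the strongest version of the signature.
Presence/absence cutoffs (absent ≤ 0.5 FPKM in every sterile sample,
present ≥ 5 in every restorer sample) separate a true absence pattern from
background with margin and are configurable. Ranking tiers: (1) common-up ∩
presence/absence, (2) common-up, (3) presence/absence; ties by pools log2FC
descending (undefined-with-expression ranks highest), then gene id.

ORF length n (a multiple of 3, ≥ 6) encodes n/3 − 1 residues, the terminal
stop codon excluded. Marker–phenotype concordance is the fraction of
individuals whose carrier status at the marker predicts their phenotype
under the dominant model.

## Numerical and implementation notes

- The sliding median is pandas `rolling(2·flank+1, center=True,
  min_periods=1).median()` applied per chromosome; tests compare it against
  an independent explicit window loop.
- All randomness flows from one `numpy` `default_rng` seeded by
  `SimConfig.seed` (expression uses a `SeedSequence` child so variant and
  expression streams are independent); identical configs give byte-identical
  output files.
- Degenerate inputs: fewer than 2 fitted points cannot yield a threshold
  (error); zero pool depth makes base frequencies undefined (error,
  unreachable after min-support filtering); an empty interval list is a
  valid scan result.

## Known limitations

- The genome-wide median + 3·SD threshold is not a calibrated
  false-positive rate: the fitted profile is a moving median (neighbouring
  values share ~100 of 101 inputs) and right-skewed, so even under a null
  design with phenotype-blind bulks a few percent of sites — in contiguous
  blocks — exceed the threshold (measured ≈ 3–4% of sites at the default
  design; ≈ 2% even for idealized independent noise). Interpreting called
  intervals should rely on the peak ranking and on replication, not on the
  threshold as an error guarantee.
- With 2000 SNPs per chromosome the 101-SNP window spans ~1 Mb; intervals
  narrower than that cannot be resolved, and called interval widths
  (median ≈ 2 Mb at defaults) reflect the smoother as much as linkage.
- The DEG rule ignores count uncertainty; with single libraries per
  accession a dispersion-aware test would be underdetermined anyway.
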