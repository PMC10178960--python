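# Methods

## The inference problem

An F2 population from a cross of two inbred parents segregates every SNP that
distinguishes the parents.  Pooling the phenotypic extremes and sequencing
the pools turns a mapping experiment into an allele-frequency contrast: at a
SNP unlinked to the causal locus both phenotype bulks sit near allele
frequency 1/2, while at the causal locus a fully penetrant recessive
phenotype forces the mutant bulk to frequency 1 and leaves the normal bulk at
1/3 (phenotypically normal plants are 1 hom-wild : 2 het).  The SNP-index of
a bulk estimates that frequency from reads; Δ(SNP-index) = index(O) −
index(N) therefore has expectation 0 genome-wide and 2/3 at a recessive
causal locus, decaying with genetic distance as linkage to the selected locus
weakens.

## F2 simulator (`bsamap.simcross`)

* **Recombination.** Haldane model: per gamete, crossover count ~
  Poisson(genetic length in Morgans), genetic length = bp × (cM/Mb) / 1e8,
  breakpoints uniform, starting haplotype Bernoulli(1/2), no interference.
  Default 4 cM/Mb — a round order-of-magnitude figure for the rice genome
  (~1,500 cM over ~380 Mb); no genetic map is modeled.  An F2 plant is the
  sum of two independent recombinant gametes, since both of its parents are
  the same fully heterozygous F1.
* **Phenotype and bulks.** Phenotype is a deterministic recessive function of
  the causal-locus dosage.  Bulks (default 152 plants each, matching the
  mapped experiment's design; parental bulks default 9) are sampled without
  replacement within phenotype class from an F2 of default 800 plants — the
  recessive quarter (expected 200, SD ≈ 12) then fills a 152-plant mutant
  bulk with failure probability < 1e-4; a shortfall raises an explicit error
  rather than silently shrinking the bulk.
* **Sequencing.** Reads are sampled at allele-count level only: per site and
  bulk, depth ~ Poisson(mean 50 by default; the real experiment's depth is
  unpublished) and maternal count ~ Binomial(depth, f(1−e) + (1−f)e) with
  error rate e (default 0).  Read pairing, mapping and variant calling are
  upstream of this package's inputs and are not emulated — consequences:
  simulated data contain no mapping artifacts, no depth heterogeneity beyond
  Poisson, no allele-specific bias, and every marker is a clean biallelic
  parental SNP.  Passing tests therefore validate the statistics, not
  robustness to alignment pathologies.
* **Orientation.** The maternal (mutant-parent) allele is written as ALT, so
  a bulk's SNP-index is simply its ALT-depth fraction.
* **Determinism.** One `numpy` Generator seeded from `CrossConfig.seed`
  drives marker placement, meiosis, bulk choice and read sampling; the same
  seed yields a byte-identical VCF.

## Screening and scan (`bsamap.snpindex`)

"Each parental bulk supports its own allele at ≥ 0.8 of its reads" is the
operative reading of the parental-uniqueness ratio: maternal-allele fraction
≥ 0.8 in MO and ≤ 0.2 in PN, plus a per-bulk depth floor (default 7 reads, a
common QTL-seq choice) and presence in all four bulks.  A zero-depth index is
*missing*, never 0 — 0 is a real biological value here.  Windows start at
position 1 and advance by the step (defaults 1 Mb / 10 kb); membership is
1-based inclusive; means are unweighted over member SNPs' non-missing values
(depth-weighting is not used; the per-window SNP minimum defaults to 1 and
is configurable); trailing windows are truncated at the chromosome end.
Candidate intervals are maximal runs of consecutive windows whose mean Δ
exceeds the band, reported as the union span and additionally formatted at
0.01 Mb precision.

## Null confidence bands (`bsamap.null_ci`)

How the original analysis computed its 95%/99% intervals is unpublished;
this package adopts the standard QTL-seq-family null simulation and states
it precisely.  Under no causal gene, a bulk of n plants has summed maternal
dosage ~ Binomial(2n, 1/2) → bulk frequency f, and the site's index is
Binomial(depth, f)/depth; Δ is the difference of two such independent bulks.
`simulate_null_site` implements exactly that marginal model (analytic check:
Var(Δ) = 2[1/(8n) + (1/4 − 1/(8n))/depth], SD ≈ 0.108 at n = 152,
depth = 50).

For *window-level* bands the marginal model is not enough: member SNPs of a
window are carried by the same plants and are genetically linked, so their
genotype-stage fluctuations are strongly correlated — under Haldane
recombination the dosage correlation at genetic distance d Morgans is
exactly exp(−2d).  Treating sites as independent shrinks the genotype
component of the window-mean variance by ~the SNP count and yields a
markedly anticonservative band (measured ~7% exceedance of a nominal 1%
band).  `build_band` therefore simulates the genotype stage as a stationary
Gaussian Markov (AR(1)-in-distance) process with SD √(1/(8n)) and
autocorrelation exp(−2d) — the Gaussian approximation is excellent at
n = 152 — and layers independent per-site Binomial(depth, f) read noise
using each SNP's *observed* O- and N-bulk depths, honoring depth
heteroscedasticity across windows.  Within a replicate one null genome is
drawn and averaged into every window exactly as the observed scan does, so
overlapping windows are properly correlated.  Options: `recomb_rate=None`
recovers the naive independent-site band (kept for comparison);
`n_population=N` applies the finite-population correction (N−n)/(N−1) to the
genotype variance when the two disjoint bulks are drawn from one F2 of N
plants (the simulator's truth); the default (None) assumes an effectively
infinite population and is slightly conservative.  Bands are empirical
2.5/97.5 and 0.5/99.5 percentiles over replicates (default 10,000; < 1,000
warns), linear interpolation between order statistics, bit-reproducible
given a seed.  Calibration is verified empirically: over null genomes, ~1%
of windows fall outside the 99% band (two-sided; the upper tail alone is
~0.5%).

## Candidate screen and effect annotation (`bsamap.candidate_screen`)

Range criteria (N-index 0.30–0.40, Δ 0.60–0.70) are inclusive at both ends;
the equality criteria (PN = 0.00, O = 1.00) use an absolute tolerance,
default exact (appropriate for error-free simulation; ~0.02 is suggested for
noisy data).  Sensitivity caveat: the N-bulk index of a *single* site at
depth 50 has SD ≈ 0.074 around 1/3 — ≈ 0.029 of it from bulk composition,
which no amount of depth removes — so the 0.30–0.40 window captures the
causal SNP itself in only ~half of replicates (~0.87 as depth → ∞).  The
screen's practical power comes from several tightly linked SNPs being
screened jointly inside the interval; unlinked SNPs essentially never pass,
because index(O) = 1.00 exactly at depth ~50 from a frequency-~1/2 bulk has
probability ~2⁻⁵⁰.

The annotator handles SNVs against spliced CDS models: CDS segments are
concatenated in genomic order, reverse-complemented for minus-strand
models, the variant located in spliced-CDS coordinates (codon index =
⌊(pos−1)/3⌋ + 1), both codons translated with the standard genetic code, and
the change classified as synonymous / missense / stop_gained / stop_lost;
positions outside the CDS report noncoding, or splice_adjacent within 2 bp
of a CDS boundary.  Models whose CDS length is not a multiple of 3 are
refused loudly (a silent frameshift would corrupt every downstream codon).
Every annotation is cross-checked in the test suite against an independent
oracle that rebuilds and translates the entire mutated protein.

## Assay arithmetic (`bsamap.assay_stats`)

Percent change is (reference − other)/reference × 100 with a
"lowered"/"increased" direction label matching how such results are phrased.
`t_from_summary` gives the classic pooled Student's t (or Welch) from means,
SDs and ns; replicate counts must be supplied by the user — published
composition tables often omit n, in which case significance stars cannot be
recomputed, only the percent changes.  2^−ΔΔCT normalizes a target gene's CT
to an endogenous control within sample and calibrator; it is invariant to
any constant CT shift.  `log2fc` uses a configurable pseudocount (default 1,
appropriate for FPKM-scale abundances).

## Problem sizes and numerical choices

Simulation-based validation uses 2 × 25 Mb genomes with 1,000 SNPs, bulks of
152 from 800 F2 plants at mean depth 50× — interval recovery is checked over
50 seeded genomes and band calibration over 20 null genomes with 2,000 band
replicates each (the library default of 10,000 replicates is used for
single-run analyses; 2,000 keeps repeated-genome studies fast at the cost of
slightly noisier tail quantiles, which the calibration assertions absorb).
Quantiles use numpy's linear interpolation; window means are exact
cumulative-sum differences validated against a brute-force re-scan oracle;
all TSV output uses 6-decimal floats with `NA` for missing.

## Known limitations

* Single fully penetrant recessive locus only; no polygenic or incompletely
  penetrant phenotypes.
* Biallelic SNPs only — multiallelic and indel records are counted and
  skipped, and the annotator does not handle indels or non-standard codes.
* The null band's Gaussian-Markov genotype stage assumes the Haldane map is
  correct and the same recombination rate genome-wide.
* The simulator does not emulate mapping/calling artifacts, GC or
  allele-specific coverage bias, or contaminated bulks (a parental
  cross-contamination knob exists only via `error_rate`'s read-level noise).
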