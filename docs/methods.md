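# Methods

This note records the models implemented, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the
numerical conventions — the decisions a maintainer would otherwise have to
reverse-engineer from the code.

## Data model and coordinates

Allele counts live in sync format (`chrom pos ref A:T:C:G:N:del` per
population), 1-based inclusive, as are pileup positions.  All internal
mask intervals are 0-based half-open (BED convention); the only
conversions happen in `sync_io`, so off-by-one drift has a single place to
be wrong.  The `ExperimentDesign` maps each sequenced pool to a
(replicate, time point, generation) cell; the canonical design is three
replicates with base pools at generation 0, middle pools at 15/15/23, end
pools at 37, and one extra pool of replicate 1 at generation 27.  Base
pools are paired replicate-wise in contrasts.

## SNP calling

A site is a SNP when exactly two nucleotides carry reads after noise
handling.  Filters (all exposed as parameters): the minor allele has ≥ 1
read in ≥ 2 populations, ≥ 10 reads summed over all populations in the
file, and no population exceeds 500× coverage (a per-population rule:
coverage outliers flag CNV/paralogy per sample; a summed-coverage mode is
available).  Allele identity is defined on counts summed over all
populations, ties broken alphabetically, so a SNP keeps one identity
across time points.  A third-ranked allele is treated as sequencing noise
and zeroed when all non-top-two alleles total ≤ 2 reads; anything stronger
disqualifies the site — this keeps every downstream table strictly
2 × 2 × k.  Coverage counts A/C/G/T only.

Windowed diversity uses the per-site unbiased heterozygosity
`n/(n−1) · (1 − Σ f²)` averaged over genotyped sites in non-overlapping
10-kb windows.  This is a deliberate simplification of the full Pool-Seq
π estimator (no explicit pool-size correction); it is used for relative,
within-dataset comparisons, not absolute diversity estimates.

## CMH scan

The statistic is the classic stratified 2×2 form with variance
`row1·row2·col1·col2 / (n²(n−1))` per stratum and a χ²₁ reference; the
continuity correction is off by default because Pool-Seq counts are large
(flag provided).  Strata with a zero margin are skipped; replicates with
zero coverage at either time point are dropped per SNP and `k_used`
records the remainder.  Replicates sequenced at different generations
within one time-point class (15 vs 23) are pooled into the same contrast;
the per-replicate generations matter only to the null simulation.

Reads, not chromosomes, are the sampling unit of the table.  Drift between
time points is therefore real extra variance the test never models: on a
simulated neutral experiment at Ne = 200 the statistic is inflated ~2.7×
and the p-value distribution is far from uniform (KS distance ≈ 0.27 at
10⁵ SNPs).  This is intrinsic to the design, not a defect of the
implementation — in the no-drift limit (N → ∞, read resampling only) the
p-values are uniform, which the test suite verifies.  All significance
statements must therefore go through the simulated null below.

## Drift null and empirical FDR

The null re-simulates the entire experiment: per SNP and replicate,
`t` binomial Wright–Fisher generations at constant size N starting from
the observed base frequency (pairs of starting frequency and coverage row
are bootstrapped jointly so their correlation survives), reads redrawn
binomially at the observed (or modelled) coverages at every sequenced
generation, the same quality filters, the same scan.  N defaults to the
estimated Ne fed directly into the haploid engine — the convention of the
experimental literature this pipeline follows — with a flag for 2·Ne.

The significance threshold is the ⌈f·n⌉-th smallest simulated p-value
(default f = 10⁻⁵); the empirical FDR divides the rescaled count of
simulated SNPs at or below the threshold by the experimental count, ties
counted inclusively (conservative).  At the top-candidate variant the
threshold is the n-th smallest experimental p (default n = 2000).  Note
that at f = 10⁻⁵ and 10⁵ simulated SNPs the threshold rests on a single
order statistic, so the FDR of a null-vs-null comparison fluctuates
Poisson-style around 1; the acceptance script also reports the denser
f = 10⁻³ probe, which is stable.

Randomness: each simulation is driven by one seeded numpy PCG64 generator
over fully vectorised locus arrays; identical seed + config reproduce
byte-identical outputs.

## Temporal Ne

Standardised variance of allele-frequency change
`F = Σ(x−y)² / Σ z(1−z)`, `z = (x+y)/2`, in ratio-of-means form (stable at
extreme frequencies), over SNPs polymorphic at the first time point.  The
estimator is the moment form for non-destructive sampling (plan II):

    Ne = t / (2·[F − 1/S₀ − 1/S₁])

with S the *effective allele-sample size* of each sampling event.  One
sampling event at allele-sample size S contributes pq/S of variance, i.e.
1/S to F; with S expressed in diploid individuals this is the textbook
1/(2S) term.  Pool-Seq samples twice — a pool of 2·pool_size chromosomes,
then coverage reads — composed harmonically:
`S = (n_pool · cov) / (n_pool + cov)` (flags for reads-only / pool-only).
A non-positive bracket returns an infinity sentinel (drift below the
sampling floor).  Ne here is a diploid effective size: simulated truths
of N individuals are generated by drifting 2N chromosomes, and recovery
is essentially unbiased (medians 100/199/494 at truths 100/200/500 under
the canonical design).  Confidence intervals are percentile bootstrap over
SNPs (default 1000 resamples).  The estimator is a moment method chosen
for transparency and speed; likelihood-based temporal machinery is out of
scope and the report header says which method produced it.

## Trajectories and classification

The selected allele at a SNP is the one whose mean frequency change across
replicates over the identification contrast is positive (exact zero maps
to the minor allele and is flagged, as are replicates disagreeing in
sign).  Interval AFCs are replicate means; they telescope exactly
(AFC(B→M) + AFC(M→E) = AFC(B→E)).

Classification into plateau / continuous / other:

* plateau — AFC(B→M) ≥ rise_min and |AFC(M→E)| ≤ flat_max;
* continuous — AFC(B→M) ≥ rise_min/2 and AFC(M→E) ≥ flat_max;
* other — everything else (labels partition the set).

The automatic thresholds are data-driven: rise_min is the median early
AFC among the candidates, flat_max the 95th percentile of |AFC(M→E)| in a
matched neutral simulation (the drift envelope).  A caveat worth stating
plainly: at Ne ≈ 200 the drift envelope is wide (flat_max ≈ 0.13 under
the canonical design), and weakly selected additive alleles (s ≈ 0.1)
have late-phase changes of the same order — roughly half of them fall
inside the envelope and classify as "other" rather than "continuous".
Overdominant alleles that reached equilibrium before the middle time
point classify as plateau reliably (> 90% in recovery runs), because
selection actively shrinks their late-phase variance below the neutral
envelope.  No threshold rule on two AFCs can separate weak continuous
selection from drift here; treat the continuous label as conservative.

Fixation fractions are reported on replicate-mean frequencies at both
≥ 0.99 and > 0.90 (a per-replicate mode exists).  Flanking-decay curves
stack non-candidate SNPs into |distance| bins (floor(d/width), default
100 bp up to 1 kb) around each candidate, candidates excluded from their
own flanks, with position-adjusted controls 500 kb upstream to cancel
chromosome-scale drift heterogeneity.  The difference between the two
candidate classes' late-phase AFC distributions is tested with a
Mann–Whitney U — a deliberately assumption-light stand-in for a formal
dynamical test.

## Feature annotation and enrichment

The annotator is minimal by design: merged exons per gene, the CDS chain
of the longest transcript, codon lookups against the supplied genome for
synonymous/nonsynonymous calls (reverse strand handled by complementing
alleles), intron for in-gene non-exon positions, UTR labels by position
relative to the CDS, upstream/downstream within 200 bp of the gene span,
intergenic only when nothing else applies.  SNPs under several genes or
features carry every label (so per-feature totals exceed SNP counts, and
each feature is tested against its own complement with a 1-df Pearson
χ²).  It is not a full effect predictor — no splice sites, start/stop
gains, or per-transcript multiplicity.

GO enrichment corrects gene-length bias by permuting SNPs, not genes:
random SNPs are drawn without replacement until they hit as many genes as
the candidates did (gene = span ± 200 bp, consistent with the
upstream/downstream rule), per-term gene hits are recorded, and the
empirical p is `(1 + #perms ≥ observed) / (1 + n_perm)` with floor
1/(1+n_perm).  Default n_perm = 10⁵ keeps desk-scale runs interactive;
raise it (the reference workflow uses 10⁷) when p-values near the floor
matter.  Two multiple-testing summaries are reported: Benjamini–Hochberg
over the empirical p-values, and the permutation-ensemble empirical FDR
(expected null terms at the observed p over observed terms), the latter
requiring the per-permutation count matrix and hence bounded n_perm.

## Synthetic experiments

The generator emulates the canonical experiment: a base of unlinked
biallelic SNPs with a neutral 1/i folded site-frequency spectrum (Beta
alternative available), three replicates drifting at Ne = 200, coverage
Uniform{30..64} per SNP and population, reads binomial.  Because its
fitness schemes are diploid (additive: w = 1+s, 1+hs, 1; overdominant:
1−s₁, 1, 1−s₂ with equilibrium s₂/(s₁+s₂)), drift defaults to 2·Ne
chromosomes for a population of Ne individuals; selection acts
deterministically before each drift draw.  The standard planting scheme
uses additive s = 0.1 with starting frequencies spread over [0.05, 0.2]
and overdominant s₁ = 0.45, s₂ = 0.55 from p₀ = 0.3 — a rapid ~0.25 rise
to the 0.55 equilibrium just before generation 15, reproducing the
plateau phenomenology.

What the generator does **not** emulate — and what passing recovery tests
therefore cannot show about real data: linkage (loci are independent, so
flanking-decay curves are flat by construction and hitchhiking is absent),
new mutations during the experiment, demographic change, mapping and
sequencing artefacts beyond binomial read noise, and base-composition or
mappability structure along the genome.

## Problem sizes and numerics

Recovery and calibration runs use 10⁵ SNPs for null calibration, 10⁴+150
for selection recovery averaged over 10 seeds, 100 replicate estimates for
Ne, and 10⁵ Monte-Carlo trajectories for moment identities — sizes at
which every Monte-Carlo band in the tests is a 3-SE band of the quantity
it checks.  Ties in candidate ranking break by (chrom, pos); empirical
thresholds clamp to the smallest simulated p; p-value work uses NaN for
undefined (all-degenerate) SNPs and propagates it explicitly.  All
statistical primitives with an established reference (χ² tails, Fisher
exact, Mann–Whitney, BH) come from scipy/statsmodels conventions; the CMH
statistic itself is implemented here and cross-checked in the tests
against an independent brute-force evaluation and an external reference
implementation.
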