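# erps — evolve-and-resequence Pool-Seq analysis

`erps` detects SNPs responding to selection in replicated
evolve-and-resequence (E&R) experiments sequenced as pools (Pool-Seq), and
then characterises what those alleles did.  It is written for the standard
fly-style design: replicate populations founded from one base population,
evolved under a novel regime, and pool-sequenced at a few time points
(e.g. generations 0, 15/23 and 37).

## The method

At every biallelic SNP the allele counts form a 2 × 2 × k contingency
stack — rows the two alleles, columns two time points, strata the k
replicates.  The **Cochran–Mantel–Haenszel** statistic

```
X² = ( |Σₖ (aₖ − E[aₖ])| − c )² / Σₖ Var(aₖ),   E[aₖ] = row1ₖ·col1ₖ/nₖ
```

tests for a frequency change *consistent across replicates* and follows
χ²₁ under its null.  But that null treats reads as the sampling unit:
genetic drift between the time points is real variance the table never
sees, so raw CMH p-values are anti-conservative.  Significance is
therefore calibrated empirically: the whole experiment is re-simulated
under neutral **Wright–Fisher drift** (binomial resampling of N genomes
per generation, starting from the observed base frequencies, reads redrawn
at the observed coverages, identical filters and scan), and

* the p-value threshold is taken from the top fraction (default 10⁻⁵) of
  simulated SNPs,
* the **empirical FDR** is `(simulated hits × |exp|/|sim|) / experimental
  hits` at that threshold.

Around this core the package provides: sync/pileup I/O with repeat, indel
and region masking; SNP calling with the classic three quality filters
(minor allele in ≥ 2 populations, ≥ 10 reads summed, coverage ≤ 500);
windowed π and heterozygosity loss; temporal **Ne** estimation
(`Ne = t / 2(F − 1/S₀ − 1/S₁)` with two-stage pool+read effective sample
sizes); allele-trajectory classification (plateau vs continuous), fixation
and overlap summaries and flanking-decay curves; feature annotation with
χ² enrichment; and a gene-length-bias-corrected, Gowinda-style GO test
that permutes SNPs rather than genes.  A synthetic-experiment generator
(`erps.synth`) produces complete experiments with planted additive or
overdominant loci and a truth table, so every stage is testable without
fly data.

## Worked example

```python
from erps import default_design, generate_experiment, cmh_scan, top_candidates
from erps.synth import standard_planting
from erps.snp_calling import snp_filter_mask
from erps.drift import (SimulationConfig, simulate_null_experiment,
                        empirical_threshold, empirical_fdr)

design = default_design()                       # 3 replicates; B, M(15/15/23), E(37)
exp = generate_experiment(n_snps=10_150, planted=standard_planting(), seed=4)
keep = snp_filter_mask(exp.snps.minor_counts, exp.snps.coverages)
snps = exp.snps.subset(keep)
print(f"{keep.sum()} of {len(exp.snps)} simulated sites pass the quality filters")

scan = cmh_scan(snps, design, ("B", "E"))
cfg = SimulationConfig(ne=200.0, seed=5, coverage_model=("uniform", 30, 64))
_, sims = simulate_null_experiment(snps, design, cfg, contrasts=[("B", "E")])
sim_p = sims["B-E"]["p_value"].dropna().to_numpy()
thr = empirical_threshold(sim_p, top_fraction=1e-3)
res = empirical_fdr(scan["p_value"].to_numpy(), sim_p, thr)
print(f"p-value threshold from the drift null: {thr:.3e}")
print(f"experimental SNPs below it: {res.n_exp_below}  (empirical FDR {res.fdr:.3f})")

cand = top_candidates(scan, 100)
merged = cand.table.merge(exp.truth, on=["chrom", "pos"])
print("top-100 candidates by planted class:", merged["mode"].value_counts().to_dict())
```

prints (seed 4):

```
6717 of 10150 simulated sites pass the quality filters
p-value threshold from the drift null: 1.045e-11
experimental SNPs below it: 33  (empirical FDR 0.209)
top-100 candidates by planted class: {'additive': 65, 'overdominant': 20, 'neutral': 15}
```

Of 10 150 simulated SNPs (100 planted additive at s = 0.1, 50 planted
overdominant, the rest neutral), 33 clear the drift-calibrated threshold
with an estimated one-in-five false discoveries, and the top-100 candidate
list is dominated by the planted loci — the 15 neutral entries are the
drift tail the empirical FDR exists to quantify.

The same pipeline runs from the shell on sync files:

```
erps synth --n-snps 100000 --ne 200 --plant additive:100:s=0.1 --seed 3 -o synth/
erps call-snps --sync synth/experiment.sync -o snps.tsv
erps cmh --snps snps.tsv --contrast B:E -o cmh_BE.tsv
erps simulate-null --base snps.tsv --ne 200 --contrast B:E --seed 42 -o sim.tsv
erps fdr --exp cmh_BE.tsv --sim sim.tsv --top-fraction 1e-5
erps run --config experiment.yaml -o results/   # everything, with a manifest
```

## Layout

| module | role |
|---|---|
| `erps.sync_io` | sync/pileup parsing, BED/GFF masks, indel masking |
| `erps.snp_calling` | quality filters, SNP tables, π windows, heterozygosity |
| `erps.cmh` | CMH statistic and per-SNP scans |
| `erps.drift` | Wright–Fisher null, empirical thresholds and FDR |
| `erps.ne` | temporal (moment) Ne estimation with Pool-Seq corrections |
| `erps.trajectories` | candidates, trajectory shapes, fixation, overlap, decay |
| `erps.enrichment` | feature annotation, χ²/region tests, GO SNP-permutation |
| `erps.synth` | synthetic experiments with planted selection + truth tables |
| `erps.pipeline` / `erps.cli` | one-config orchestration, `erps` command |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
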