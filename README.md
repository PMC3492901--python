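# divscan

Per-gene nucleotide diversity and neutrality-outlier scans for haploid
resequencing alignments, aimed at candidate-gene studies in conifers and
other non-model plants where amplicons are Sanger-resequenced from haploid
megagametophyte tissue (phased sequences, no heterozygous calls) and a
related reference species serves as the outgroup.

## What it computes

For each gene alignment (ingroup rows + outgroup rows over the same
columns) the package:

1. masks primer-annealing flanks, then removes every column containing
   missing data, an indel, or more than two ingroup alleles
   (infinite-sites filter);
2. estimates diversity and divergence: segregating sites *S*, pairwise
   diversity θ̂_π, Watterson's θ̂_W = S/(a₁L) with a₁ = Σ_{i<n} 1/i,
   outgroup divergence D_xy, per-category π and θ_W over noncoding /
   synonymous / nonsynonymous / silent sites (Nei–Gojobori fractional site
   counting), and K_a/K_s;
3. computes four neutrality statistics — Tajima's *D*, Fay & Wu's
   normalized *H* (Zeng et al. 2006 normalization, outgroup-polarized),
   Ewens–Watterson homozygosity *F* = Σp_k², and Kelly's Z_nS (mean
   pairwise r²) — with empirical P-values from a built-in Hudson-style
   coalescent simulator under the standard neutral model, conditional on
   the gene's sample size and observed θ_π;
4. applies the compound DHEW test (Zeng et al. 2007): an adjusted
   per-component level P* is calibrated by simulation so that the joint
   event {P_D ≤ P*, P_H ≤ P*, P_EW-upper ≤ P*} has probability *a* under
   neutrality, and a gene is an outlier only when all three components
   clear it (one-SNP genes are excluded);
5. summarizes species × gene-category cells with across-locus bootstrap
   means and 95% percentile confidence intervals, compared by interval
   overlap.

A first-class synthetic-data generator emits study-shaped inputs
(coalescent genes mapped onto random sequences, an outgroup at configured
divergence, injected missing/indel/triallelic defect columns, and a
star-tree sweep caricature for power checks), so the whole pipeline is
testable without any sequence downloads.

## Worked example

```python
from divscan import NeutralityScan, RunConfig, StudyConfig, generate_study

cfg = StudyConfig(seed=21)          # four-species study-shaped defaults
generate_study(cfg, "study")        # FASTA + annotations + manifest + truth

rc = RunConfig(seed=2, reps_single=1000, reps_dhew=2000, a=0.05,
               bootstrap_reps=2000)
scan = NeutralityScan.from_manifest("study/manifest.tsv", rc)
results = scan.fit()
print(results.summary())
results.to_tsv("out")               # five deterministic TSV tables
```

On a small two-species synthetic study (seed 2, reduced replicate counts)
the summary prints, per species × category cell, the gene count, percent
polymorphic, and bootstrap-CI'd means, e.g.:

```
species  category  n_genes  percent_polymorphic  theta_pi_mean  theta_pi_ci_low  theta_pi_ci_high  theta_w_mean  dxy_mean
    SpA candidate        6                  100       0.005154          0.00282          0.007331       0.00502   0.04954
    SpB candidate        6                66.67       0.001621        0.0004994          0.002722      0.001463   0.02664
```

Here `theta_pi_mean` ≈ the configured per-site θ of each synthetic species
(0.006 and 0.003), the CI half-widths reflect the across-locus coalescent
variance at 6 genes, and `dxy_mean` recovers the configured outgroup
divergence. The compound-test table (`outliers.tsv`) lists per-gene P_D,
P_H, P_EW, P_Zns (all lower-tail), the calibrated P*, and the outlier
call; on neutral input the outlier percentage stays near the chosen level
*a*.

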