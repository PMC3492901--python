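# Methods

## Data model and filtering

Input is one aligned FASTA per gene: ≥ 2 haploid ingroup sequences plus
≥ 1 outgroup row over the same columns, with optional primer intervals
(TSV, 0-based half-open) and optional coding intervals with a frame
offset.  Because the sequences come from haploid tissue, IUPAC ambiguity
codes are treated as missing (`N`) rather than as heterozygous calls.

Primer masking keeps the interior `[fwd_end, rev_start)` and replaces
everything else with `N`.  Site filtering then removes, with precedence
primer > indel > missing > infinite-sites, every column that is
primer-masked, contains a gap or `N` in any ingroup row, or carries more
than two distinct ingroup nucleotides.  The infinite-sites rule counts
*ingroup* alleles only: a third allele seen only in the outgroup leaves
the site in the analysis but blocks its polarization.  Statistics
therefore always operate on a complete, at-most-biallelic matrix, and no
missing-data policy is needed for haplotype-based statistics.

The outgroup is collapsed to a strict-majority consensus per column
(> half of the non-gap, non-`N` outgroup characters; ties give `N`).
Columns with an unresolved consensus are excluded from divergence and
polarization and the denominators renormalized — the treatment of such
columns is a design choice here, made explicit because alternatives
(counting them as missing ingroup data) would shrink L.

## Estimators

* θ̂_π: Σ over all n(n−1)/2 pairs of per-pair differences, divided by the
  pair count and by L (the unbiased pairwise form).
* θ̂_W: S/(a₁L), a₁ = Σ_{i=1}^{n−1} 1/i.
* D_xy: mean over ingroup rows of (differences to the outgroup consensus
  / usable sites).  Averaging over sampled rows rather than
  consensus-to-consensus uses all the data; no multiple-hit correction is
  applied, so configured divergences should stay ≲ 0.1.
* Site categories: within codons, a polymorphic site is synonymous iff
  every segregating allele substituted into the ingroup-consensus codon
  context leaves the amino acid unchanged (a change to a stop codon is
  nonsynonymous).  Fractional site counts are Nei–Gojobori: each coding
  position contributes (synonymous single-nucleotide changes)/3 to the
  synonymous-site total.  Codons with an untranslatable consensus context
  (N, or a stop) and partial codons at interval edges are
  `mixed_excluded` and leave all totals.  For codons with several
  segregating sites the enum label is assigned in consensus context
  (deterministic); full pathway averaging — all orderings of the changes,
  stop-passing paths excluded — is used where it matters numerically,
  i.e. in K_a/K_s difference counting.  Such codons are vanishingly rare
  at the diversity levels this package targets (θ ≈ 0.005 over 3-bp
  windows).  This counting style can differ in the third decimal from
  libsequence's (Comeron-style) counting; the deviation is accepted and
  confined to category denominators.
* K_a/K_s compares the ingroup consensus against the outgroup consensus
  over retained coding positions of codons where both codons are fully
  resolved sense codons; site denominators accumulate over exactly the
  same positions so numerator and denominator stay matched.  Ratios with
  zero denominators are NA, and raw difference/site counts are carried
  alongside because small-denominator ratios are unstable.

## Neutrality statistics

Tajima's D uses the 1989 constants.  Fay & Wu's H is the normalized
version: numerator θ_π − θ_L with θ_L = Σ i·S_i/(n−1) over polarizable
sites, variance per Zeng et al. (2006) with θ̂ = S/a₁ and
θ̂² = S(S−1)/(a₁²+a₂), S restricted to polarizable sites; the raw
numerator is exposed for debugging.  When sites cannot be polarized both
θ_π and θ_L are computed over the polarizable subset, so dropping
unpolarizable sites never moves only one term.  F is haplotype
homozygosity over distinct filtered rows; Z_nS is the mean squared
column correlation (identical to r² = D²/(p(1−p)q(1−q)) and
label-invariant).

P-value convention: all four reported P-values are lower-tail
P(stat_sim ≤ stat_obs) with the (+1)/(+1) estimator, so excess
homozygosity appears as P_EW near 1.  The choice is deliberate and
matches how compound-test component directions are usually tabulated;
the homozygosity-excess direction enters the DHEW rule as the directly
computed upper tail.

## Coalescent nulls

The simulator is the standard Hudson construction in 2N time units:
waiting time Exp(k(k−1)/2), uniform pair merge, Poisson(θ_locus/2 ×
total length) mutations placed on branches proportionally to length,
infinite sites.  This gives E[S] = θ_locus·a₁ exactly — the same product
as ms's 4N-units/θ-rate convention, just factored differently.  Nulls are
simulated with no recombination (conservative for Z_nS) and per-gene
conditioning on (n, θ_locus = θ̂_π × L); a fixed-S mode exists behind a
flag for sensitivity analysis, but conditioning on observed θ_π is the
default convention here.  H nulls use the simulator's true
ancestral states (perfect polarization).  Null replicates where a
statistic is undefined (S = 0 for D; S < 2 for Z_nS) are recorded as NA
and excluded from the reference distribution.

## DHEW calibration

Two *independent* replicate sets at (n, θ_locus) are drawn: a reference
set defining the component null distributions and a calibration set on
which the three one-sided component P-values (D lower, H lower, F upper)
are evaluated; using independent substreams avoids the optimism of
scoring a replicate against a null that contains it.  P* is the largest
threshold p′ with empirical P(max of the three component P-values ≤ p′)
≤ a, floored at max(a, 1/(reps+1)); replicates with S ≤ 1 are dropped
from calibration, mirroring the exclusion of one-SNP genes from outlier
calling.  A gene is an outlier iff all three components are ≤ P*.  The
defaults (a = 0.0001, 50,000 replicates) sit at the resolution floor of
the calibration — by design, since a joint level of 10⁻⁴ is what makes
single-gene outlier calls defensible without further multiple-testing
correction.  Verification runs use a = 0.05 with 5,000 replicates: at
that size the non-binomial noise of the calibrated rejection rate (sd ≈
0.003, dominated by P*-quantile and reference-set error) is small
against the ±0.013 band of a 2,000-gene binomial check, which is not
true at 2,000–3,000 replicates.

## Bootstrap comparisons

Species × category means of per-gene statistics are bootstrapped across
loci (resample genes with replacement, percentile CI; BCa is deliberately
not used).  Two cells differ significantly only when their closed
intervals are disjoint; touching endpoints count as overlap.
Monomorphic genes enter the means as θ = 0 by default (the natural
reading when whole-study gene counts are the denominators); a flag
excludes them instead.

## Synthetic data

The generator's defaults are the study conditions: four species with
per-site θ of 0.0059/0.0077/0.0025/0.0082, outgroup divergence
0.0873/0.0829/0.0378/0.0157, mean sample sizes 5/3/6/4 (clipped to
3–12), amplicon lengths ~N(385, 40²) clipped to 300–450 bp, 0.8 coding
fraction, annotation available for 80% of candidate and 50% of control
genes, and per-column defect rates 0.02/0.01/0.005 for
missing/indel/triallelic injections.  `outgroup_divergence` means the
expected per-site tip-to-outgroup divergence: the outgroup branch
receives Poisson((d − θ_site(1 − 1/n))·L) substitutions because the
ingroup lineages contribute θ_site(1 − 1/n) of divergence on average.
Outgroup substitutions may coincide with polymorphic sites, which
exercises the unpolarizable-site path at a low, divergence-dependent
rate.  The `star_sweep` scenario is a caricature, not a sweep model: a
swept clade of n−1 near-identical tips under a long stem plus one
escaped lineage, which produces the high-frequency-derived,
high-homozygosity, negative-D signature the compound test targets.
What passing tests on these data do *not* show: robustness to real
demography, recombination, alignment error, or base-composition bias —
none of which the generator emulates.

## Numerical and test design choices

* Percentages round half-up (decimal arithmetic), not banker's style.
* Empirical P-values use (+1)/(+1), so P = "<1/(reps+1)" never reaches 0.
* Reproducibility: one run seed; each gene's simulations use a substream
  keyed by (seed, crc32(gene_id)), each species-cell bootstrap by
  (seed, crc32("boot|species|category")); reruns are byte-identical.
* The aggregated unfolded SFS check uses per-class z-scores with
  across-replicate empirical variance rather than a Pearson χ² on summed
  counts: summed counts are mixed-Poisson overdispersed, and the naive χ²
  rejects a correct simulator (measured inflation ≈ 5–7× the dof).
* Verification problem sizes (package's own choices): 800 genes for
  estimator-consistency means (SE ≈ 2.5% of θ against a 5% band), 5,000
  replicates for null centering, 20,000 for closed-form E[S], 5,000
  calibration replicates / 2,000 genes for DHEW type-I, 1,000 outer
  datasets × 600 resamples for bootstrap coverage.
* msprime appears in the test suite only as an independent oracle for
  the hand-written simulator (matched time scales: ploidy 1, N = 1,
  mutation rate θ/2 on unit sequence length).

## Known limitations

* No Jukes–Cantor correction on divergence; D_xy and K_a/K_s saturate
  above ~0.1 substitutions/site.
* Minus-strand coding intervals are not supported (amplicons are assumed
  EST-oriented).
* The compound test's calibration is per gene; at paper-scale settings
  (50,000 replicates × hundreds of genes) a run is hours of CPU.  There
  is no caching across genes because θ_locus differs per gene.
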