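# Methods

## The model

`autozyg` estimates an individual's genomic inbreeding coefficient *f* —
the fraction of their autosomal genome that is homozygous-by-descent
(HBD), i.e. where the two genome copies descend from the same ancestral
copy through an inbreeding loop — from unphased genotypes and a genetic
map.

The HBD process along a chromosome is modelled as a two-state hidden
Markov chain over {nonHBD, HBD} indexed by genetic position.  Two
parameters govern the chain: *f*, the stationary probability of the HBD
state, and a rate *a* per cM, with expected HBD segment length
1/(*a*(1−*f*)) cM.  Over a genetic distance *d* the transition
probabilities are

```
P(HBD    → HBD) = e^(−a·d) + f·(1 − e^(−a·d))
P(nonHBD → HBD) = f·(1 − e^(−a·d))
```

so (1−*f*, *f*) is the stationary distribution and the chain restarts
from it at every chromosome start (encoded as an infinite predecessor
distance).

Emissions depend on the marker's alt-allele frequency *p*: Hardy-Weinberg
genotype probabilities {(1−p)², 2p(1−p), p²} in the nonHBD state; allelic
probabilities {1−p, 0, p} in the HBD state, mixed with the HWE
distribution at a genotyping-error rate ε (default 10⁻³, configurable in
[0, 0.05]).  The mixture keeps isolated heterozygotes from zeroing the
likelihood of a long HBD stretch; the exact error parameterisation is a
documented convention of this package.  Missing genotypes emit
probability 1 in both states.

## Submaps and aggregation

Single-marker emissions assume linkage equilibrium, so the model is never
run on a dense map.  The genome is cut into regions delimited by
recombination hotspots (map intervals with intensity above 10 cM/Mb by
default; consecutive hot intervals merge into one separator, and a marker
physically inside a separator belongs to the downstream region).  Many
random sparse submaps are drawn — by default 100 submaps of 2 markers per
region, drawn uniformly without replacement, independent across submaps
and regions, reproducible under a seed.

Per individual and submap, (*f*, *a*) are fitted by maximum likelihood
(scaled forward algorithm).  Per individual the pipeline then reports:

* **f_median** — the median of the per-submap *f̂* after discarding fits
  with *â* > 1 (implausibly short segments: the signature of residual LD
  or of allele frequencies that do not match the individual's ancestry);
* **Q-score** — the number of surviving submaps; an estimate with Q-score
  ≤ q_min (default 50 of 100 submaps; scaled proportionally when fewer
  submaps are used) is flagged low quality;
* **LRT p-value** — per retained submap, Λ = 2(ln L(f̂,â) − ln L(f₀,â₀))
  clipped at 0, with f₀ = 0.001 and the null profile maximised over *a*;
  the per-submap p-value uses the boundary mixture ½χ²₀ + ½χ²₁ (the
  alternative is one-sided in *f*), and the reported p is the **median**
  of per-submap p-values — the same robust-combination philosophy as the
  median-f.  A mean-Λ combiner was considered; the median is used for
  symmetry with the point estimate and is the documented convention.
* **mating-type posteriors** — likelihoods of the genotypes under fixed
  parameters for each parental mating type: AV (f=1/8, a=0.05), 2×1C
  (1/8, 0.06), 1C (1/16, 0.06), 2C (1/64, 0.08) and OUT (0.001, 1.0),
  where each *a* is loop-meioses/100 per cM (5, 6, 6 and 8 meioses; the
  AV vs 2×1C tie in expected f is broken by the rate).  Per retained
  submap the posterior under a uniform prior is computed and the final
  posterior is the average; the most likely type is the argmax.
* **inbred call** — LRT p < 0.05 **and** most likely type ≠ OUT.

An individual is excluded from population summaries (but reported) when
low quality.  Reference-panel construction removes, on top of that, one
member of each supplied relationship pair (greedily dropping the member
that resolves the most pairs, ties by lexicographic id) and individuals
whose most likely type is AV/2×1C (panel A) or additionally 1C (panel B,
built from panel A so B ⊆ A).

## Numerical choices

* Forward/backward recursions are scaled (not log-space) with a numba
  JIT; a pure-Python fallback keeps the package importable without numba.
* ML fit: Nelder-Mead on (logit(f/0.5), log a) from three fixed starts
  ((0.05, 0.05), (0.01, 0.5), (0.2, 0.1)), f ∈ [0, 0.5],
  a ∈ (10⁻⁴, 4] (segments ≥ 0.25 cM), likelihood tolerance 10⁻⁶, plus a
  one-dimensional profile over f at a reference rate a = 0.06.  When f̂ → 0
  the likelihood is flat in *a* and a naive argmax lands at an arbitrary
  rate, often past the a > 1 retention filter — which would discard most
  submaps of perfectly well-behaved outbred individuals.  Among candidate
  optima within 0.1 log-likelihood units (practically indistinguishable)
  the fit with the smallest *a* — fewest, longest segments — is therefore
  reported.  Genuine wrong-frequency pathologies (e.g. an individual whose
  ancestry does not match the supplied frequencies) still produce decisive
  a > 1 fits and low Q-scores, which is the intended diagnostic.
* The null profile over *a* uses bounded Brent on log a.
* Frequencies outside (0,1) carry no information and the affected markers
  are treated as missing for that frequency set.
* The Hardy-Weinberg filter uses the plain exact conditional test (no
  mid-p), two-sided by summing all heterozygote-count configurations with
  probability ≤ the observed one.  Whether the original pipeline used the
  exact or the χ² test is not documented; the exact test is the
  reproducible choice and is cross-checked against full enumeration in
  the tests.
* Genetic positions are interpolated linearly between map anchors,
  extrapolated at the terminal interval's rate and floored to be
  non-decreasing and non-negative.  Physical positions are 1-based.

## The synthetic-data generator

The generator emulates a two-ancestry admixture design with exact truth:

* **Genome** — n_chrom chromosomes (default 10 × 150 cM) with uniform
  background intensity 1 cM/Mb, punctuated every region_spacing_cM
  (default 0.25 cM, i.e. ~6,000 regions genome-wide) by 1-kb hotspots at
  20 cM/Mb; a pool of markers_per_region (default 5) markers uniform per
  region.
* **Panels** — ancestral frequencies uniform on [0.1, 0.9]; population
  frequencies Beta-distributed around them (Balding-Nichols) at a target
  Fst (default 0.15, the CEU-YRI scale); 232 and 226 independent
  haplotypes per population by default.  Realised Hudson Fst is checked
  against the target in the tests.
* **Pedigrees** — canonical genealogies for AV, 2×1C, 1C-4C and OUT; a
  degree-n cousin pedigree has 2n+2 founders (8 founder genome copies for
  1C).  Expected offspring f per pedigree is verified against a recursive
  kinship oracle in the tests.
* **Gene dropping** — each founder is assigned an origin population
  (probability ½ each, or forced for homogeneous samples); meioses follow
  Haldane's model (Poisson crossovers, mean L/100 per chromosome, uniform
  positions in cM, no interference); reference haplotypes are drawn
  without replacement per chromosome.  HBD segments are the maximal
  intervals where both proband copies descend from the same founder copy;
  f_true is their cM length over the marker-spanned genome length, and
  adm_a the diploid cM fraction carried on population-A founder copies.
* A replicate is 300 individuals (6 1C, 6 2C, 18 3C, 30 4C, 240 OUT) and
  a study is 100 such replicates by default.

What the generator does **not** emulate: background LD within
populations (sites are independent given population frequencies — the
submap machinery is therefore exercised, but its LD-thinning purpose is
moot on synthetic data), mutation, genotyping error, phasing error, and
realistic per-locus Fst heterogeneity (every locus shares the target
Fst, which makes pooled-frequency misspecification somewhat harsher than
in real admixed panels).  Passing tests therefore demonstrate the
statistical machinery, not robustness to LD or call errors.

## Scaled study sizes

The estimator-comparison study (tests and `scripts/acceptance.py`) runs a
scaled-down version of the full design: 10 replicates of 300 individuals
instead of 100, on a human-autosome-scale synthetic genome (22
chromosomes × 160 cM ≈ 3,520 cM; 0.58-cM regions, ~6,070 genome-wide) with
20 submaps of ~12,000 markers (the full study's submaps held ~14,000 SNPs
on ~3,540 cM), sample-estimated frequencies, and a Q-score floor of 10 of
20 submaps.  One individual per inbred mating type with f_true > 0 plus
one outbred individual is drawn per replicate, so RMSE cells hold ≤ 10
individuals and are themselves noisy; the binding cell is 1C, where the
residual error mixes the intrinsic gap between the chain-parameter MLE
and the realised HBD fraction of a finite genome with mild
pooled-frequency bias for ancestry-extreme individuals.

The parameter-recovery check runs the fitter on data simulated from the
HMM itself at (f = 1/16, a = 0.06) with 10,000 markers laid out at 5-cM
spacing on 20 chromosomes: that geometry yields ~100 independent HBD
segments, so the realised HBD fraction — which is what the MLE estimates
— concentrates within the ±0.02 window being asserted.  On denser, shorter
maps the same estimator is unbiased but the window is dominated by
realised-fraction variance rather than estimation error.

## Known limitations

* The reported f̂ is the chain-parameter MLE, not a posterior-decoded
  realised fraction; on short genomes the two can differ by ~0.01 for
  first-cousin offspring even with perfect segment detection.
* Mating-type classification uses fixed per-type rates a_m; FSuite-style
  per-type refitting of *a* is not implemented.
* Pairwise relationship inference is out of scope: panel construction
  takes relationship pairs as input.
* No X chromosome, no multi-class HBD models, no haplotype-based HBD.
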