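# autozyg

Homozygosity-by-descent (HBD) inference for population-genetic samples:
per-individual genomic inbreeding coefficients from unphased SNP
genotypes, parental mating-type classification, unrelated/outbred panel
construction — and a pedigree gene-dropping simulator with exact truth to
validate all of it on admixed samples.

The package is aimed at anyone who needs to know *who is inbred* in a
sequencing panel (quality control, association-study design, reference
panel curation) or wants to study how inbreeding estimators behave under
admixture.

## The model

The offspring of related parents carries HBD segments: stretches where
its two genome copies descend from the same ancestral copy.  `autozyg`
models the HBD status along each chromosome as a two-state hidden Markov
chain with parameters *f* (the inbreeding coefficient, the stationary HBD
probability) and *a* (a rate per cM; 1/(*a*(1−*f*)) is the expected HBD
segment length in cM):

    P(HBD    → HBD) = e^(−a·d) + f·(1 − e^(−a·d))
    P(nonHBD → HBD) = f·(1 − e^(−a·d))

Emissions are Hardy-Weinberg genotype probabilities outside HBD and
allelic probabilities {1−p, 0, p} inside, with a small error mixture.
Because single-marker emissions assume linkage equilibrium, the model is
run on many random sparse *submaps* (a couple of markers per
recombination-hotspot-delimited region); per individual the pipeline
reports the median *f̂* over submaps after discarding fits with *â* > 1,
a Q-score (number of surviving submaps), a likelihood-ratio test of
*f* ≠ 0.001, and posterior probabilities of parental mating types
(avuncular, double first cousin, first cousin, second cousin, outbred).

A single-point moment estimator (excess homozygosity, optionally with
ancestry-weighted individual allele frequencies) is included as the
classical comparator, and `autozyg.simulate` gene-drops admixed samples
through canonical cousin pedigrees over Balding-Nichols haplotype panels,
tracking every founder genome copy so each simulated individual carries
its exact realised f and ancestry.

## Worked example

`examples/02_estimate_inbreeding.py` simulates a homogeneous sample of 50
individuals (4 first-cousin, 4 second-cousin offspring, 42 outbred) on a
synthetic 1,500-cM genome and runs the full pipeline with 10 submaps:

```
3000 hotspot-delimited regions; submaps of ~6000 markers

      id mating_type  f_true  f_median  q_score  lrt_p best_type  inbred
 r0_1C_0          1C  0.0434    0.0449       10 0.0000        1C    True
 r0_1C_3          1C  0.0835    0.0970       10 0.0000      2x1C    True
 r0_2C_0          2C  0.0159    0.0231       10 0.0029        2C    True
 r0_2C_1          2C  0.0060    0.0075       10 0.0571        2C   False
r0_OUT_0         OUT  0.0000    0.0000       10 0.4433       OUT   False
```

(abridged).  Each first-cousin offspring's `f_median` tracks its realised
`f_true` (the pedigree expectation is 1/16, but any one individual's
realised value scatters widely around it); the LRT rejects f = 0.001 for
the inbred individuals; `r0_2C_1` shows why second-cousin offspring are
harder: its realised f is only 0.006 and the test cannot call it.
Outbred individuals keep `f_median` ≈ 0, full Q-scores and type OUT.

The other examples cover simulation with truth (`01`), the
multi-point-vs-single-point comparison under admixture (`03`) and
unrelated/outbred panel construction (`04`).  A thin CLI wraps the same
stages: `autozyg simulate | estimate | evaluate | panel` (see
`autozyg --help`).

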