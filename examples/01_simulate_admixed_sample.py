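"""Simulate an admixed sample with exact inbreeding and ancestry truth.

Builds a small hotspot-punctuated genome, two Balding-Nichols reference
panels at Fst 0.15 (European-like and African-like stand-ins), and
gene-drops one sample containing first- to fourth-cousin offspring plus
outbred individuals.  Every individual carries its truth: realised
inbreeding coefficient f_true (fraction of the genome that is
homozygous-by-descent, in cM) and ancestry proportion adm_a.
"""

import numpy as np

from autozyg import (
    ReplicateSpec,
    SyntheticGenomeConfig,
    generate_map,
    generate_panel,
    simulate_replicate,
)

rng = np.random.default_rng(0)
genome = SyntheticGenomeConfig(
    n_chrom=6, chrom_length_cM=120.0, region_spacing_cM=0.5, markers_per_region=4
)
gmap, markers = generate_map(genome, rng)
panel = generate_panel(markers, gmap, fst=0.15, rng=rng)
print(f"genome: {genome.n_chrom} chromosomes, {len(markers)} markers")

spec = ReplicateSpec(
    counts={"1C": 6, "2C": 6, "3C": 18, "4C": 30, "OUT": 240}, n_replicates=1
)
g, truth, individuals = simulate_replicate(spec, panel, rng)
print(f"sample: {g.n_individuals} individuals x {g.n_markers} markers\n")

summary = truth.groupby("mating_type").agg(
    n=("f_true", "size"),
    mean_f_true=("f_true", "mean"),
    mean_segments=("n_segments", "mean"),
    mean_ancestry_a=("adm_a", "mean"),
)
print(summary.round(4))
print(
    "\nmean_f_true should sit near the pedigree expectations "
    "1/16, 1/64, 1/256, 1/1024 and 0; mean_ancestry_a near 1/2 "
    "(founder origins are fair coin flips)."
)
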