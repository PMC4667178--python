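import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from autozyg.simulate import (
    SyntheticGenomeConfig,
    generate_map,
    generate_panel,
)


@pytest.fixture(scope="session")
def small_genome():
    """A small synthetic genome: 4 chromosomes x 60 cM, 0.5-cM regions."""
    cfg = SyntheticGenomeConfig(
        n_chrom=4, chrom_length_cM=60.0, region_spacing_cM=0.5, markers_per_region=4
    )
    rng = np.random.default_rng(2024)
    gmap, markers = generate_map(cfg, rng)
    return gmap, markers


@pytest.fixture(scope="session")
def small_panel(small_genome):
    gmap, markers = small_genome
    rng = np.random.default_rng(99)
    return generate_panel(
        markers, gmap, fst=0.15, rng=rng, pop_sizes={"POPA": 80, "POPB": 80}
    )


TOY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tI1\tI2\tI3
1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t250\t.\tC\tT,G\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0
1\t400\t.\tG\tA\t.\tPASS\t.\tGT\t./.\t0/0\t1/1
X\t500\t.\tT\tC\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1
2\t150\t.\tT\tC\t.\tPASS\t.\tGT\t0/1\t0/1\t0/0
2\t900\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\t1/1\t1/1
1\t50\t.\tG\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture
def toy_pops():
    return {"I1": "P1", "I2": "P1", "I3": "P2"}
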