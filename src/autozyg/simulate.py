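"""Pedigree gene-dropping simulator for admixed samples with exact truth.

The generator emulates the ingredients of an admixture simulation study
for inbreeding estimators:

* a hotspot-punctuated genetic map (uniform background intensity with
  short high-intensity separators) carrying a dense marker panel;
* two ancestral haplotype reference panels (stand-ins for European- and
  African-ancestry panels) built under the Balding-Nichols model at a
  tunable differentiation Fst;
* canonical inbreeding genealogies (avuncular, double-first-cousin and
  first- to fourth-cousin matings, plus outbred), through which founder
  genomes are dropped with Haldane (no-interference) recombination.

Each pedigree founder is independently assigned a population origin with
probability 1/2 and receives reference haplotypes drawn without
replacement per chromosome from that population's panel.  Because founder
genome copies are tracked exactly, every simulated individual carries its
truth: the HBD segments (both proband copies descending from the same
founder copy), the realised inbreeding coefficient f_true (HBD cM length
over total marker-spanned cM length) and the ancestry proportion adm_a
(fraction of the diploid genome, in cM, carried on population-A founder
copies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .maps import GeneticMap, MAP_COLUMNS

POP_A = "POPA"  # CEU-like stand-in
POP_B = "POPB"  # YRI-like stand-in

SIM_TYPES = ("AV", "2x1C", "1C", "2C", "3C", "4C", "OUT")

EXPECTED_F = {
    "AV": 1 / 8,
    "2x1C": 1 / 8,
    "1C": 1 / 16,
    "2C": 1 / 64,
    "3C": 1 / 256,
    "4C": 1 / 1024,
    "OUT": 0.0,
}


# ---------------------------------------------------------------------------
# Synthetic genome: hotspot-punctuated map + marker panel


@dataclass
class SyntheticGenomeConfig:
    """Geometry of the synthetic genome.

    Defaults give 10 chromosomes of ~150 cM cut into 0.25-cM regions by
    narrow hotspots, i.e. ~6,000 regions genome-wide, so that 2-marker-per-
    region submaps carry ~12,000 SNPs.  Background intensity is 1 cM/Mb and
    hotspots are 1-kb intervals at 20 cM/Mb, above the usual 10 (and 13)
    cM/Mb separator thresholds.
    """

    n_chrom: int = 10
    chrom_length_cM: float = 150.0
    region_spacing_cM: float = 0.25
    markers_per_region: int = 5
    hotspot_width_bp: int = 1000
    hotspot_rate_cM_per_Mb: float = 20.0
    background_rate_cM_per_Mb: float = 1.0


def generate_map(
    cfg: SyntheticGenomeConfig, rng: np.random.Generator
) -> tuple[GeneticMap, pd.DataFrame]:
    """Build the synthetic map and its marker table.

    Returns (map, markers) where markers has columns
    ``chrom, pos_bp, pos_cM, ref, alt`` sorted by position.
    """
    points = []
    marker_rows = []
    hotspot_cM = cfg.hotspot_rate_cM_per_Mb * cfg.hotspot_width_bp / 1e6
    region_bp = int(cfg.region_spacing_cM / cfg.background_rate_cM_per_Mb * 1e6)
    n_regions = max(1, round(cfg.chrom_length_cM / cfg.region_spacing_cM))
    for c in range(1, cfg.n_chrom + 1):
        chrom = str(c)
        bp, cm = 1, 0.0
        points.append((chrom, bp, cm, cfg.background_rate_cM_per_Mb))
        for r in range(n_regions):
            # markers uniform inside the background region
            u = np.sort(rng.random(cfg.markers_per_region))
            for x in u:
                marker_rows.append(
                    (chrom, bp + int(x * region_bp), cm + x * cfg.region_spacing_cM)
                )
            bp += region_bp
            cm += cfg.region_spacing_cM
            if r < n_regions - 1:
                points.append((chrom, bp, cm, cfg.hotspot_rate_cM_per_Mb))
                bp += cfg.hotspot_width_bp
                cm += hotspot_cM
                points.append((chrom, bp, cm, cfg.background_rate_cM_per_Mb))
        points.append((chrom, bp, cm, 0.0))
    gmap = GeneticMap(pd.DataFrame(points, columns=MAP_COLUMNS))
    markers = pd.DataFrame(marker_rows, columns=["chrom", "pos_bp", "pos_cM"])
    markers["ref"] = "A"
    markers["alt"] = "G"
    markers = markers.drop_duplicates(["chrom", "pos_bp"]).reset_index(drop=True)
    return gmap, markers


# ---------------------------------------------------------------------------
# Reference panels (Balding-Nichols)


@dataclass
class ReferencePanel:
    """Phased haplotype panels for the ancestral populations, with the
    genome they live on."""

    markers: pd.DataFrame  # chrom, pos_bp, pos_cM, ref, alt
    gmap: GeneticMap
    haplotypes: dict[str, np.ndarray]  # pop -> (n_hap, n_markers) uint8
    fst: float

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def populations(self) -> list[str]:
        return list(self.haplotypes)

    def panel_frequencies(self, pop: str) -> np.ndarray:
        """Alt-allele frequencies estimated on the panel haplotypes."""
        return self.haplotypes[pop].mean(axis=0)

    def chrom_lengths_cM(self) -> dict[str, float]:
        pts = self.gmap.points
        return {
            str(c): float(sub["cM"].max()) for c, sub in pts.groupby("chrom", sort=False)
        }


def generate_panel(
    markers: pd.DataFrame,
    gmap: GeneticMap,
    fst: float,
    rng: np.random.Generator,
    pop_sizes: dict[str, int] | None = None,
) -> ReferencePanel:
    """Balding-Nichols haplotype panels at a target differentiation.

    Ancestral frequencies are uniform on [0.1, 0.9]; each population's
    frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral p, and
    haplotype alleles are independent Bernoulli draws per site.
    """
    if not 0 < fst < 0.5:
        raise ValueError("fst must be in (0, 0.5)")
    pop_sizes = pop_sizes or {POP_A: 232, POP_B: 226}
    m = len(markers)
    p_anc = rng.uniform(0.1, 0.9, size=m)
    lam = (1 - fst) / fst
    haplotypes = {}
    for pop, n_hap in pop_sizes.items():
        p_pop = rng.beta(p_anc * lam, (1 - p_anc) * lam)
        p_pop = np.clip(p_pop, 1e-6, 1 - 1e-6)
        haplotypes[pop] = (rng.random((n_hap, m)) < p_pop).astype(np.uint8)
    return ReferencePanel(markers=markers, gmap=gmap, haplotypes=haplotypes, fst=fst)


def realized_fst(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Hudson-style Fst between two haplotype panels (ratio of averages)."""
    n1, n2 = hap_a.shape[0], hap_b.shape[0]
    p1, p2 = hap_a.mean(axis=0), hap_b.mean(axis=0)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.mean() / den.mean())


# ---------------------------------------------------------------------------
# Genealogies


@dataclass
class Genealogy:
    """A pedigree as an ordered member list; entry i is (father, mother)
    indices or None for founders, parents precede children, the proband is
    the last member."""

    label: str
    parents: list[tuple[int, int] | None]

    @property
    def founders(self) -> list[int]:
        return [i for i, p in enumerate(self.parents) if p is None]

    @property
    def n_founder_copies(self) -> int:
        return 2 * len(self.founders)

    @property
    def proband(self) -> int:
        return len(self.parents) - 1

    @property
    def expected_f(self) -> float:
        return EXPECTED_F[self.label]


def build_genealogy(mating_type: str) -> Genealogy:
    """Canonical genealogy for a mating type.

    Cousin matings of degree n have 2n+2 founders (the shared ancestral
    couple plus 2n married-in spouses): 8 founder genome copies for 1C, 12
    for 2C, 16 for 3C, 20 for 4C; OUT is simply two unrelated founders.
    """
    t = mating_type
    if t == "OUT":
        return Genealogy("OUT", [None, None, (0, 1)])
    if t == "AV":
        # uncle x niece: proband's parents are a child of the ancestral
        # couple and that child's sibling's daughter
        return Genealogy("AV", [None, None, (0, 1), (0, 1), None, (3, 4), (2, 5)])
    if t == "2x1C":
        parents: list[tuple[int, int] | None] = [None, None, None, None]
        c1 = len(parents); parents.append((0, 1))
        c2 = len(parents); parents.append((0, 1))
        d1 = len(parents); parents.append((2, 3))
        d2 = len(parents); parents.append((2, 3))
        p1 = len(parents); parents.append((c1, d1))
        p2 = len(parents); parents.append((c2, d2))
        parents.append((p1, p2))
        return Genealogy("2x1C", parents)
    if t.endswith("C") and t[:-1].isdigit():
        degree = int(t[:-1])
        if degree < 1:
            raise ValueError(f"unknown mating type {mating_type!r}")
        parents = [None, None]  # shared ancestral couple
        tips = []
        for _ in range(2):  # two descent lines
            child = len(parents)
            parents.append((0, 1))
            for _ in range(degree - 1):
                spouse = len(parents)
                parents.append(None)
                nxt = len(parents)
                parents.append((child, spouse))
                child = nxt
            spouse = len(parents)
            parents.append(None)
            tip = len(parents)
            parents.append((child, spouse))
            tips.append(tip)
        parents.append((tips[0], tips[1]))
        return Genealogy(t, parents)
    raise ValueError(f"unknown mating type {mating_type!r}")


# ---------------------------------------------------------------------------
# Gene dropping


@dataclass
class SimTruth:
    """Exact bookkeeping of a simulated individual's genome."""

    hbd_segments: list[tuple[str, float, float]]  # (chrom, start_cM, end_cM)
    f_true: float
    adm_a: float  # diploid genome fraction (cM) of population-A origin


@dataclass
class SimulatedIndividual:
    id: str
    mating_type: str
    genotypes: np.ndarray  # int8, aligned with the panel's markers
    truth: SimTruth


Mosaic = tuple[np.ndarray, np.ndarray]  # (segment start positions cM, copy ids)


def _meiosis(
    hap0: Mosaic, hap1: Mosaic, length_cM: float, rng: np.random.Generator
) -> Mosaic:
    """One Haldane meiosis: Poisson(L/100) crossovers uniform in cM."""
    n_x = rng.poisson(length_cM / 100.0)
    xs = np.sort(rng.uniform(0.0, length_cM, size=n_x))
    cur = int(rng.integers(2))
    haps = (hap0, hap1)
    bounds = np.concatenate(([0.0], xs, [length_cM]))
    starts: list[float] = []
    ids: list[int] = []
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        if hi <= lo:
            cur = 1 - cur
            continue
        s, i = haps[cur]
        j0 = int(np.searchsorted(s, lo, side="right") - 1)
        j1 = int(np.searchsorted(s, hi, side="left"))
        for j in range(j0, j1):
            seg_start = max(float(s[j]), lo)
            if ids and ids[-1] == int(i[j]) and starts[-1] <= seg_start:
                continue  # merge with previous identical segment
            starts.append(seg_start)
            ids.append(int(i[j]))
        cur = 1 - cur
    return np.asarray(starts), np.asarray(ids, dtype=int)


def _drop_pedigree(
    gen: Genealogy, lengths: dict[str, float], rng: np.random.Generator
) -> dict[str, tuple[Mosaic, Mosaic]]:
    """Drop founder copy labels down the pedigree; return the proband's two
    mosaics per chromosome."""
    founders = gen.founders
    copy_id = {m: (2 * k, 2 * k + 1) for k, m in enumerate(founders)}
    out: dict[str, tuple[Mosaic, Mosaic]] = {}
    for chrom, length in lengths.items():
        genomes: list[tuple[Mosaic, Mosaic]] = []
        for m, par in enumerate(gen.parents):
            if par is None:
                c0, c1 = copy_id[m]
                genomes.append(
                    (
                        (np.array([0.0]), np.array([c0])),
                        (np.array([0.0]), np.array([c1])),
                    )
                )
            else:
                fa, mo = par
                genomes.append(
                    (
                        _meiosis(*genomes[fa], length, rng),
                        _meiosis(*genomes[mo], length, rng),
                    )
                )
        out[chrom] = genomes[gen.proband]
    return out


def _overlap_segments(m0: Mosaic, m1: Mosaic, length: float):
    """Yield (start, end, id0, id1) over the joint refinement of two mosaics."""
    bounds = np.unique(np.concatenate((m0[0], m1[0], [length])))
    for k in range(len(bounds) - 1):
        lo, hi = float(bounds[k]), float(bounds[k + 1])
        i0 = int(m0[1][np.searchsorted(m0[0], lo, side="right") - 1])
        i1 = int(m1[1][np.searchsorted(m1[0], lo, side="right") - 1])
        yield lo, hi, i0, i1


def gene_drop(
    gen: Genealogy,
    panel: ReferencePanel,
    rng: np.random.Generator,
    ind_id: str = "",
    p_pop_a: float = 0.5,
) -> SimulatedIndividual:
    """Simulate one individual: origins, recombination, haplotype assignment.

    Each founder is assigned population A with probability ``p_pop_a``
    (both copies of a founder share the origin; 1.0 or 0.0 gives a
    homogeneous pedigree); reference haplotypes are drawn without
    replacement within each chromosome.
    """
    pops = panel.populations
    if len(pops) < 2:
        raise ValueError("panel must carry two populations")
    lengths = panel.chrom_lengths_cM()
    founders = gen.founders
    n_copies = gen.n_founder_copies
    origin_of_founder = (rng.random(len(founders)) >= p_pop_a).astype(int)
    origin_of_copy = np.repeat(origin_of_founder, 2)

    proband = _drop_pedigree(gen, lengths, rng)

    chroms = panel.markers["chrom"].to_numpy()
    pos_cm = panel.markers["pos_cM"].to_numpy()
    m_total = panel.n_markers
    alleles = np.zeros((2, m_total), dtype=np.int8)
    hbd: list[tuple[str, float, float]] = []
    hbd_len = 0.0
    a_len = 0.0
    total_len = 0.0

    for chrom, length in lengths.items():
        sel = np.flatnonzero(chroms == chrom)
        cm = pos_cm[sel]
        span_lo, span_hi = (float(cm[0]), float(cm[-1])) if len(cm) else (0.0, 0.0)
        total_len += max(0.0, span_hi - span_lo)
        # per-chromosome haplotype assignment without replacement
        assign = np.empty(n_copies, dtype=int)
        for pop_idx, pop in enumerate(pops[:2]):
            want = np.flatnonzero(origin_of_copy == pop_idx)
            n_hap = panel.haplotypes[pop].shape[0]
            if len(want) > n_hap:
                raise ValueError(
                    f"panel {pop} exhausted: {len(want)} copies need haplotypes, "
                    f"only {n_hap} available"
                )
            assign[want] = rng.choice(n_hap, size=len(want), replace=False)
        m0, m1 = proband[chrom]
        for which, (starts, ids) in enumerate((m0, m1)):
            ends = np.concatenate((starts[1:], [length]))
            for s, e, cid in zip(starts, ends, ids):
                lo_i = int(np.searchsorted(cm, s, side="left"))
                hi_i = int(np.searchsorted(cm, e, side="left"))
                if hi_i > lo_i:
                    pop = pops[origin_of_copy[cid]]
                    alleles[which, sel[lo_i:hi_i]] = panel.haplotypes[pop][
                        assign[cid], sel[lo_i:hi_i]
                    ]
                if origin_of_copy[cid] == 0:
                    a_len += max(0.0, min(e, span_hi) - max(s, span_lo))
        for lo, hi, i0, i1 in _overlap_segments(m0, m1, length):
            if i0 == i1:
                c_lo, c_hi = max(lo, span_lo), min(hi, span_hi)
                if c_hi > c_lo:
                    # merge with a contiguous previous HBD segment
                    if hbd and hbd[-1][0] == chrom and abs(hbd[-1][2] - c_lo) < 1e-12:
                        hbd[-1] = (chrom, hbd[-1][1], c_hi)
                    else:
                        hbd.append((chrom, c_lo, c_hi))
                    hbd_len += c_hi - c_lo

    f_true = hbd_len / total_len if total_len > 0 else 0.0
    adm_a = a_len / (2 * total_len) if total_len > 0 else 0.0
    genotypes = (alleles[0] + alleles[1]).astype(np.int8)
    return SimulatedIndividual(
        id=ind_id,
        mating_type=gen.label,
        genotypes=genotypes,
        truth=SimTruth(hbd_segments=hbd, f_true=f_true, adm_a=adm_a),
    )


# ---------------------------------------------------------------------------
# Replicates


@dataclass
class ReplicateSpec:
    """Sample composition of the simulation study."""

    counts: dict[str, int] = field(
        default_factory=lambda: {"1C": 6, "2C": 6, "3C": 18, "4C": 30, "OUT": 240}
    )
    n_replicates: int = 100
    rng_seed: int = 0
    p_pop_a: float = 0.5  # per-founder probability of population-A origin

    @property
    def n_individuals(self) -> int:
        return sum(self.counts.values())


def simulate_replicate(
    spec: ReplicateSpec,
    panel: ReferencePanel,
    rng: np.random.Generator,
    replicate: int = 0,
    population: str = "SIM",
) -> tuple[GenotypeMatrix, pd.DataFrame, list[SimulatedIndividual]]:
    """One sample of the configured composition; ids encode replicate,
    mating type and index."""
    genealogies = {t: build_genealogy(t) for t in spec.counts}
    inds: list[SimulatedIndividual] = []
    for t, n in spec.counts.items():
        for i in range(n):
            inds.append(
                gene_drop(
                    genealogies[t],
                    panel,
                    rng,
                    ind_id=f"r{replicate}_{t}_{i}",
                    p_pop_a=spec.p_pop_a,
                )
            )
    calls = np.vstack([ind.genotypes for ind in inds])
    individuals = pd.DataFrame(
        {"id": [ind.id for ind in inds], "population": population}
    )
    g = GenotypeMatrix(
        markers=panel.markers.copy(), individuals=individuals, calls=calls
    )
    truth = pd.DataFrame(
        {
            "id": [ind.id for ind in inds],
            "replicate": replicate,
            "mating_type": [ind.mating_type for ind in inds],
            "f_true": [ind.truth.f_true for ind in inds],
            "adm_a": [ind.truth.adm_a for ind in inds],
            "n_segments": [len(ind.truth.hbd_segments) for ind in inds],
        }
    )
    return g, truth, inds


def simulate_study(
    spec: ReplicateSpec, panel: ReferencePanel
):
    """Generate replicates lazily: yields (replicate index, matrix, truth)."""
    root = np.random.default_rng(spec.rng_seed)
    for r in range(spec.n_replicates):
        rng = np.random.default_rng(root.integers(2**31))
        g, truth, _ = simulate_replicate(spec, panel, rng, replicate=r)
        yield r, g, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_segments(inds: list[SimulatedIndividual], path) -> None:
    """BED-like TSV of true HBD segments in cM coordinates."""
    with open(path, "w") as fh:
        fh.write("id\tchrom\tstart_cM\tend_cM\n")
        for ind in inds:
            for chrom, s, e in ind.truth.hbd_segments:
                fh.write(f"{ind.id}\t{chrom}\t{s:.6f}\t{e:.6f}\n")
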