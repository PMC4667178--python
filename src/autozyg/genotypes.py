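"""Genotype containers, I/O and marker quality control.

The central container is :class:`GenotypeMatrix`: an individuals x markers
matrix of alt-allele dosages (0/1/2, -1 for missing) with per-marker
metadata (chromosome, physical and genetic position, alleles) and a
population label per individual.  Quality control follows the standard
recipe for building an inbreeding-analysis marker panel: keep biallelic
autosomal SNPs with minor allele frequency above a floor in *every*
population and no extreme Hardy-Weinberg departure in *any* population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

_AUTOSOMES = {str(i) for i in range(1, 23)}


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def is_autosome(chrom: str) -> bool:
    return _norm_chrom(str(chrom)) in _AUTOSOMES


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP with physical and genetic coordinates (1-based bp, cM)."""

    chrom: str
    pos_bp: int
    pos_cM: float
    ref: str
    alt: str


@dataclass
class GenotypeMatrix:
    """Individuals x markers alt-allele dosage matrix with metadata.

    Attributes
    ----------
    markers : pandas.DataFrame
        One row per marker, columns ``chrom, pos_bp, pos_cM, ref, alt``,
        sorted by (chrom, pos_bp).
    individuals : pandas.DataFrame
        One row per individual, columns ``id, population``.
    calls : numpy.ndarray
        ``int8`` array of shape (n_individuals, n_markers); values in
        {0, 1, 2} count alt-allele copies, ``-1`` is missing.
    """

    markers: pd.DataFrame
    individuals: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        n_ind, n_mark = self.calls.shape
        if len(self.individuals) != n_ind or len(self.markers) != n_mark:
            raise ValueError(
                f"inconsistent dimensions: calls {self.calls.shape}, "
                f"{len(self.individuals)} individuals, {len(self.markers)} markers"
            )

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> list[str]:
        return sorted(self.individuals["population"].unique())

    def individual_index(self, ind_id: str) -> int:
        idx = self.individuals.index[self.individuals["id"] == ind_id]
        if len(idx) == 0:
            raise KeyError(f"unknown individual {ind_id!r}")
        return int(idx[0])

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            markers=self.markers.iloc[keep].reset_index(drop=True),
            individuals=self.individuals,
            calls=np.ascontiguousarray(self.calls[:, keep]),
        )

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        rows = [self.individual_index(i) for i in ids]
        return GenotypeMatrix(
            markers=self.markers,
            individuals=self.individuals.iloc[rows].reset_index(drop=True),
            calls=np.ascontiguousarray(self.calls[rows, :]),
        )


@dataclass
class FrequencySet:
    """Per-marker alt-allele frequencies from a named source.

    ``source_label`` is a reference-panel name, ``"SAMPLE"`` (estimated on
    the analysed sample itself) or ``"INDIVIDUAL"`` (one frequency vector
    per individual, shape (n_individuals, n_markers)).
    """

    source_label: str
    freqs: np.ndarray

    @property
    def per_individual(self) -> bool:
        return self.freqs.ndim == 2


@dataclass
class QCConfig:
    """Marker-filter thresholds applied per population."""

    maf_min: float = 0.05
    hwe_alpha: float = 1e-5
    autosomes_only: bool = True
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.maf_min < 0.5:
            raise ValueError("maf_min must be in (0, 0.5)")
        if not 0 < self.hwe_alpha < 1:
            raise ValueError("hwe_alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# I/O


def read_genotypes(
    path: str | Path,
    pop_labels: Mapping[str, str],
    autosomes_only: bool = True,
    biallelic_only: bool = True,
) -> GenotypeMatrix:
    """Read a (possibly gzipped) VCF into a :class:`GenotypeMatrix`.

    Every sample in the VCF must appear in ``pop_labels``; multiallelic,
    non-SNP and non-autosomal records are dropped according to the flags.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in pop_labels:
            raise ValueError(f"individual {s!r} has no population label")

    rows = []
    cols = []
    for var in vcf:
        if biallelic_only:
            if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
                continue
        if autosomes_only and not is_autosome(var.CHROM):
            continue
        alt = var.ALT[0] if var.ALT else "."
        rows.append((_norm_chrom(var.CHROM), var.POS, np.nan, var.REF, alt))
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = var.gt_types
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        cols.append(dosage.astype(np.int8))
    vcf.close()

    markers = pd.DataFrame(rows, columns=["chrom", "pos_bp", "pos_cM", "ref", "alt"])
    calls = (
        np.array(cols, dtype=np.int8).T
        if cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    # sort by chromosome (numeric where possible) then position
    key = markers["chrom"].map(lambda c: (0, int(c)) if c.isdigit() else (1, c))
    order = np.lexsort((markers["pos_bp"].to_numpy(), key.to_numpy()))
    markers = markers.iloc[order].reset_index(drop=True)
    calls = np.ascontiguousarray(calls[:, order])

    individuals = pd.DataFrame(
        {"id": samples, "population": [pop_labels[s] for s in samples]}
    )
    return GenotypeMatrix(markers=markers, individuals=individuals, calls=calls)


def read_pop_labels(path: str | Path) -> dict[str, str]:
    """Read a 2-column (id, population) TSV, with or without a header."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0] in ("id", "individual", "sample"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write an uncompressed minimal VCF (GT-only)."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individuals["id"])
            + "\n"
        )
        m = g.markers
        for j in range(g.n_markers):
            fields = [
                str(m.iloc[j]["chrom"]),
                str(int(m.iloc[j]["pos_bp"])),
                f"snp{j}",
                m.iloc[j]["ref"],
                m.iloc[j]["alt"],
                ".",
                "PASS",
                ".",
                "GT",
            ] + [gt_strings[int(c)] for c in g.calls[:, j]]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Frequencies and QC


def estimate_frequencies(
    g: GenotypeMatrix,
    scope: str = "SAMPLE",
    exclude: Sequence[str] = (),
) -> FrequencySet:
    """Alt-allele frequencies from the sample (``scope="SAMPLE"``) or one population.

    ``freq = alt-allele count / (2 x non-missing individuals)`` per marker.
    ``exclude`` removes individuals (e.g. known relatives) from the tally.
    """
    mask = np.ones(g.n_individuals, dtype=bool)
    if scope != "SAMPLE":
        mask &= (g.individuals["population"] == scope).to_numpy()
        if not mask.any():
            raise ValueError(f"no individuals in population {scope!r}")
    if len(exclude):
        excl = g.individuals["id"].isin(exclude).to_numpy()
        mask &= ~excl
    calls = g.calls[mask]
    nonmiss = calls != MISSING
    n_obs = nonmiss.sum(axis=0)
    if (n_obs == 0).any():
        bad = np.flatnonzero(n_obs == 0)
        labels = [
            f"{g.markers.iloc[j]['chrom']}:{g.markers.iloc[j]['pos_bp']}" for j in bad
        ]
        raise ValueError(f"all-missing markers in scope {scope!r}: {labels}")
    alt = np.where(nonmiss, calls, 0).sum(axis=0)
    return FrequencySet(source_label=scope, freqs=alt / (2.0 * n_obs))


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Two-sided plain exact test (no mid-p): conditioning on the observed
    allele counts, the p-value sums the probabilities of all heterozygote
    counts whose null probability does not exceed the observed one.
    Returns a p-value in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = n_Aa + 2 * n_aa  # minor-or-not does not matter; test is symmetric
    n_rare = min(n_a, 2 * n - n_a)
    het_obs = n_Aa
    # possible heterozygote counts share the parity of n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    from scipy.special import gammaln

    # P(het | allele counts) ∝ n! / (nAA! nAa! naa!) * 2^het, with
    # nAA = (n_rare - het)/2 rare-homs ... standard conditional distribution
    n_hom_rare = (n_rare - hets) // 2
    n_hom_com = n - hets - n_hom_rare
    logp = (
        hets * np.log(2.0)
        - gammaln(n_hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(n_hom_com + 1)
    )
    logp -= max(logp.max(), -np.inf)
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == het_obs][0]
    # tolerance guards against ties lost to floating point
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def apply_qc(
    g: GenotypeMatrix,
    cfg: QCConfig | None = None,
    exclude_from_freqs: Sequence[str] = (),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter markers by per-population MAF and HWE; return (filtered, log).

    A marker is retained only if its MAF is ``>= cfg.maf_min`` in every
    population and its HWE exact-test p-value is ``>= cfg.hwe_alpha`` in
    every population.  The log records, per excluded marker, the first rule
    violated and the offending population.  ``exclude_from_freqs`` names
    individuals (e.g. close relatives) left out of the per-population
    frequency and HWE tallies.
    """
    cfg = cfg or QCConfig()
    keep = np.ones(g.n_markers, dtype=bool)
    reasons: list[tuple[int, str, str]] = []

    freq_mask = ~g.individuals["id"].isin(exclude_from_freqs).to_numpy()

    if cfg.autosomes_only:
        for j, chrom in enumerate(g.markers["chrom"]):
            if keep[j] and not is_autosome(chrom):
                keep[j] = False
                reasons.append((j, "not_autosomal", ""))
    if cfg.biallelic_only:
        for j in range(g.n_markers):
            row = g.markers.iloc[j]
            if keep[j] and not (len(row["ref"]) == 1 and len(row["alt"]) == 1):
                keep[j] = False
                reasons.append((j, "not_biallelic_snp", ""))

    pops = g.populations
    pop_masks = {
        p: freq_mask & (g.individuals["population"] == p).to_numpy() for p in pops
    }
    for pop in pops:
        calls = g.calls[pop_masks[pop]]
        nonmiss = calls != MISSING
        n_obs = nonmiss.sum(axis=0)
        alt = np.where(nonmiss, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_obs > 0, alt / (2.0 * np.maximum(n_obs, 1)), np.nan)
        maf = np.minimum(freq, 1 - freq)
        for j in np.flatnonzero(keep):
            if np.isnan(maf[j]) or maf[j] < cfg.maf_min:
                keep[j] = False
                reasons.append((j, "maf", pop))
        for j in np.flatnonzero(keep):
            c = calls[:, j]
            p = hwe_exact_test(
                int((c == 0).sum()), int((c == 1).sum()), int((c == 2).sum())
            )
            if p < cfg.hwe_alpha:
                keep[j] = False
                reasons.append((j, "hwe", pop))

    log = pd.DataFrame(reasons, columns=["marker_index", "rule", "population"])
    if len(log):
        log = log.sort_values("marker_index").reset_index(drop=True)
        log["chrom"] = g.markers["chrom"].to_numpy()[log["marker_index"]]
        log["pos_bp"] = g.markers["pos_bp"].to_numpy()[log["marker_index"]]
    else:
        log["chrom"] = []
        log["pos_bp"] = []
    return g.subset_markers(np.flatnonzero(keep)), log


def interpolate_cM(
    markers_bp: np.ndarray,
    anchors_bp: np.ndarray,
    anchors_cM: np.ndarray,
) -> np.ndarray:
    """Genetic positions by linear interpolation between map anchors.

    Positions outside the anchor range are extrapolated at the terminal
    interval's cM/bp rate; the result is floored to be non-decreasing and
    non-negative.  Arrays are for a single chromosome; anchors must be
    sorted with at least two points.
    """
    markers_bp = np.asarray(markers_bp, dtype=float)
    anchors_bp = np.asarray(anchors_bp, dtype=float)
    anchors_cM = np.asarray(anchors_cM, dtype=float)
    if len(anchors_bp) < 2:
        raise ValueError("need at least 2 map anchors per chromosome")
    if np.any(np.diff(anchors_bp) <= 0):
        raise ValueError("map anchors must be sorted by position")
    cm = np.interp(markers_bp, anchors_bp, anchors_cM)
    lo_rate = (anchors_cM[1] - anchors_cM[0]) / (anchors_bp[1] - anchors_bp[0])
    hi_rate = (anchors_cM[-1] - anchors_cM[-2]) / (anchors_bp[-1] - anchors_bp[-2])
    below = markers_bp < anchors_bp[0]
    above = markers_bp > anchors_bp[-1]
    cm[below] = anchors_cM[0] + (markers_bp[below] - anchors_bp[0]) * lo_rate
    cm[above] = anchors_cM[-1] + (markers_bp[above] - anchors_bp[-1]) * hi_rate
    cm = np.maximum(cm, 0.0)
    order = np.argsort(markers_bp, kind="stable")
    cm[order] = np.maximum.accumulate(cm[order])
    return cm
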