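"""Genetic maps, hotspot-delimited regions and random sparse submaps.

Multi-point HBD inference with single-marker emissions needs markers in
minimal linkage disequilibrium.  Rather than LD-pruning, the genome is cut
into regions delimited by recombination hotspots (map intervals whose
intensity exceeds a cM/Mb threshold) and many random sparse "submaps" are
drawn, each keeping only a couple of markers per region.  Estimates are
later aggregated over submaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

MAP_COLUMNS = ["chrom", "pos_bp", "cM", "rate_cM_per_Mb"]


@dataclass
class GeneticMap:
    """Recombination map: anchor points with the intensity of the interval
    starting at each point (``rate_cM_per_Mb``; the last point's rate per
    chromosome is unused)."""

    points: pd.DataFrame  # columns MAP_COLUMNS, sorted by (chrom, pos_bp)

    def __post_init__(self) -> None:
        missing = [c for c in MAP_COLUMNS if c not in self.points.columns]
        if missing:
            raise ValueError(f"genetic map missing columns {missing}")
        for _, sub in self.points.groupby("chrom", sort=False):
            if np.any(np.diff(sub["pos_bp"].to_numpy()) <= 0):
                raise ValueError("map points must be strictly sorted by pos_bp")

    @classmethod
    def read(cls, path: str | Path) -> "GeneticMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def write(self, path: str | Path) -> None:
        self.points[MAP_COLUMNS].to_csv(path, sep="\t", index=False)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.points["chrom"]))

    def interpolate(self, chrom: str, pos_bp: np.ndarray) -> np.ndarray:
        from .genotypes import interpolate_cM

        sub = self.points[self.points["chrom"] == str(chrom)]
        if len(sub) == 0:
            raise ValueError(f"chromosome {chrom!r} absent from the genetic map")
        return interpolate_cM(
            np.asarray(pos_bp), sub["pos_bp"].to_numpy(), sub["cM"].to_numpy()
        )


@dataclass
class HotspotRegion:
    """Half-open physical interval between hotspot separators, with the
    indices of the markers it contains."""

    chrom: str
    start_bp: int
    end_bp: int
    marker_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class SubmapConfig:
    n_submaps: int = 100
    intensity_threshold: float = 10.0  # cM/Mb; 13 used for small-marker variants
    markers_per_region: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_submaps < 1:
            raise ValueError("n_submaps must be >= 1")
        if self.markers_per_region < 1:
            raise ValueError("markers_per_region must be >= 1")


@dataclass
class Submap:
    """Ordered marker subset with predecessor genetic distances.

    ``distances_cM[i]`` is the distance from marker ``i-1`` to ``i``;
    ``numpy.inf`` marks a chromosome start, where the HBD chain restarts
    from its stationary distribution.
    """

    marker_indices: np.ndarray
    distances_cM: np.ndarray

    def __len__(self) -> int:
        return len(self.marker_indices)

    @classmethod
    def from_indices(cls, g: GenotypeMatrix, indices: np.ndarray) -> "Submap":
        indices = np.asarray(indices, dtype=int)
        chroms = g.markers["chrom"].to_numpy()[indices]
        cm = g.markers["pos_cM"].to_numpy()[indices]
        d = np.empty(len(indices))
        d[0] = np.inf
        if len(indices) > 1:
            d[1:] = cm[1:] - cm[:-1]
            d[1:][chroms[1:] != chroms[:-1]] = np.inf
        if np.any(d[np.isfinite(d)] < 0):
            raise ValueError("markers not sorted by genetic position")
        return cls(marker_indices=indices, distances_cM=d)


def build_regions(
    gmap: GeneticMap,
    threshold: float = 10.0,
    g: GenotypeMatrix | None = None,
) -> list[HotspotRegion]:
    """Cut each chromosome into regions at hotspot intervals.

    A run of consecutive map intervals with intensity above ``threshold``
    acts as one separator; a chromosome with k separators yields k+1
    regions.  Region boundaries sit at separator starts, so a marker lying
    physically inside a hotspot belongs to the downstream region.  When a
    :class:`GenotypeMatrix` is given, each region's marker indices are
    filled in.
    """
    regions: list[HotspotRegion] = []
    for chrom in gmap.chromosomes():
        sub = gmap.points[gmap.points["chrom"] == chrom]
        bp = sub["pos_bp"].to_numpy()
        rate = sub["rate_cM_per_Mb"].to_numpy()
        hot = rate[:-1] > threshold  # interval i = [bp[i], bp[i+1])
        # starts of maximal hotspot runs = region cutpoints
        starts = [
            int(bp[i]) for i in range(len(hot)) if hot[i] and (i == 0 or not hot[i - 1])
        ]
        bounds = [0] + starts + [np.iinfo(np.int64).max]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            regions.append(HotspotRegion(chrom=str(chrom), start_bp=lo, end_bp=hi))
    if g is not None:
        assign_markers(regions, g)
    return regions


def assign_markers(regions: list[HotspotRegion], g: GenotypeMatrix) -> None:
    """Fill each region's ``marker_indices`` from the matrix's marker table."""
    chrom_arr = g.markers["chrom"].to_numpy()
    bp_arr = g.markers["pos_bp"].to_numpy()
    for r in regions:
        mask = (chrom_arr == r.chrom) & (bp_arr >= r.start_bp) & (bp_arr < r.end_bp)
        r.marker_indices = np.flatnonzero(mask)


def draw_submaps(
    g: GenotypeMatrix,
    regions: list[HotspotRegion],
    cfg: SubmapConfig | None = None,
) -> list[Submap]:
    """Draw ``cfg.n_submaps`` independent random sparse submaps.

    Per submap and region, ``min(markers_per_region, region size)`` markers
    are drawn uniformly without replacement; draws are independent across
    submaps and regions and reproducible under ``cfg.rng_seed``.
    """
    cfg = cfg or SubmapConfig()
    if g.n_markers == 0:
        raise ValueError("genotype matrix has no markers")
    if all(len(r.marker_indices) == 0 for r in regions):
        assign_markers(regions, g)
    rng = np.random.default_rng(cfg.rng_seed)
    nonempty = [r for r in regions if len(r.marker_indices) > 0]
    submaps = []
    for _ in range(cfg.n_submaps):
        picks = [
            rng.choice(
                r.marker_indices,
                size=min(cfg.markers_per_region, len(r.marker_indices)),
                replace=False,
            )
            for r in nonempty
        ]
        idx = np.sort(np.concatenate(picks))
        submaps.append(Submap.from_indices(g, idx))
    return submaps


def write_regions_bed(regions: list[HotspotRegion], path: str | Path) -> None:
    """Write regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp}\t{r.end_bp}\n")


def write_submaps(submaps: list[Submap], g: GenotypeMatrix, path: str | Path) -> None:
    """One whitespace-separated line of marker IDs (chrom:pos) per submap."""
    chrom = g.markers["chrom"].to_numpy()
    bp = g.markers["pos_bp"].to_numpy()
    with open(path, "w") as fh:
        for sm in submaps:
            ids = [f"{chrom[i]}:{bp[i]}" for i in sm.marker_indices]
            fh.write(" ".join(ids) + "\n")
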