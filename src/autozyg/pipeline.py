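"""Per-individual inbreeding inference from many submap fits.

The multi-point estimate of an individual's inbreeding coefficient is the
median of the per-submap ML estimates after discarding fits with a > 1
(implausibly short HBD segments, symptomatic of residual LD or unsuitable
allele frequencies).  The number of surviving submaps is the Q-score; an
estimate with Q-score <= q_min is flagged low quality.  A likelihood-ratio
test against f0 = 0.001 and a mating-type classification (avuncular, double
first cousin, first cousin, second cousin, outbred) complete the call: an
individual is reported inbred when the test rejects AND the most likely
mating type is not OUT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .genotypes import GenotypeMatrix, FrequencySet
from .hmm import EmissionModel, HBDModelFit, HBDModelParams, fit_ml, forward_loglik
from .maps import Submap


@dataclass(frozen=True)
class MatingType:
    """A parental mating type with its expected offspring inbreeding
    coefficient and the fixed chain rate used for classification.

    ``a`` derives from the number of meioses k in the inbreeding loop
    (expected HBD segment length 100/k cM, so a = k/100 per cM); OUT uses
    a = 1, the retention-filter boundary.
    """

    label: str
    expected_f: float
    a: float


# loop meioses: AV 5, 2x1C 6, 1C 6, 2C 8
MATING_TYPES: tuple[MatingType, ...] = (
    MatingType("AV", 1 / 8, 0.05),
    MatingType("2x1C", 1 / 8, 0.06),
    MatingType("1C", 1 / 16, 0.06),
    MatingType("2C", 1 / 64, 0.08),
    MatingType("OUT", 0.001, 1.0),
)

INBRED_TYPES = ("AV", "2x1C", "1C", "2C")


@dataclass
class DetectionConfig:
    f0: float = 0.001
    alpha: float = 0.05
    q_min: int = 50  # Q-score <= q_min flags the estimate low quality

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")


@dataclass
class InbreedingEstimate:
    """Aggregated per-individual result."""

    id: str
    population: str
    f_median: float  # NaN when no submap fit survived
    q_score: int
    lrt_p: float
    posteriors: dict[str, float]
    best_type: str
    inbred: bool
    low_quality: bool


def aggregate_fits(fits: Sequence[HBDModelFit]) -> tuple[float, int]:
    """Median f over retained (converged, a <= 1) fits, and their count.

    Returns (NaN, 0) when nothing survives the filter.
    """
    if len(fits) == 0:
        raise ValueError("need at least one fit")
    kept = [fit.params.f for fit in fits if fit.retained]
    if not kept:
        return float("nan"), 0
    return float(np.median(kept)), len(kept)


def lrt_inbreeding(fits: Sequence[HBDModelFit]) -> float:
    """Likelihood-ratio test of f != f0, aggregated over submaps.

    Per retained submap, Lambda = 2(loglik - loglik_h0) clipped at 0, with
    the p-value from the boundary mixture null (1/2)chi2_0 + (1/2)chi2_1;
    the reported p is the median per-submap p-value.
    """
    ps = []
    for fit in fits:
        if not fit.retained or np.isnan(fit.loglik_h0):
            continue
        lam = max(0.0, 2.0 * (fit.loglik - fit.loglik_h0))
        ps.append(1.0 if lam == 0.0 else 0.5 * float(chi2.sf(lam, df=1)))
    if not ps:
        return float("nan")
    return float(np.median(ps))


def classify_mating_type(
    genotypes: np.ndarray,
    submaps: Sequence[Submap],
    em_freqs: np.ndarray,
    retained_mask: Sequence[bool],
    eps: float = 1e-3,
    types: Sequence[MatingType] = MATING_TYPES,
) -> dict[str, float]:
    """Posterior probability of each mating type under a uniform prior.

    Per retained submap the likelihood of the individual's genotypes is
    computed with the type's fixed (expected_f, a); per-submap posteriors
    are averaged over the retained submaps.  ``genotypes`` and ``em_freqs``
    are full-matrix-length vectors indexed by the submaps.
    """
    weights = np.zeros(len(types))
    n_used = 0
    for sm, keep in zip(submaps, retained_mask):
        if not keep:
            continue
        idx = sm.marker_indices
        em = EmissionModel(freqs=em_freqs[idx], eps=eps)
        lls = np.array(
            [
                forward_loglik(
                    genotypes[idx],
                    sm.distances_cM,
                    em,
                    HBDModelParams(f=t.expected_f, a=t.a),
                )
                for t in types
            ]
        )
        lls -= lls.max()
        post = np.exp(lls)
        weights += post / post.sum()
        n_used += 1
    if n_used == 0:
        return {t.label: float("nan") for t in types}
    weights /= n_used
    return {t.label: float(w) for t, w in zip(types, weights)}


def estimate_individual(
    ind_id: str,
    genotypes: np.ndarray,
    submaps: Sequence[Submap],
    freqs: np.ndarray,
    cfg: DetectionConfig | None = None,
    population: str = "",
    eps: float = 1e-3,
    classify: bool = True,
    fit_null: bool = True,
    min_informative: int = 50,
) -> tuple[InbreedingEstimate, list[HBDModelFit]]:
    """Full per-individual pipeline over a set of submaps.

    ``freqs`` are full-length per-marker alt-allele frequencies (a single
    vector; individual-specific frequencies are passed per individual).
    Markers whose frequency falls outside (0,1) carry no information for
    the emission model and are treated as missing.
    """
    cfg = cfg or DetectionConfig()
    fits: list[HBDModelFit] = []
    usable = (freqs > 0) & (freqs < 1)
    safe_freqs = np.where(usable, freqs, 0.5)
    geno = np.where(usable, genotypes, -1).astype(np.int8)
    for sm in submaps:
        idx = sm.marker_indices
        em = EmissionModel(freqs=safe_freqs[idx], eps=eps)
        fits.append(
            fit_ml(
                geno[idx],
                sm.distances_cM,
                em,
                f0=cfg.f0,
                fit_null=fit_null,
                min_informative=min_informative,
            )
        )
    f_median, q_score = aggregate_fits(fits)
    lrt_p = lrt_inbreeding(fits) if fit_null else float("nan")
    retained = [fit.retained for fit in fits]
    if classify and q_score > 0:
        posteriors = classify_mating_type(geno, submaps, safe_freqs, retained, eps=eps)
        best_type = max(posteriors, key=posteriors.get)
    else:
        posteriors = {t.label: float("nan") for t in MATING_TYPES}
        best_type = "OUT" if q_score else ""
    inbred = bool(lrt_p < cfg.alpha and best_type != "OUT") if lrt_p == lrt_p else False
    est = InbreedingEstimate(
        id=ind_id,
        population=population,
        f_median=f_median,
        q_score=q_score,
        lrt_p=lrt_p,
        posteriors=posteriors,
        best_type=best_type,
        inbred=inbred,
        low_quality=q_score <= cfg.q_min,
    )
    return est, fits


def estimate_sample(
    g: GenotypeMatrix,
    submaps: Sequence[Submap],
    freqs: FrequencySet,
    cfg: DetectionConfig | None = None,
    ids: Sequence[str] | None = None,
    eps: float = 1e-3,
    classify: bool = True,
    fit_null: bool = True,
    progress: bool = False,
) -> list[InbreedingEstimate]:
    """Run :func:`estimate_individual` over a sample (optionally a subset)."""
    cfg = cfg or DetectionConfig()
    if ids is None:
        ids = list(g.individuals["id"])
    iterator: Iterable[str] = ids
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(ids, desc="individuals")
        except ImportError:
            pass
    out = []
    for ind_id in iterator:
        row = g.individual_index(ind_id)
        fvec = freqs.freqs[row] if freqs.per_individual else freqs.freqs
        est, _ = estimate_individual(
            ind_id,
            g.calls[row],
            submaps,
            fvec,
            cfg=cfg,
            population=str(g.individuals.iloc[row]["population"]),
            eps=eps,
            classify=classify,
            fit_null=fit_null,
        )
        out.append(est)
    return out


def fits_to_frame(ind_id: str, fits: Sequence[HBDModelFit]) -> pd.DataFrame:
    """Per-submap fit records (one row per submap), TSV-ready."""
    return pd.DataFrame(
        {
            "id": ind_id,
            "submap": np.arange(len(fits)),
            "f": [fit.params.f for fit in fits],
            "a": [fit.params.a for fit in fits],
            "loglik": [fit.loglik for fit in fits],
            "loglik_h0": [fit.loglik_h0 for fit in fits],
            "retained": [fit.retained for fit in fits],
            "converged": [fit.converged for fit in fits],
        }
    )


def estimates_to_frame(estimates: Sequence[InbreedingEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        row = {
            "id": e.id,
            "population": e.population,
            "f_median": e.f_median,
            "q_score": e.q_score,
            "lrt_p": e.lrt_p,
            "best_type": e.best_type,
            "inbred": e.inbred,
            "low_quality": e.low_quality,
        }
        row.update({f"P_{k}": v for k, v in e.posteriors.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_population(
    estimates: Sequence[InbreedingEstimate],
) -> pd.DataFrame:
    """Counts per population of inbred calls by mating type.

    Low-quality estimates are excluded from the inbred tallies and counted
    separately.  ``total_inbred`` equals the row sum over mating types.
    """
    cols = list(INBRED_TYPES) + ["total_inbred", "low_quality", "n"]
    if not estimates:
        return pd.DataFrame(columns=["population"] + cols)
    rows: dict[str, dict[str, int]] = {}
    for e in estimates:
        r = rows.setdefault(e.population, {c: 0 for c in cols})
        r["n"] += 1
        if e.low_quality:
            r["low_quality"] += 1
            continue
        if e.inbred and e.best_type in INBRED_TYPES:
            r[e.best_type] += 1
            r["total_inbred"] += 1
    out = pd.DataFrame.from_dict(rows, orient="index").reset_index(names="population")
    return out.sort_values("population").reset_index(drop=True)


def _greedy_pair_break(ids: set[str], pairs: Iterable[tuple[str, str]]) -> set[str]:
    """Individuals to remove so no pair survives: repeatedly drop the
    member involved in the most unresolved pairs, ties by lexicographic id."""
    live = [tuple(p) for p in pairs if p[0] in ids and p[1] in ids and p[0] != p[1]]
    removed: set[str] = set()
    while live:
        degree: dict[str, int] = {}
        for a, b in live:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        victim = min(degree, key=lambda k: (-degree[k], k))
        removed.add(victim)
        live = [p for p in live if victim not in p]
    return removed


def build_panels(
    estimates: Sequence[InbreedingEstimate],
    close_pairs: Sequence[tuple[str, str]] = (),
    cousin_pairs: Sequence[tuple[str, str]] = (),
) -> tuple[list[str], list[str]]:
    """Construct the two unrelated-and-outbred reference panels.

    Panel A removes low-quality estimates, one member of each first/second
    degree pair, and individuals classified AV or 2x1C.  Panel B starts
    from panel A and additionally breaks first-cousin pairs and removes
    individuals classified 1C, so panel_B is a subset of panel_A by
    construction.
    """
    known = {e.id for e in estimates}
    for a, b in list(close_pairs) + list(cousin_pairs):
        for x in (a, b):
            if x not in known:
                raise ValueError(f"pair references unknown individual {x!r}")
    by_id = {e.id: e for e in estimates}
    panel_a = {e.id for e in estimates if not e.low_quality}
    panel_a -= _greedy_pair_break(panel_a, close_pairs)
    panel_a -= {i for i in panel_a if by_id[i].best_type in ("AV", "2x1C")}
    panel_b = set(panel_a)
    panel_b -= _greedy_pair_break(panel_b, list(close_pairs) + list(cousin_pairs))
    panel_b -= {i for i in panel_b if by_id[i].best_type == "1C"}
    return sorted(panel_a), sorted(panel_b)
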