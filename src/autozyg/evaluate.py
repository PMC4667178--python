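"""Estimator comparison on simulated truth: Delta-f, RMSE, sampling rules.

The comparison metric is the root mean square error of
``delta_f = f_hat - f_true`` per (estimator, frequency set, mating type)
cell, computed over an evaluation subset drawn as one individual of each
inbred mating type per replicate with f_true > 0, plus one outbred
individual per replicate.  Single-point estimates are truncated at 0
before Delta-f; multi-point records with a low Q-score are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

INBRED_SIM_TYPES = ("1C", "2C", "3C", "4C")


def sample_eval_individuals(
    truth: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Per replicate: one random individual per inbred type with f_true > 0
    and one OUT individual (no constraint).  Cells with no eligible
    individual are simply absent (logged via the returned frame's gaps).

    ``truth`` needs columns id, replicate, mating_type, f_true.
    """
    picks = []
    for rep, sub in truth.groupby("replicate"):
        for t in INBRED_SIM_TYPES + ("OUT",):
            pool = sub[sub["mating_type"] == t]
            if t != "OUT":
                pool = pool[pool["f_true"] > 0]
            if len(pool) == 0:
                continue
            picks.append(pool.iloc[int(rng.integers(len(pool)))])
    return pd.DataFrame(picks).reset_index(drop=True)


def rmse(delta_fs) -> float:
    """sqrt(mean(delta_f^2))."""
    d = np.asarray(delta_fs, dtype=float)
    if d.size == 0:
        raise ValueError("empty delta_f list")
    return float(np.sqrt(np.mean(d**2)))


@dataclass
class EstimateTable:
    """Per-individual estimates for one (estimator, frequency set) combo.

    ``kind`` is ``"multi_point"`` (Q-score filter applies) or
    ``"single_point"`` (negative estimates truncated at 0).
    """

    estimator: str
    freq_set: str
    kind: str
    f_hat: dict[str, float]  # id -> estimate
    q_score: dict[str, int] | None = None


def build_records(
    eval_individuals: pd.DataFrame,
    tables: list[EstimateTable],
    q_min: int = 50,
) -> pd.DataFrame:
    """Per-individual Delta-f records for every estimator table.

    Individuals missing from a table, or multi-point individuals at or
    below the Q-score floor, are excluded from that table's records.
    """
    rows = []
    for tab in tables:
        for _, ind in eval_individuals.iterrows():
            iid = ind["id"]
            if iid not in tab.f_hat:
                continue
            f_hat = tab.f_hat[iid]
            if not np.isfinite(f_hat):
                continue
            q = tab.q_score.get(iid) if tab.q_score else None
            if tab.kind == "multi_point" and q is not None and q <= q_min:
                continue
            if tab.kind == "single_point":
                f_hat = max(f_hat, 0.0)
            rows.append(
                {
                    "id": iid,
                    "mating_type": ind["mating_type"],
                    "estimator": tab.estimator,
                    "freq_set": tab.freq_set,
                    "f_hat": f_hat,
                    "delta_f": f_hat - ind["f_true"],
                    "adm_a": ind.get("adm_a", np.nan),
                    "q_score": q if q is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def rmse_table(records: pd.DataFrame) -> pd.DataFrame:
    """RMSE of Delta-f per (estimator, freq_set, mating_type) with counts."""
    if len(records) == 0:
        return pd.DataFrame(
            columns=["estimator", "freq_set", "mating_type", "rmse", "n"]
        )
    out = (
        records.groupby(["estimator", "freq_set", "mating_type"])
        .agg(rmse=("delta_f", lambda d: rmse(d.to_numpy())), n=("delta_f", "size"))
        .reset_index()
    )
    return out


def run_admixture_study(
    cfg,
    estimators: set[str] | None = None,
    q_min: int | None = None,
) -> pd.DataFrame:
    """End-to-end scaled replication of the admixture simulation study.

    Generates the synthetic genome and Balding-Nichols panels from
    ``cfg`` (a :class:`autozyg.config.RunConfig`), gene-drops the
    configured replicates, draws the per-replicate evaluation individuals
    (one per inbred mating type with f_true > 0 plus one outbred), runs the
    requested estimators on them with sample-estimated frequencies, and
    returns the per-individual Delta-f records.

    ``estimators`` is a subset of ``{"multi", "single", "single_ind"}``:
    the multi-point HBD-HMM median-f, the single-point moment estimator
    with pooled sample frequencies, and the moment estimator with true
    ancestry-weighted individual frequencies.  The Q-score floor defaults
    to half the submap count (mirroring the 50-of-100 convention).
    """
    from .genotypes import estimate_frequencies
    from .maps import build_regions, draw_submaps
    from .pipeline import estimate_sample
    from .simulate import generate_map, generate_panel, simulate_study
    from .single_point import individual_frequencies, moment_f

    estimators = estimators or {"multi", "single"}
    if q_min is None:
        q_min = cfg.submaps.n_submaps // 2
    rng = np.random.default_rng(cfg.seed)
    gmap, markers = generate_map(cfg.genome, rng)
    panel = generate_panel(markers, gmap, cfg.fst, rng)
    pick_rng = np.random.default_rng(cfg.seed + 1)
    p_a = panel.panel_frequencies(panel.populations[0])
    p_b = panel.panel_frequencies(panel.populations[1])
    all_records = []
    for r, g, truth in simulate_study(cfg.replicates, panel):
        eval_inds = sample_eval_individuals(truth, pick_rng)
        freqs = estimate_frequencies(g)
        tables: list[EstimateTable] = []
        if "multi" in estimators:
            regions = build_regions(gmap, cfg.submaps.intensity_threshold, g)
            submaps = draw_submaps(g, regions, cfg.submaps)
            ests = estimate_sample(
                g,
                submaps,
                freqs,
                cfg.detection,
                ids=list(eval_inds["id"]),
                eps=cfg.eps,
                classify=False,
                fit_null=False,
            )
            tables.append(
                EstimateTable(
                    estimator="multi_point",
                    freq_set="SAMPLE",
                    kind="multi_point",
                    f_hat={e.id: e.f_median for e in ests},
                    q_score={e.id: e.q_score for e in ests},
                )
            )
        if "single" in estimators:
            f_hat = {}
            for iid in eval_inds["id"]:
                i = g.individual_index(iid)
                f_hat[iid] = moment_f(g.calls[i], freqs.freqs, ind_id=iid).f_hat
            tables.append(
                EstimateTable(
                    estimator="single_point",
                    freq_set="SAMPLE",
                    kind="single_point",
                    f_hat=f_hat,
                )
            )
        if "single_ind" in estimators:
            tr = truth.set_index("id")
            f_hat = {}
            for iid in eval_inds["id"]:
                i = g.individual_index(iid)
                p_ind = individual_frequencies(tr.loc[iid, "adm_a"], p_a, p_b)
                f_hat[iid] = moment_f(
                    g.calls[i], p_ind, ind_id=iid, freq_source="INDIVIDUAL"
                ).f_hat
            tables.append(
                EstimateTable(
                    estimator="single_point",
                    freq_set="INDIVIDUAL",
                    kind="single_point",
                    f_hat=f_hat,
                )
            )
        all_records.append(build_records(eval_inds, tables, q_min=q_min))
    return pd.concat(all_records, ignore_index=True)


def plot_delta_vs_ancestry(records: pd.DataFrame, path) -> None:
    """Optional diagnostic scatter of Delta-f against ancestry, one facet
    per estimator x frequency set (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    combos = sorted(set(zip(records["estimator"], records["freq_set"])))
    ncols = min(3, len(combos))
    nrows = int(np.ceil(len(combos) / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False
    )
    for ax, (est, fs) in zip(axes.flat, combos):
        sub = records[(records["estimator"] == est) & (records["freq_set"] == fs)]
        for t, grp in sub.groupby("mating_type"):
            ax.scatter(grp["adm_a"], grp["delta_f"], s=6, label=t, alpha=0.6)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_title(f"{est} / {fs}", fontsize=9)
        ax.set_xlabel("ancestry (pop A fraction)")
        ax.set_ylabel(r"$\Delta f$")
    axes.flat[0].legend(fontsize=7)
    for ax in axes.flat[len(combos):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
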