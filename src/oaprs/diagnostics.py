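"""Visual diagnosis of residual overfitting after overlap adjustment.

The idea: if the adjustment really removed the overlap samples' signal,
then after excluding every variant that is associated in either the
adjusted consortium summary or the target's own GWAS, a PRS built from the
surviving (null) variants should have no predictive power — its AUROC on
the overlap samples should sit at 0.5.  A summary still contaminated by
overlap keeps residual signal in nominally null variants, and its AUROC
trajectory stays elevated.

The procedure filters in two stages (drop strongly associated variants and
their LD neighbours; then drop variants of medium association at a grid of
exclusion thresholds), scores the survivors, and traces per-group AUROC
against the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prs import PRSWeights, VariantSubset, _standardized_columns, auroc, score
from .simulate import run_gwas

logger = logging.getLogger(__name__)

__all__ = [
    "DiagnosticTrajectory",
    "diagnostic_filter",
    "threshold_trajectory",
    "plot_trajectory",
]

DEFAULT_P_HIGH = 1e-4
DEFAULT_THRESHOLDS = (0.0, 0.01, 0.05, 0.1, 0.2, 0.5)


def diagnostic_filter(
    consortium,
    target_gwas,
    reference,
    p_high: float = DEFAULT_P_HIGH,
    p_threshold: float = 0.0,
    r2_threshold: float = 0.1,
    window: int = 250_000,
) -> VariantSubset:
    """Two-stage exclusion filter for the diagnostic trajectory.

    Stage 1 removes every variant with P < ``p_high`` in *either* table,
    together with all reference variants in LD with one of them
    (r^2 >= ``r2_threshold`` within ``window`` bp).  Stage 2 keeps only
    variants whose P >= ``p_threshold`` in *both* tables; ``p_threshold = 0``
    removes nothing beyond stage 1.
    """
    c = consortium.df.set_index("variant_id")
    t = target_gwas.df.set_index("variant_id")
    ids = c.index.union(t.index)
    p_c = c["pvalue"].reindex(ids)
    p_t = t["pvalue"].reindex(ids)
    p_min = np.fmin(p_c, p_t)  # NaN-ignoring minimum across the two tables
    hot = set(ids[(p_min < p_high).to_numpy()])

    # LD neighbours of hot variants, from the reference genotypes
    n_ld = 0
    if hot:
        ref_index = {v: j for j, v in enumerate(reference.variant_ids)}
        hot_cols = [ref_index[v] for v in hot if v in ref_index]
        if hot_cols:
            G = _standardized_columns(reference.genotypes)
            n_ref = G.shape[0]
            pos = np.asarray(reference.pos, dtype=float)
            chrom = np.asarray(reference.chrom, dtype=object)
            hot_pos = pos[hot_cols]
            hot_chrom = chrom[hot_cols]
            corr = (G.T @ G[:, hot_cols]) / n_ref  # (m, n_hot)
            near = (chrom[:, None] == hot_chrom[None, :]) & (
                np.abs(pos[:, None] - hot_pos[None, :]) <= window
            )
            ld_hit = np.any((corr**2 >= r2_threshold) & near, axis=1)
            neighbours = {
                reference.variant_ids[j]
                for j in np.flatnonzero(ld_hit)
                if reference.variant_ids[j] not in hot
            }
            n_ld = len(neighbours)
            hot |= neighbours

    survivors = [v for v in ids if v not in hot]
    n_stage1 = len(ids) - len(survivors)
    n_stage2 = 0
    if p_threshold > 0:
        # keep only variants with P >= threshold in every table that has them
        medium = set(ids[(p_min < p_threshold).to_numpy()])
        kept = [v for v in survivors if v not in medium]
        n_stage2 = len(survivors) - len(kept)
        survivors = kept
    return VariantSubset(
        survivors, stage1_removed=n_stage1, ld_neighbours=n_ld, stage2_removed=n_stage2
    )


@dataclass
class DiagnosticTrajectory:
    """AUROC as a function of the exclusion threshold, for one summary."""

    method: str
    points: pd.DataFrame  # threshold, n_variants, auroc_{total,overlap,non_overlap}

    def to_frame(self) -> pd.DataFrame:
        out = self.points.copy()
        out.insert(0, "method", self.method)
        return out


def _group_auroc(scores, labels, mask):
    y = labels[mask]
    if mask.sum() == 0 or y.min() == y.max():
        return np.nan
    return auroc(scores[mask], y)


def threshold_trajectory(
    summaries: dict,
    dataset,
    thresholds=DEFAULT_THRESHOLDS,
    p_high: float = DEFAULT_P_HIGH,
    r2_threshold: float = 0.1,
    window: int = 250_000,
    target_gwas=None,
) -> list[DiagnosticTrajectory]:
    """Trace per-group AUROC across exclusion thresholds for each summary.

    ``summaries`` maps a method label (e.g. ``"unadjusted"``, ``"zscore"``)
    to a summary-statistics table.  Weights at each point are the summary
    betas of the surviving variants — deliberately not re-fitted, since the
    diagnostic probes residual signal.  Points with no surviving variants or
    single-class groups are emitted with NaN AUROCs.
    """
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    target_idx = dataset.subset_indices("target")
    labels = dataset.phenotype[target_idx]
    part = dataset.partition[target_idx]
    masks = {
        "total": np.ones(len(target_idx), dtype=bool),
        "overlap": part == "overlap",
        "non_overlap": part == "target_only",
    }
    from .prs import _SubsetGenotypes

    ref = _SubsetGenotypes(dataset, target_idx)
    ref.pos = dataset.pos
    ref.chrom = dataset.chrom
    if target_gwas is None:
        target_gwas = run_gwas(dataset, "target")

    out = []
    for label, table in summaries.items():
        rows = []
        for t in thresholds:
            ids = diagnostic_filter(
                table,
                target_gwas,
                ref,
                p_high=p_high,
                p_threshold=t,
                r2_threshold=r2_threshold,
                window=window,
            )
            rec = {"threshold": t, "n_variants": len(ids)}
            aucs = dict.fromkeys(masks, np.nan)
            if ids:
                w = PRSWeights.from_sumstats(table, ids, provenance=f"diagnostic t={t}")
                if len(w) and np.any(w.df["weight"] != 0):
                    sc = score(ref, w).scores
                    if np.std(sc) > 0:
                        for g, m in masks.items():
                            aucs[g] = _group_auroc(sc, labels, m)
            for g in masks:
                rec[f"auroc_{g}"] = aucs[g]
            rows.append(rec)
        out.append(DiagnosticTrajectory(label, pd.DataFrame(rows)))
    return out


def plot_trajectory(trajectories, out_path, table_path=None):
    """Line plot of the AUROC trajectories plus the underlying table.

    One line per method per group (non-overlap dotted, as the no-overfitting
    reference), a horizontal rule at 0.5, gaps at non-evaluable points.  The
    plotted numbers are also written tab-delimited next to the figure.
    Returns ``(figure_path, table_path)``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    trajectories = list(trajectories)
    table = pd.concat([t.to_frame() for t in trajectories], ignore_index=True)
    if not np.isfinite(
        table[[c for c in table.columns if c.startswith("auroc_")]].to_numpy()
    ).any():
        raise ValueError("no evaluable trajectory points to plot")

    fig, ax = plt.subplots(figsize=(7, 4.5))
    styles = {"total": "-", "overlap": "-", "non_overlap": ":"}
    markers = {"total": "o", "overlap": "s", "non_overlap": "^"}
    for traj in trajectories:
        for group, ls in styles.items():
            col = f"auroc_{group}"
            if traj.points[col].notna().any():
                ax.plot(
                    traj.points["threshold"],
                    traj.points[col],
                    ls,
                    marker=markers[group],
                    markersize=4,
                    label=f"{traj.method} ({group})",
                )
    ax.axhline(0.5, color="grey", lw=1, ls="--")
    ax.set_xlabel("exclusion P-value threshold")
    ax.set_ylabel("AUROC")
    ax.set_title("Residual-overfitting diagnostic")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    if table_path is None:
        table_path = str(out_path).rsplit(".", 1)[0] + ".tsv"
    table.to_csv(table_path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    return str(out_path), str(table_path)
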