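"""Polygenic risk scores by clumping + P-value thresholding, and evaluation.

The constructor is the classic C+T procedure: greedily keep the most
significant variant of every correlated group (LD computed against a
reference genotype matrix), restrict to variants passing a P-value
threshold, and score individuals as the weighted sum of effect-allele
dosages.  Discrimination is summarized as AUROC (exact Mann–Whitney rank
statistic) and odds ratio per standard deviation of score (logistic
regression), reported separately on the overlap, non-overlap, and total
target samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "VariantSubset",
    "PRSWeights",
    "ScoreResult",
    "GroupMetrics",
    "EvalReport",
    "ORResult",
    "clump",
    "threshold",
    "score",
    "auroc",
    "or_per_sd",
    "evaluate",
    "fit_ct_prs",
    "CTResult",
    "DEFAULT_P_GRID",
]

DEFAULT_P_GRID = (5e-8, 1e-5, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)
DEFAULT_R2 = 0.1
DEFAULT_WINDOW = 250_000  # bp


class VariantSubset(list):
    """A list of variant ids with bookkeeping counts attached."""

    def __init__(self, ids, **counts):
        super().__init__(ids)
        self.counts = counts


def _standardized_columns(genotypes: np.ndarray) -> np.ndarray:
    g = genotypes.astype(np.float64)
    g -= g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    return g / sd


def clump(
    sumstats,
    reference,
    r2_threshold: float = DEFAULT_R2,
    window: int = DEFAULT_WINDOW,
) -> VariantSubset:
    """Greedy LD clumping against a reference genotype matrix.

    Variants are visited in order of ascending P (ties broken by variant id);
    a variant is kept unless its squared correlation with an already-kept
    variant on the same chromosome within ``window`` bp reaches
    ``r2_threshold``.  Variants absent from the reference pass through
    unclumped and are counted.
    """
    df = sumstats.df
    if len(df) == 0:
        raise ValueError("cannot clump an empty summary-statistics table")
    ref_index = {v: j for j, v in enumerate(reference.variant_ids)}
    order = df.sort_values(["pvalue", "variant_id"], kind="mergesort")

    G = _standardized_columns(reference.genotypes)
    n_ref = G.shape[0]
    m_ref = G.shape[1]
    # one BLAS call beats per-candidate products up to a few thousand variants
    R2 = (G.T @ G / n_ref) ** 2 if m_ref <= 5000 else None

    vids = order["variant_id"].to_numpy()
    chroms = pd.factorize(order["chrom"].astype(str))[0]
    poss = order["pos"].to_numpy(dtype=float)
    cols = np.fromiter((ref_index.get(v, -1) for v in vids), dtype=np.int64, count=len(vids))

    m = len(vids)
    kept: list[str] = []
    kept_cols = np.empty(m, dtype=np.int64)
    kept_chrom = np.empty(m, dtype=np.int64)
    kept_pos = np.empty(m, dtype=float)
    k = 0
    pruned = 0
    missing = 0
    for i in range(m):
        j = cols[i]
        if j < 0:
            kept.append(vids[i])
            missing += 1
            continue
        hit = False
        if k:
            near = np.flatnonzero(
                (kept_chrom[:k] == chroms[i]) & (np.abs(kept_pos[:k] - poss[i]) <= window)
            )
            if near.size:
                if R2 is not None:
                    hit = bool(np.any(R2[j, kept_cols[near]] >= r2_threshold))
                else:
                    r = (G[:, kept_cols[near]].T @ G[:, j]) / n_ref
                    hit = bool(np.any(r**2 >= r2_threshold))
        if hit:
            pruned += 1
        else:
            kept.append(vids[i])
            kept_cols[k] = j
            kept_chrom[k] = chroms[i]
            kept_pos[k] = poss[i]
            k += 1
    return VariantSubset(kept, pruned=pruned, missing_reference=missing)


def threshold(sumstats, p_max: float) -> VariantSubset:
    """Variants with P <= p_max; ``p_max = 0`` is the empty set."""
    if not (0 <= p_max <= 1):
        raise ValueError("p_max must lie in [0, 1]")
    if p_max == 0:
        return VariantSubset([])
    df = sumstats.df
    keep = df.loc[df["pvalue"] <= p_max, "variant_id"].tolist()
    return VariantSubset(keep)


@dataclass
class PRSWeights:
    """Per-variant scoring weights on a stated effect allele."""

    df: pd.DataFrame  # variant_id, effect_allele, other_allele, weight
    provenance: str = ""

    def __post_init__(self):
        if self.df["variant_id"].duplicated().any():
            raise ValueError("duplicate variant ids in weights")
        if not np.all(np.isfinite(self.df["weight"].to_numpy(dtype=float))):
            raise ValueError("weights must be finite")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_sumstats(cls, sumstats, variant_ids=None, provenance="") -> "PRSWeights":
        df = sumstats.df
        if variant_ids is not None:
            df = df[df["variant_id"].isin(set(variant_ids))]
        out = df[["variant_id", "effect_allele", "other_allele", "beta"]].rename(
            columns={"beta": "weight"}
        )
        out = out.dropna(subset=["weight"]).reset_index(drop=True)
        return cls(out, provenance=provenance)


@dataclass
class ScoreResult:
    """Per-sample PRS values plus variant-usage counts."""

    scores: np.ndarray
    n_used: int
    n_missing: int
    n_flipped: int
    n_mismatch: int

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.scores, dtype=dtype)


def score(genotypes, weights: PRSWeights) -> ScoreResult:
    """Weighted allele-dosage sum per sample.

    ``genotypes`` is any object exposing ``genotypes`` (samples x variants
    dosage matrix), ``variant_ids``, ``effect_allele`` and ``other_allele``
    (the simulator's :class:`~oaprs.simulate.SimDataset` qualifies).  Weight
    alleles are reconciled to the genotype coding: a weight on the genotype's
    other allele scores ``weight * (2 - dosage)``.  Missing and
    allele-incompatible weight variants are skipped and counted.
    """
    idx = {v: j for j, v in enumerate(genotypes.variant_ids)}
    n = genotypes.genotypes.shape[0]
    prs = np.zeros(n)
    used = missing = flipped = mismatch = 0
    cols, ws, flips = [], [], []
    for vid, ea, oa, w in weights.df[
        ["variant_id", "effect_allele", "other_allele", "weight"]
    ].itertuples(index=False):
        j = idx.get(vid)
        if j is None:
            missing += 1
            continue
        g_ea, g_oa = genotypes.effect_allele[j], genotypes.other_allele[j]
        if ea == g_ea and oa == g_oa:
            cols.append(j), ws.append(w), flips.append(False)
        elif ea == g_oa and oa == g_ea:
            cols.append(j), ws.append(w), flips.append(True)
            flipped += 1
        else:
            mismatch += 1
            continue
        used += 1
    if used == 0:
        raise ValueError("no usable variants: weights and genotypes do not overlap")
    X = genotypes.genotypes[:, cols].astype(np.float64)
    ws = np.asarray(ws)
    flips = np.asarray(flips)
    dosage = np.where(flips, 2.0 - X, X)
    prs = dosage @ ws
    return ScoreResult(prs, used, missing, flipped, mismatch)


def auroc(scores, labels) -> float:
    """Exact Mann–Whitney AUROC: P(case outscores control) + half-ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cases = labels == 1
    n1 = int(cases.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUROC")
    ranks = rankdata(scores)
    return float((ranks[cases].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class ORResult:
    """Odds ratio per SD of score from logistic regression."""

    value: float
    converged: bool = True
    message: str | None = None

    def __float__(self):
        return float(self.value)


def or_per_sd(scores, labels, covariates=None) -> ORResult:
    """Exponentiated coefficient of the standardized score in a logistic fit.

    Fitted by Newton IRLS to tolerance 1e-8.  Separation or non-convergence
    yields a flagged result rather than an exception.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValueError("scores are constant; OR per SD undefined")
    zs = (scores - scores.mean()) / sd
    X = zs[:, None] if covariates is None else np.column_stack([zs, covariates])
    X = sm.add_constant(X, prepend=True)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation / non-convergence is detected and flagged below
            warnings.simplefilter("ignore")
            res = sm.Logit(labels, X).fit(method="newton", tol=1e-8, maxiter=100, disp=0)
        coef = float(res.params[1])
        conv = bool(res.mle_retvals.get("converged", False))
        if not conv or abs(coef) > 15:
            return ORResult(float(np.exp(coef)), False, "separation or non-convergence")
        return ORResult(float(np.exp(coef)))
    except Exception as exc:  # PerfectSeparation, singular matrix, ...
        return ORResult(float("nan"), False, f"logistic fit failed: {exc}")


@dataclass
class GroupMetrics:
    group: str
    n: int
    n_cases: int
    auroc: float = float("nan")
    or_per_sd: float = float("nan")
    evaluable: bool = True
    note: str | None = None


@dataclass
class EvalReport:
    """Discrimination metrics per target group (total / overlap / non_overlap)."""

    groups: dict[str, GroupMetrics] = field(default_factory=dict)

    def __getitem__(self, key) -> GroupMetrics:
        return self.groups[key]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(g) for g in self.groups.values()])


def evaluate(scores, labels, partition) -> EvalReport:
    """Per-group AUROC and OR per SD on the target samples.

    ``partition`` holds the simulator's labels; the groups are ``total``
    (everything passed in), ``overlap``, and ``non_overlap``
    (= ``target_only``).  Groups missing a class — or empty — are marked
    not evaluable instead of raising.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    partition = np.asarray(partition, dtype=object)
    masks = {
        "total": np.ones(len(labels), dtype=bool),
        "overlap": partition == "overlap",
        "non_overlap": partition == "target_only",
    }
    report = EvalReport()
    for name, mask in masks.items():
        n = int(mask.sum())
        n_cases = int((labels[mask] == 1).sum())
        gm = GroupMetrics(name, n, n_cases)
        if n == 0 or n_cases in (0, n):
            gm.evaluable = False
            gm.note = "empty group" if n == 0 else "single phenotype class"
        else:
            gm.auroc = auroc(scores[mask], labels[mask])
            if scores[mask].std(ddof=1) > 0:
                orr = or_per_sd(scores[mask], labels[mask])
                gm.or_per_sd = orr.value
                if not orr.converged:
                    gm.note = orr.message
            else:
                gm.note = "constant scores; OR undefined"
        report.groups[name] = gm
    return report


@dataclass
class CTResult:
    """Fitted clumping + thresholding PRS."""

    weights: PRSWeights
    best_p: float
    scores: ScoreResult  # on the target samples
    auroc_by_threshold: dict[float, float]
    clumped: VariantSubset


def fit_ct_prs(
    sumstats,
    dataset,
    p_grid=DEFAULT_P_GRID,
    r2_threshold: float = DEFAULT_R2,
    window: int = DEFAULT_WINDOW,
) -> CTResult:
    """Clump + threshold against the target data, choosing the threshold
    that maximizes AUROC on the total target set (ties go to the smaller,
    sparser threshold)."""
    target_idx = dataset.subset_indices("target")
    ref = _SubsetGenotypes(dataset, target_idx)
    clumped = clump(sumstats, ref, r2_threshold=r2_threshold, window=window)
    clumped_set = set(clumped)
    labels = dataset.phenotype[target_idx]

    best = None
    aucs: dict[float, float] = {}
    for p_max in sorted(p_grid):
        ids = [v for v in threshold(sumstats, p_max) if v in clumped_set]
        if not ids:
            continue
        w = PRSWeights.from_sumstats(sumstats, ids, provenance=f"C+T p<={p_max}")
        if len(w) == 0:
            continue
        sc = score(ref, w)
        if np.std(sc.scores) == 0:
            continue
        a = auroc(sc.scores, labels)
        aucs[p_max] = a
        if best is None or a > best[0]:
            best = (a, p_max, w, sc)
    if best is None:
        raise ValueError("no threshold produced a scorable variant set")
    _, best_p, weights, scores = best
    return CTResult(weights, best_p, scores, aucs, clumped)


class _SubsetGenotypes:
    """Genotype view restricted to a sample subset (keeps variant metadata)."""

    def __init__(self, dataset, sample_idx):
        self.genotypes = dataset.genotypes[sample_idx]
        self.variant_ids = dataset.variant_ids
        self.effect_allele = dataset.effect_allele
        self.other_allele = dataset.other_allele
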