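"""Removal of overlap-sample contributions from GWAS summary statistics.

A consortium GWAS that was (or behaves as if it was) produced by fixed-effect
meta-analysis can be algebraically inverted: given the consortium summary and
a summary computed on the overlapping samples alone, the summary of the
remaining, non-overlapped samples is recovered exactly.  Two inversions are
provided —

* **IVW**: invert inverse-variance weighting on (beta, se);
* **Z-score**: invert the sample-size-weighted Z meta-analysis, then map
  the adjusted Z back to (beta, se) using the allele frequency, assuming a
  phenotype standardized to mean 0, SD 1;

plus a **de-correlation** comparator that whitens the consortium Z against
the overlap Z under a known cross-statistic correlation.

The high-level entry point is :class:`OverlapAdjustment` (a model object
built from two :class:`~oaprs.sumstats.SumStatsTable`) whose :meth:`fit`
returns an :class:`AdjustmentResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import CANONICAL_COLUMNS, MatchedPairs, SumStatsTable, harmonize

logger = logging.getLogger(__name__)

__all__ = [
    "ivw_meta",
    "ivw_inverse",
    "z_meta",
    "z_inverse",
    "z_to_beta",
    "pvalue_from_z",
    "estimate_rho",
    "decorrelate",
    "DecorrelationParams",
    "OverlapAdjustment",
    "AdjustmentResults",
    "adjust_table",
]

METHODS = ("ivw", "zscore", "decorrelation")

STATUS_ADJUSTED = "adjusted"
STATUS_PASSTHROUGH = "passthrough"
STATUS_UNSTABLE = "dropped_unstable"


def _as_float(x):
    return np.asarray(x, dtype=float)


def _maybe_scalar(*arrays):
    """Return floats for 0-d results, arrays otherwise."""
    out = tuple(float(a) if np.ndim(a) == 0 else a for a in arrays)
    return out[0] if len(out) == 1 else out


def ivw_meta(b1, se1, b2, se2):
    """Fixed-effect inverse-variance-weighted meta-analysis of two studies.

    Returns the combined ``(beta, se)``:
    ``beta = (b1/se1^2 + b2/se2^2) / (1/se1^2 + 1/se2^2)`` and
    ``se = sqrt(1 / (1/se1^2 + 1/se2^2))``.
    """
    b1, se1, b2, se2 = map(_as_float, (b1, se1, b2, se2))
    if np.any(se1 <= 0) or np.any(se2 <= 0):
        raise ValueError("standard errors must be positive")
    w1, w2 = se1**-2, se2**-2
    b = (b1 * w1 + b2 * w2) / (w1 + w2)
    se = np.sqrt(1.0 / (w1 + w2))
    return _maybe_scalar(b, se)


def ivw_inverse(b_all, se_all, b_o, se_o, eps=1e-12):
    """Invert IVW meta-analysis: remove study *o* from the combined result.

    Solves ``se_s^2 = 1 / (1/se_all^2 - 1/se_o^2)`` and
    ``b_s = se_s^2 * (b_all/se_all^2 - b_o/se_o^2)``.

    The inversion is undefined when the overlap carries at least as much
    precision as the consortium; such entries are flagged unstable rather
    than returned.  Returns ``(b_s, se_s, stable)`` where unstable entries
    hold NaN.
    """
    b_all, se_all, b_o, se_o = map(_as_float, (b_all, se_all, b_o, se_o))
    if np.any(se_all <= 0) or np.any(se_o <= 0):
        raise ValueError("standard errors must be positive")
    w_diff = se_all**-2 - se_o**-2
    stable = w_diff > eps
    var_s = np.where(stable, 1.0 / np.where(stable, w_diff, 1.0), np.nan)
    b_s = var_s * (b_all * se_all**-2 - b_o * se_o**-2)
    se_s = np.sqrt(var_s)
    if np.ndim(stable) == 0:
        return float(b_s), float(se_s), bool(stable)
    return b_s, se_s, stable


def z_meta(z_o, n_o, z_s, n_s):
    """Sample-size-weighted Z-score meta-analysis of two studies.

    ``z = (sqrt(n_o) z_o + sqrt(n_s) z_s) / sqrt(n_o + n_s)``.
    """
    z_o, n_o, z_s, n_s = map(_as_float, (z_o, n_o, z_s, n_s))
    if np.any(n_o <= 0) or np.any(n_s <= 0):
        raise ValueError("sample sizes must be positive")
    z = (np.sqrt(n_o) * z_o + np.sqrt(n_s) * z_s) / np.sqrt(n_o + n_s)
    return _maybe_scalar(z)


def z_inverse(z_all, n_all, z_o, n_o):
    """Invert the Z meta-analysis: remove the overlap study.

    Returns ``(z_s, n_s)`` with ``n_s = n_all - n_o`` and
    ``z_s = (sqrt(n_all) z_all - sqrt(n_o) z_o) / sqrt(n_s)``; by
    construction ``z_meta(z_o, n_o, z_s, n_s) == z_all``.
    """
    z_all, n_all, z_o, n_o = map(_as_float, (z_all, n_all, z_o, n_o))
    if np.any(n_o < 1):
        raise ValueError("overlap sample size must be >= 1")
    if np.any(n_all <= n_o):
        raise ValueError("consortium sample size must exceed the overlap's")
    n_s = n_all - n_o
    z_s = (np.sqrt(n_all) * z_all - np.sqrt(n_o) * z_o) / np.sqrt(n_s)
    return _maybe_scalar(z_s), _maybe_scalar(n_s)


def z_to_beta(z, n, maf):
    """Recover (beta, se) from a Z score, sample size and allele frequency.

    Assumes the phenotype is scaled to mean 0, SD 1, and HWE dosage variance
    ``2 maf (1-maf)``:  ``se = 1/sqrt(2 maf (1-maf) n)``, ``beta = z se``.
    """
    z, n, maf = map(_as_float, (z, n, maf))
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    return _maybe_scalar(z * se), _maybe_scalar(se)


def pvalue_from_z(z):
    """Two-sided standard-normal tail probability, clipped into (0, 1]."""
    p = np.clip(2.0 * stats.norm.sf(np.abs(_as_float(z))), 1e-300, 1.0)
    return _maybe_scalar(p)


def estimate_rho(n_c, n_all, n_o, cor_y):
    """Cross-statistic correlation induced by n_c shared samples.

    ``rho = n_c / sqrt(n_all * n_o) * cor(Y1, Y2)``, the correlation between
    the two studies' Z statistics at null variants.
    """
    if not (1 <= n_c <= min(n_all, n_o)):
        raise ValueError("need 1 <= n_c <= min(n_all, n_o)")
    if abs(cor_y) > 1:
        raise ValueError("|cor_y| must be <= 1")
    rho = n_c / np.sqrt(float(n_all) * float(n_o)) * cor_y
    if abs(rho) >= 1:
        raise ValueError("derived |rho| >= 1: complete overlap cannot be de-correlated")
    return float(rho)


def decorrelate(z_all, z_o, rho):
    """Whiten the consortium Z against the overlap Z.

    ``zeta = (z_all - rho z_o) / sqrt(1 - rho^2)``.  Under a bivariate-normal
    null with correlation ``rho``, the result has unit variance and zero
    correlation with ``z_o``.
    """
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    z_all, z_o = _as_float(z_all), _as_float(z_o)
    return _maybe_scalar((z_all - rho * z_o) / np.sqrt(1.0 - rho**2))


@dataclass
class DecorrelationParams:
    """Known overlap structure for the de-correlation comparator.

    n_c: number of samples shared by the two GWAS; n_all / n_o: their total
    sample sizes; cor_y: phenotype correlation on the shared samples (1 when
    the same trait was measured).
    """

    n_c: int
    n_all: int
    n_o: int
    cor_y: float = 1.0

    @property
    def rho(self) -> float:
        return estimate_rho(self.n_c, self.n_all, self.n_o, self.cor_y)


class OverlapAdjustment:
    """Model object: consortium summary + overlap summary -> adjusted summary.

    Parameters
    ----------
    consortium, overlap
        Validated :class:`SumStatsTable` objects.  They are harmonized on
        construction; harmonization drop counts are kept for reporting.
    method
        ``"ivw"``, ``"zscore"`` or ``"decorrelation"``.
    maf_source
        Allele-frequency source for the Z-to-beta back-transformation:
        ``"consortium"`` (default) or ``"overlap"``.
    params
        :class:`DecorrelationParams`, required for the de-correlation method.
    eps
        Stability floor for the IVW precision difference.
    """

    def __init__(
        self,
        consortium: SumStatsTable,
        overlap: SumStatsTable,
        method: str = "zscore",
        maf_source: str = "consortium",
        params: DecorrelationParams | None = None,
        eps: float = 1e-12,
    ):
        if method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if maf_source not in ("consortium", "overlap"):
            raise ValueError("maf_source must be 'consortium' or 'overlap'")
        if method == "decorrelation" and params is None:
            raise ValueError("decorrelation requires DecorrelationParams")
        self.method = method
        self.maf_source = maf_source
        self.params = params
        self.eps = eps
        self.pairs: MatchedPairs = harmonize(consortium, overlap)

    def _maf(self, pairs: pd.DataFrame) -> np.ndarray:
        col = "maf_all" if self.maf_source == "consortium" else "maf_o"
        maf = pairs[col].to_numpy(dtype=float)
        if np.isnan(maf).any():
            raise ValueError(
                f"method {self.method!r} needs MAF from the {self.maf_source} table, "
                "but it is missing for some variants"
            )
        return maf

    def _need(self, pairs: pd.DataFrame, cols: list[str]):
        out = []
        for c in cols:
            v = pairs[c].to_numpy(dtype=float)
            if np.isnan(v).any():
                raise ValueError(f"column {c!r} required by method {self.method!r} has missing values")
            out.append(v)
        return out

    def fit(self) -> "AdjustmentResults":
        pairs = self.pairs.pairs
        adj = pd.DataFrame(
            {
                "variant_id": pairs["variant_id"],
                "chrom": pairs["chrom_all"],
                "pos": pairs["pos_all"],
                "effect_allele": pairs["effect_allele_all"],
                "other_allele": pairs["other_allele_all"],
                "maf": pairs["maf_all"],
            }
        )
        status = np.full(len(pairs), STATUS_ADJUSTED, dtype=object)

        if self.method == "ivw":
            b_all, se_all, b_o, se_o = self._need(
                pairs, ["beta_all", "se_all", "beta_o", "se_o"]
            )
            b_s, se_s, stable = ivw_inverse(b_all, se_all, b_o, se_o, eps=self.eps)
            z_s = np.where(stable, b_s / se_s, np.nan)
            status[~stable] = STATUS_UNSTABLE
            n_s = pairs["n_all"].to_numpy(dtype=float) - pairs["n_o"].to_numpy(dtype=float)
            adj["beta"], adj["se"], adj["zscore"], adj["n"] = b_s, se_s, z_s, n_s
        elif self.method == "zscore":
            z_all, n_all, z_o, n_o = self._need(
                pairs, ["zscore_all", "n_all", "zscore_o", "n_o"]
            )
            maf = self._maf(pairs)
            z_s, n_s = z_inverse(z_all, n_all, z_o, n_o)
            b_s, se_s = z_to_beta(z_s, n_s, maf)
            adj["beta"], adj["se"], adj["zscore"], adj["n"] = b_s, se_s, z_s, n_s
            adj["maf"] = maf
        else:  # decorrelation
            z_all, z_o = self._need(pairs, ["zscore_all", "zscore_o"])
            rho = self.params.rho
            zeta = decorrelate(z_all, z_o, rho)
            n_all = pairs["n_all"].to_numpy(dtype=float)
            maf = self._maf(pairs)
            b, se = z_to_beta(zeta, n_all, maf)
            adj["beta"], adj["se"], adj["zscore"], adj["n"] = b, se, zeta, n_all
            adj["maf"] = maf

        adj["pvalue"] = np.where(
            status == STATUS_ADJUSTED, pvalue_from_z(adj["zscore"].to_numpy()), np.nan
        )
        adj["status"] = status

        passthrough = self.pairs.passthrough.df.copy()
        passthrough["status"] = STATUS_PASSTHROUGH
        full = pd.concat([adj, passthrough], ignore_index=True)[
            CANONICAL_COLUMNS + ["status"]
        ]
        return AdjustmentResults(self, full)


@dataclass
class AdjustmentResults:
    """Adjusted summary statistics plus per-variant statuses and diagnostics."""

    model: OverlapAdjustment
    table: pd.DataFrame  # canonical columns + status

    @property
    def method(self) -> str:
        return self.model.method

    @property
    def adjusted(self) -> SumStatsTable:
        """Usable output: adjusted + passthrough rows (unstable rows excluded)."""
        keep = self.table["status"] != STATUS_UNSTABLE
        return SumStatsTable.from_dataframe(
            self.table.loc[keep, CANONICAL_COLUMNS].reset_index(drop=True), validate=False
        )

    @property
    def status_counts(self) -> dict[str, int]:
        return self.table["status"].value_counts().to_dict()

    @property
    def mean_se_inflation(self) -> float:
        """Mean ratio of adjusted to consortium SE over adjusted variants.

        Removing samples removes information, so for the IVW method this is
        strictly greater than 1.
        """
        pairs = self.model.pairs.pairs
        mask = (self.table["status"] == STATUS_ADJUSTED).to_numpy()[: len(pairs)]
        se_all = pairs["se_all"].to_numpy(dtype=float)[mask]
        se_adj = self.table["se"].to_numpy(dtype=float)[: len(pairs)][mask]
        with np.errstate(invalid="ignore"):
            ratio = se_adj / se_all
        return float(np.nanmean(ratio))

    def summary(self) -> str:
        counts = self.status_counts
        drops = dict(self.model.pairs.drop_counts)
        lines = [
            "Overlap adjustment results",
            "==========================",
            f"method:            {self.method}",
            f"matched variants:  {len(self.model.pairs)}",
            f"flipped alleles:   {self.model.pairs.n_flipped}",
        ]
        for k in (STATUS_ADJUSTED, STATUS_PASSTHROUGH, STATUS_UNSTABLE):
            lines.append(f"{k + ':':<19}{counts.get(k, 0)}")
        for k, v in sorted(drops.items()):
            lines.append(f"dropped ({k}): {v}")
        try:
            lines.append(f"mean SE inflation: {self.mean_se_inflation:.4f}")
        except (KeyError, ValueError):
            pass
        if self.method == "decorrelation":
            lines.append(f"rho:               {self.model.params.rho:.6f}")
        return "\n".join(lines)


def adjust_table(
    consortium: SumStatsTable,
    overlap: SumStatsTable,
    method: str = "zscore",
    maf_source: str = "consortium",
    params: DecorrelationParams | None = None,
    eps: float = 1e-12,
) -> AdjustmentResults:
    """One-call convenience wrapper around :class:`OverlapAdjustment`."""
    return OverlapAdjustment(
        consortium, overlap, method=method, maf_source=maf_source, params=params, eps=eps
    ).fit()
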