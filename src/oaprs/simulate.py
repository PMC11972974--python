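"""Synthetic genotype/phenotype data with controlled train/target overlap.

The generator emulates a biobank overlap-injection design: a population of
``n_train + n_target`` unrelated individuals is simulated with biallelic
genotypes in Hardy–Weinberg equilibrium, a sparse-causal additive liability
with heritability ``h2``, and a binary phenotype from a liability threshold
at the configured prevalence.  The population is split into a training and a
target partition, and a chosen fraction (or explicit case/control counts) of
target samples is additionally merged into the training set, producing the
three partition labels ``train_only`` / ``overlap`` / ``target_only``.

Per-partition association summaries are computed by :func:`run_gwas` —
per-variant simple linear regression of the (standardized) phenotype on
dosage — so that the full stack (adjustment, PRS, diagnostics) is testable
end to end without external data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adjust import pvalue_from_z
from .sumstats import SumStatsTable, _fold_maf

__all__ = [
    "SimConfig",
    "SimDataset",
    "simulate_population",
    "run_gwas",
    "make_design_grid",
    "derive_seed",
]

PARTITIONS = ("train_only", "overlap", "target_only")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one overlap-injection experiment.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 2,000 variants with 50 causal, h2 = 0.5 on the liability scale,
    prevalence 0.3, 8,000 training and 2,000 target samples, and 30% of the
    target merged into training.
    """

    n_variants: int = 2000
    n_causal: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2: float = 0.5
    prevalence: float = 0.3
    n_train: int = 8000
    n_target: int = 2000
    overlap_fraction: float = 0.3
    overlap_counts: tuple[int, int] | None = None  # (cases, controls) from target
    ld_block_size: int | None = None  # None = linkage equilibrium
    ld_r2: float = 0.9  # target minimum pairwise dosage r^2 within a block
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.n_causal <= self.n_variants or self.h2 == 0):
            raise ValueError("need 0 < n_causal <= n_variants (unless h2 == 0)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.h2 < 1):
            raise ValueError("h2 must lie in [0, 1)")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_train <= 0 or self.n_target <= 0:
            raise ValueError("sample sizes must be positive")
        if not (0 <= self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must lie in [0, 1]")


@dataclass
class SimDataset:
    """Realized genotypes, phenotype, true effects, and partition labels."""

    genotypes: np.ndarray  # (n_samples, n_variants), dosages {0,1,2}, int8
    phenotype: np.ndarray  # binary, int8
    liability: np.ndarray
    beta_true: np.ndarray  # per-variant liability-scale effects
    partition: np.ndarray  # str labels, one per sample
    variant_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    allele_freq: np.ndarray  # generating frequency of the effect allele
    config: SimConfig = field(repr=False, default=None)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def subset_indices(self, subset) -> np.ndarray:
        """Resolve a partition selector to sample indices.

        Selectors: ``train`` (train_only ∪ overlap — the "consortium"),
        ``train_only``, ``overlap``, ``target`` (overlap ∪ target_only),
        ``target_only``, ``all``, or an explicit index array.
        """
        if not isinstance(subset, str):
            return np.asarray(subset, dtype=int)
        p = self.partition
        if subset == "all":
            return np.arange(self.n_samples)
        if subset == "train":
            return np.flatnonzero((p == "train_only") | (p == "overlap"))
        if subset == "target":
            return np.flatnonzero((p == "overlap") | (p == "target_only"))
        if subset in PARTITIONS:
            return np.flatnonzero(p == subset)
        raise ValueError(f"unknown partition selector {subset!r}")

    def variant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "chrom": self.chrom,
                "pos": self.pos,
                "effect_allele": self.effect_allele,
                "other_allele": self.other_allele,
            }
        )


def _draw_genotypes(cfg: SimConfig, rng: np.random.Generator):
    n = cfg.n_train + cfg.n_target
    m = cfg.n_variants
    if cfg.ld_block_size is None:
        freq = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
        geno = rng.binomial(2, freq, size=(n, m)).astype(np.int8)
        return geno, freq
    # Block-exchangeable LD by haplotype copying: within a block every
    # variant shares the tag's allele with probability c and resamples
    # otherwise, giving pairwise dosage correlation c (tag-other) and c^2
    # (other-other); c = ld_r2 ** 0.25 makes the weakest pair hit ~ld_r2.
    bs = cfg.ld_block_size
    copy_p = cfg.ld_r2**0.25
    n_blocks = int(np.ceil(m / bs))
    block_freq = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n_blocks)
    freq = np.repeat(block_freq, bs)[:m]
    geno = np.empty((n, m), dtype=np.int8)
    for b in range(n_blocks):
        lo, hi = b * bs, min((b + 1) * bs, m)
        p = block_freq[b]
        tag = rng.random((n, 2)) < p  # two haplotypes
        for j in range(lo, hi):
            if j == lo:
                hap = tag
            else:
                keep = rng.random((n, 2)) < copy_p
                hap = np.where(keep, tag, rng.random((n, 2)) < p)
            geno[:, j] = hap.sum(axis=1)
    return geno, freq


def simulate_population(config: SimConfig) -> SimDataset:
    """Draw one dataset under the liability-threshold disease model."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_train + cfg.n_target
    geno, freq = _draw_genotypes(cfg, rng)

    beta_true = np.zeros(cfg.n_variants)
    if cfg.h2 > 0:
        causal = rng.choice(cfg.n_variants, size=cfg.n_causal, replace=False)
        beta_true[causal] = rng.normal(0.0, np.sqrt(cfg.h2 / cfg.n_causal), cfg.n_causal)
        x = geno.astype(np.float64)
        x -= x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        g = (x[:, causal] / sd[causal]) @ beta_true[causal]
        g_sd = g.std()
        if g_sd > 0:
            g = g / g_sd * np.sqrt(cfg.h2)
        liability = g + rng.normal(0.0, np.sqrt(1.0 - cfg.h2), n)
    else:
        liability = rng.normal(0.0, 1.0, n)

    thresh = np.quantile(liability, 1.0 - cfg.prevalence)
    pheno = (liability > thresh).astype(np.int8)

    partition = np.empty(n, dtype=object)
    partition[: cfg.n_train] = "train_only"
    partition[cfg.n_train :] = "target_only"
    target_idx = np.arange(cfg.n_train, n)
    if cfg.overlap_counts is not None:
        k_case, k_ctrl = cfg.overlap_counts
        cases = target_idx[pheno[target_idx] == 1]
        ctrls = target_idx[pheno[target_idx] == 0]
        if k_case > len(cases) or k_ctrl > len(ctrls):
            raise ValueError("overlap_counts exceed available target cases/controls")
        chosen = np.concatenate(
            [
                rng.choice(cases, size=k_case, replace=False),
                rng.choice(ctrls, size=k_ctrl, replace=False),
            ]
        )
        partition[chosen] = "overlap"
    elif cfg.overlap_fraction > 0:
        k = int(round(cfg.overlap_fraction * cfg.n_target))
        chosen = rng.choice(target_idx, size=k, replace=False)
        partition[chosen] = "overlap"

    m = cfg.n_variants
    return SimDataset(
        genotypes=geno,
        phenotype=pheno,
        liability=liability,
        beta_true=beta_true,
        partition=partition,
        variant_ids=np.array([f"rs{j + 1}" for j in range(m)]),
        chrom=np.full(m, "1", dtype=object),
        pos=np.arange(1, m + 1) * 1000,
        effect_allele=np.full(m, "A", dtype=object),
        other_allele=np.full(m, "G", dtype=object),
        allele_freq=freq,
        config=cfg,
    )


def run_gwas(
    dataset: SimDataset,
    subset="train",
    standardize_phenotype: bool = True,
    engine: str = "linear",
) -> SumStatsTable:
    """Per-variant association summary on a sample subset.

    ``engine="linear"`` (default) regresses the — optionally standardized —
    phenotype on dosage by simple linear regression; this matches the
    standardized-phenotype scaling the Z-to-beta back-transformation assumes
    and makes meta-decomposition across disjoint partitions near-exact.
    ``engine="logistic"`` computes the logistic score test instead (a realism
    check; betas are then Z-derived at the subset MAF).

    Monomorphic variants in the subset are emitted with zscore 0 and a
    missing standard error.
    """
    idx = dataset.subset_indices(subset)
    if len(idx) < 3:
        raise ValueError("degenerate subset: need at least 3 samples")
    y = dataset.phenotype[idx].astype(np.float64)
    if y.min() == y.max():
        raise ValueError("degenerate subset: phenotype has a single class")
    n = len(idx)
    X = dataset.genotypes[idx].astype(np.float64)
    xm = X.mean(axis=0)
    sxx = np.einsum("ij,ij->j", X, X) - n * xm**2
    poly = sxx > 0

    if standardize_phenotype:
        y = (y - y.mean()) / y.std()
    ym = y.mean()
    syy = float(y @ y - n * ym**2)
    sxy = X.T @ y - n * xm * ym

    beta = np.zeros(dataset.n_variants)
    se = np.full(dataset.n_variants, np.nan)
    z = np.zeros(dataset.n_variants)
    if engine == "linear":
        beta[poly] = sxy[poly] / sxx[poly]
        rss = np.maximum(syy - beta[poly] * sxy[poly], 0.0)
        with np.errstate(divide="ignore"):
            se[poly] = np.sqrt(rss / ((n - 2) * sxx[poly]))
        ok = poly.copy()
        ok[poly] &= se[poly] > 0
        z[ok] = beta[ok] / se[ok]
    elif engine == "logistic":
        mu = dataset.phenotype[idx].mean()
        u = X.T @ (dataset.phenotype[idx] - mu)
        v = mu * (1 - mu) * sxx
        z[poly] = u[poly] / np.sqrt(v[poly])
        maf_sub = xm / 2.0
        var_x = 2 * maf_sub * (1 - maf_sub)
        se[poly] = 1.0 / np.sqrt(np.maximum(var_x[poly], 1e-12) * n)
        beta[poly] = z[poly] * se[poly]
    else:
        raise ValueError("engine must be 'linear' or 'logistic'")

    maf = _fold_maf(xm / 2.0)
    maf = np.where(poly, maf, np.nan)
    df = pd.DataFrame(
        {
            "variant_id": dataset.variant_ids,
            "chrom": dataset.chrom,
            "pos": dataset.pos,
            "effect_allele": dataset.effect_allele,
            "other_allele": dataset.other_allele,
            "beta": beta,
            "se": se,
            "zscore": z,
            "pvalue": pvalue_from_z(z),
            "n": float(n),
            "maf": maf,
        }
    )
    return SumStatsTable.from_dataframe(df, validate=False)


def derive_seed(*parts) -> int:
    """Stable sub-2^31 seed derived from arbitrary labelled parts."""
    key = ":".join(repr(p) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def make_design_grid(
    split_ratios, overlap_fractions, base: SimConfig
) -> list[SimConfig]:
    """Cartesian grid of overlap-injection configurations.

    Each (split ratio, overlap fraction) cell keeps the base config's total
    sample count and gets a deterministic seed derived from the base seed
    and the cell coordinates.
    """
    n_total = base.n_train + base.n_target
    grid = []
    for r in split_ratios:
        if not (0 < r < 1):
            raise ValueError("split ratios must lie in (0, 1)")
        for f in overlap_fractions:
            if not (0 <= f <= 1):
                raise ValueError("overlap fractions must lie in [0, 1]")
            n_train = int(round(r * n_total))
            grid.append(
                replace(
                    base,
                    n_train=n_train,
                    n_target=n_total - n_train,
                    overlap_fraction=f,
                    overlap_counts=None,
                    seed=derive_seed(base.seed, r, f),
                )
            )
    return grid
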