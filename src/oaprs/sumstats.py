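"""Reading, validating, and harmonizing GWAS summary-statistic tables.

The canonical in-memory container is :class:`SumStatsTable`, a thin wrapper
around a :class:`pandas.DataFrame` with one row per variant and the columns

    variant_id, chrom, pos, effect_allele, other_allele,
    beta, se, zscore, pvalue, n, maf

``beta`` is the per-allele effect on a phenotype scaled to mean 0, SD 1;
``maf`` is always stored folded into (0, 0.5].  Validation fills derivable
fields (Z from beta/se, P from Z) and drops rows that violate the container's
invariants, keeping an audit of drop reasons.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SumStatsTable",
    "MatchedPairs",
    "SumStatsError",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "flip_effects",
]

CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "zscore",
    "pvalue",
    "n",
    "maf",
]

#: lower-cased header synonyms for the common sumstats dialects
COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "variant_id": ("variant_id", "snp", "id", "rsid", "rs_id", "markername", "snpid"),
    "chrom": ("chrom", "chr", "chromosome", "#chrom"),
    "pos": ("pos", "bp", "position", "base_pair_location"),
    "effect_allele": ("effect_allele", "a1", "alt", "ea", "allele1"),
    "other_allele": ("other_allele", "a2", "ref", "oa", "nea", "allele2", "allele0"),
    "beta": ("beta", "effect", "b", "effect_size"),
    "se": ("se", "stderr", "standard_error"),
    "pvalue": ("pvalue", "p", "p-value", "pval", "p_value"),
    "zscore": ("zscore", "z", "z_score", "zstat"),
    "n": ("n", "nsample", "samplesize", "n_total"),
    "maf": ("maf", "eaf", "af", "effect_allele_frequency", "freq"),
}

_NUMERIC = ("pos", "beta", "se", "zscore", "pvalue", "n", "maf")
_MANDATORY = ("variant_id", "effect_allele", "other_allele")

PALINDROMIC_SETS = (frozenset({"A", "T"}), frozenset({"C", "G"}))

_Z_RTOL = 1e-6  # relative tolerance for |z - beta/se| and the p/z consistency check


class SumStatsError(ValueError):
    """Unrecoverable problem with a summary-statistics input."""


def _fold_maf(freq):
    """Fold an allele frequency into the minor-allele range (0, 0.5]."""
    freq = np.asarray(freq, dtype=float)
    return np.minimum(freq, 1.0 - freq)


def flip_effects(beta, zscore, eaf):
    """Re-orient a record onto the opposite effect allele.

    Negates ``beta`` and ``zscore`` and complements the effect-allele
    frequency.  Applying the flip twice restores the inputs exactly.
    """
    beta = np.asarray(beta, dtype=float)
    zscore = np.asarray(zscore, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    return -beta, -zscore, 1.0 - eaf


def _pvalue_two_sided(z):
    z = np.asarray(z, dtype=float)
    return np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)


@dataclass
class SumStatsTable:
    """Validated per-variant association summary for one cohort."""

    df: pd.DataFrame
    drop_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.df["variant_id"].to_numpy()

    def subset(self, variant_ids) -> "SumStatsTable":
        """Rows for the given variant ids, in the table's own order."""
        keep = self.df["variant_id"].isin(set(variant_ids))
        return SumStatsTable(self.df.loc[keep].reset_index(drop=True))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, validate: bool = True) -> "SumStatsTable":
        """Build a table from any DataFrame carrying canonical column names."""
        out = pd.DataFrame(index=range(len(df)))
        for col in CANONICAL_COLUMNS:
            if col in df.columns:
                out[col] = np.asarray(df[col])
            else:
                out[col] = np.nan
        out["variant_id"] = out["variant_id"].astype(str)
        for col in ("effect_allele", "other_allele"):
            out[col] = out[col].astype(str).str.upper()
        for col in _NUMERIC:
            out[col] = pd.to_numeric(out[col], errors="coerce")
        if not validate:
            return cls(out)
        return _validate(out)

    def copy(self) -> "SumStatsTable":
        return SumStatsTable(self.df.copy(), dict(self.drop_counts))


def _validate(df: pd.DataFrame) -> SumStatsTable:
    drops: dict[str, int] = {}

    def drop(mask: np.ndarray, reason: str):
        nonlocal df
        k = int(mask.sum())
        if k:
            drops[reason] = drops.get(reason, 0) + k
            df = df.loc[~mask].reset_index(drop=True)

    dup = df["variant_id"].duplicated(keep="first").to_numpy()
    drop(dup, "duplicate_id")

    bad_se = (df["se"].notna() & (df["se"] <= 0)).to_numpy()
    drop(bad_se, "nonpositive_se")

    # fill z from beta/se where derivable, check consistency where redundant
    have_bs = df["beta"].notna() & df["se"].notna()
    z_bs = df["beta"] / df["se"]
    fill = have_bs & df["zscore"].isna()
    df.loc[fill, "zscore"] = z_bs[fill]
    redundant = have_bs & df["zscore"].notna() & ~fill
    if redundant.any():
        mism = (
            np.abs(df["zscore"] - z_bs) > _Z_RTOL * np.maximum(1.0, np.abs(df["zscore"]))
        ) & redundant
        drop(mism.to_numpy(), "inconsistent_zscore")

    no_signal = (df["zscore"].isna() & ~(df["beta"].notna() & df["se"].notna())).to_numpy()
    drop(no_signal, "no_signal")

    # p from z: fill when missing, recompute (with a warning) when inconsistent
    have_z = df["zscore"].notna()
    p_z = pd.Series(_pvalue_two_sided(df["zscore"].to_numpy()), index=df.index)
    fill_p = have_z & (df["pvalue"].isna() | (df["pvalue"] <= 0) | (df["pvalue"] > 1))
    df.loc[fill_p, "pvalue"] = p_z[fill_p]
    check = have_z & ~fill_p & df["pvalue"].notna()
    if check.any():
        mism = (np.abs(df["pvalue"] - p_z) > _Z_RTOL * np.maximum(df["pvalue"], p_z)) & check
        if mism.any():
            logger.warning(
                "%d rows had P values inconsistent with Z; recomputed from Z",
                int(mism.sum()),
            )
            df.loc[mism, "pvalue"] = p_z[mism]
    bad_p = (df["pvalue"].isna() | (df["pvalue"] <= 0) | (df["pvalue"] > 1)).to_numpy()
    drop(bad_p, "invalid_pvalue")

    # fold allele frequencies; clear out-of-range values
    df["maf"] = _fold_maf(df["maf"].to_numpy())
    bad_maf = df["maf"].notna() & ((df["maf"] <= 0) | (df["maf"] > 0.5))
    if bad_maf.any():
        drops["invalid_maf_cleared"] = int(bad_maf.sum())
        df.loc[bad_maf, "maf"] = np.nan

    bad_n = df["n"].notna() & (df["n"] <= 0)
    if bad_n.any():
        drops["invalid_n_cleared"] = int(bad_n.sum())
        df.loc[bad_n, "n"] = np.nan

    return SumStatsTable(df.reset_index(drop=True), drops)


def _resolve_columns(header: list[str], dialect) -> dict[str, str]:
    """Map canonical roles to actual column names."""
    mapping: dict[str, str] = {}
    lower = {h.lower(): h for h in header}
    if isinstance(dialect, dict):
        for role, name in dialect.items():
            if role not in CANONICAL_COLUMNS:
                raise SumStatsError(f"unknown column role {role!r} in dialect")
            if name not in header:
                raise SumStatsError(f"dialect maps {role!r} to absent column {name!r}")
            mapping[role] = name
    elif dialect != "auto":
        raise SumStatsError("dialect must be 'auto' or a role->column mapping")
    for role, syns in COLUMN_SYNONYMS.items():
        if role in mapping:
            continue
        for syn in syns:
            if syn in lower:
                mapping[role] = lower[syn]
                break
    return mapping


def read_sumstats(path, dialect="auto") -> SumStatsTable:
    """Read a tab-delimited (optionally gzipped) summary-statistics file.

    Parameters
    ----------
    path
        File with a header row.  Common header synonyms are recognised when
        ``dialect="auto"`` (SNP/ID/rsid; A1/ALT/EA; A2/REF/OA/NEA; BETA/Effect;
        SE/StdErr; P/pval; N; Z; MAF/EAF — an EAF > 0.5 is folded to MAF).
    dialect
        ``"auto"`` or an explicit ``{role: column_name}`` mapping.
    """
    raw = pd.read_csv(path, sep="\t", compression="infer", dtype=str)
    mapping = _resolve_columns(list(raw.columns), dialect)
    missing = [role for role in _MANDATORY if role not in mapping]
    has_bs = "beta" in mapping and "se" in mapping
    has_z = all(r in mapping for r in ("zscore", "n", "maf"))
    if missing or not (has_bs or has_z):
        need = missing or ["beta+se or zscore+n+maf"]
        raise SumStatsError(f"cannot resolve mandatory column(s): {', '.join(need)}")
    renamed = raw[[mapping[r] for r in mapping]].copy()
    renamed.columns = list(mapping)
    table = SumStatsTable.from_dataframe(renamed)
    if len(table) == 0:
        raise SumStatsError(f"no valid rows remain after validation of {path}")
    return table


def write_sumstats(table: SumStatsTable, path) -> None:
    """Write the canonical tab-delimited representation (NA for missing)."""
    if len(table) == 0:
        raise SumStatsError("refusing to write an empty summary-statistics table")
    out = table.df[CANONICAL_COLUMNS]
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        # 10 significant digits: comfortably exceeds the 6-digit round-trip
        # guarantee and keeps re-read rows inside the z ~ beta/se tolerance
        out.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.10g")


@dataclass
class MatchedPairs:
    """Allele-harmonized join of a consortium and an overlap summary.

    ``pairs`` has one row per retained variant with consortium columns
    suffixed ``_all`` and overlap columns suffixed ``_o``; overlap effects are
    already on the consortium's effect-allele orientation (``flipped`` marks
    rows whose overlap record was re-oriented).  Consortium-only variants are
    returned in ``passthrough``; they carry no overlap signal.
    """

    pairs: pd.DataFrame
    passthrough: SumStatsTable
    drop_counts: dict[str, int]

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_flipped(self) -> int:
        return int(self.pairs["flipped"].sum())


def harmonize(consortium: SumStatsTable, overlap: SumStatsTable) -> MatchedPairs:
    """Join two summaries on variant_id, reconciling allele orientation.

    Overlap records whose effect/other alleles are swapped relative to the
    consortium are flipped (beta and Z negated; the folded MAF is unchanged
    under complementation).  Pairs with incompatible allele sets and
    strand-ambiguous palindromic variants (A/T, C/G) are dropped and counted.
    """
    c = consortium.df.add_suffix("_all").rename(columns={"variant_id_all": "variant_id"})
    o = overlap.df.add_suffix("_o").rename(columns={"variant_id_o": "variant_id"})
    merged = c.merge(o, on="variant_id", how="inner")
    only_ids = set(consortium.df["variant_id"]) - set(merged["variant_id"])
    passthrough = consortium.subset(only_ids)

    drops: dict[str, int] = {"overlap_only": int(len(overlap) - len(merged))}

    ea_c, oa_c = merged["effect_allele_all"], merged["other_allele_all"]
    ea_o, oa_o = merged["effect_allele_o"], merged["other_allele_o"]
    palin = (
        ((ea_c == "A") & (oa_c == "T"))
        | ((ea_c == "T") & (oa_c == "A"))
        | ((ea_c == "C") & (oa_c == "G"))
        | ((ea_c == "G") & (oa_c == "C"))
    )
    same = (ea_c == ea_o) & (oa_c == oa_o)
    swapped = (ea_c == oa_o) & (oa_c == ea_o)
    mismatch = ~(same | swapped)

    drops["palindromic"] = int((palin & ~mismatch).sum())
    drops["allele_mismatch"] = int(mismatch.sum())

    keep = merged.loc[~(palin | mismatch)].reset_index(drop=True)
    flip = ((keep["effect_allele_all"] == keep["other_allele_o"])).to_numpy()
    if flip.any():
        b, z, eaf = flip_effects(
            keep.loc[flip, "beta_o"], keep.loc[flip, "zscore_o"], keep.loc[flip, "maf_o"]
        )
        keep.loc[flip, "beta_o"] = b
        keep.loc[flip, "zscore_o"] = z
        keep.loc[flip, "maf_o"] = _fold_maf(eaf)
        keep.loc[flip, "effect_allele_o"] = keep.loc[flip, "effect_allele_all"]
        keep.loc[flip, "other_allele_o"] = keep.loc[flip, "other_allele_all"]
    keep["flipped"] = flip

    if len(keep) == 0:
        raise SumStatsError("no variants remain after harmonization; nothing to adjust")
    return MatchedPairs(keep, passthrough, drops)
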