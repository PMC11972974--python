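"""Meta-inverse algebra: forward/backward exactness and the de-correlation map."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oaprs.adjust import (
    DecorrelationParams,
    OverlapAdjustment,
    adjust_table,
    decorrelate,
    estimate_rho,
    ivw_inverse,
    ivw_meta,
    pvalue_from_z,
    z_inverse,
    z_meta,
    z_to_beta,
)
from oaprs.simulate import run_gwas
from oaprs.sumstats import SumStatsTable, harmonize

from conftest import make_table

finite = dict(allow_nan=False, allow_infinity=False)


class TestIVW:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((0.0866667, 0.0516398, 0.30, 0.20), (0.10, 0.05)),  # hand arithmetic
        ],
    )
    def test_meta_values(self, args, expected):
        b, se = ivw_meta(*args)
        assert b == pytest.approx(expected[0], abs=1e-4)
        assert se == pytest.approx(expected[1], abs=1e-4)

    def test_meta_equal_inputs(self):
        b, se = ivw_meta(0.2, 0.1, 0.2, 0.1)
        assert b == pytest.approx(0.2)
        assert se == pytest.approx(0.1 / np.sqrt(2))

    def test_meta_uninformative_study_is_noop(self):
        b, se = ivw_meta(0.2, 0.1, 0.9, 1e6)
        assert b == pytest.approx(0.2, abs=1e-6)
        assert se == pytest.approx(0.1, abs=1e-6)

    def test_meta_rejects_nonpositive_se(self):
        with pytest.raises(ValueError):
            ivw_meta(0.1, 0.0, 0.1, 0.1)

    def test_inverse_values(self):
        b_s, se_s, stable = ivw_inverse(0.10, 0.05, 0.30, 0.20)
        assert stable
        assert b_s == pytest.approx(0.0866667, abs=1e-6)
        assert se_s == pytest.approx(0.0516398, abs=1e-6)

    def test_inverse_of_uninformative_overlap_is_noop(self):
        b_s, se_s, stable = ivw_inverse(0.1, 0.05, 123.0, 1e9)
        assert stable
        assert b_s == pytest.approx(0.1, abs=1e-9)
        assert se_s == pytest.approx(0.05, abs=1e-9)

    def test_equal_precision_is_unstable(self):
        _, _, stable = ivw_inverse(0.1, 0.1, 0.1, 0.1)
        assert not stable

    @given(
        b_o=st.floats(-2, 2, **finite),
        se_o=st.floats(0.01, 5, **finite),
        b_s=st.floats(-2, 2, **finite),
        se_s=st.floats(0.01, 5, **finite),
    )
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_meta_of_inverse(self, b_o, se_o, b_s, se_s):
        """inverse(meta(o, s), o) == s for every valid pair of studies."""
        b_all, se_all = ivw_meta(b_o, se_o, b_s, se_s)
        b_back, se_back, stable = ivw_inverse(b_all, se_all, b_o, se_o)
        assert stable
        assert b_back == pytest.approx(b_s, rel=1e-9, abs=1e-9)
        assert se_back == pytest.approx(se_s, rel=1e-9)

    def test_monotone_information_loss(self):
        rng = np.random.default_rng(7)
        se_all = rng.uniform(0.01, 0.1, 500)
        se_o = se_all * rng.uniform(1.5, 10, 500)  # overlap always noisier
        _, se_s, stable = ivw_inverse(rng.normal(size=500), se_all, rng.normal(size=500), se_o)
        assert stable.all()
        assert np.all(se_s > se_all)


class TestZScore:
    def test_meta_value(self):
        assert z_meta(2.0, 100, 2.49559, 900) == pytest.approx(3.0, abs=1e-4)

    def test_meta_identical_z_amplifies_evidence(self):
        # two independent studies observing the same z strengthen it by
        # (sqrt(n_o) + sqrt(n_s)) / sqrt(n_o + n_s) > 1
        expected = 1.7 * (np.sqrt(100) + np.sqrt(900)) / np.sqrt(1000)
        assert z_meta(1.7, 100, 1.7, 900) == pytest.approx(expected, rel=1e-12)

    def test_null_preserved(self):
        assert z_meta(0.0, 50, 0.0, 150) == 0.0
        z_s, _ = z_inverse(0.0, 200, 0.0, 50)
        assert z_s == 0.0

    def test_inverse_values(self):
        z_s, n_s = z_inverse(3.0, 1000, 2.0, 100)
        assert n_s == 900
        assert z_s == pytest.approx(2.49559, abs=1e-4)

    def test_inverse_rejects_no_remainder(self):
        with pytest.raises(ValueError):
            z_inverse(1.0, 100, 1.0, 100)

    @given(
        z_all=st.floats(-30, 30, **finite),
        z_o=st.floats(-30, 30, **finite),
        n_all=st.integers(3, 10**6),
        n_o=st.integers(1, 10**6),
    )
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_exactness(self, z_all, z_o, n_all, n_o):
        """z_meta(z_o, n_o, z_inverse(...)) reproduces z_all exactly."""
        if n_o >= n_all:
            n_o = n_all - 1
        z_s, n_s = z_inverse(z_all, n_all, z_o, n_o)
        assert z_meta(z_o, n_o, z_s, n_s) == pytest.approx(z_all, abs=1e-10)


class TestZToBeta:
    @pytest.mark.parametrize(
        "z, n, maf, beta, se",
        [
            (1.0, 200, 0.5, 0.1, 0.1),
            (2.0, 800, 0.25, 0.11547, 1 / np.sqrt(300)),
            (0.0, 1000, 0.1, 0.0, None),
        ],
    )
    def test_values(self, z, n, maf, beta, se):
        b, s = z_to_beta(z, n, maf)
        assert b == pytest.approx(beta, abs=1e-5)
        if se is not None:
            assert s == pytest.approx(se, rel=1e-6)

    def test_rejects_bad_maf(self):
        with pytest.raises(ValueError):
            z_to_beta(1.0, 100, 0.7)


class TestPvalue:
    @pytest.mark.parametrize(
        "z, p, tol",
        [(0.0, 1.0, 1e-12), (1.959964, 0.05, 1e-4), (3.0, 0.0026998, 1e-6)],
    )
    def test_two_sided_tail(self, z, p, tol):
        assert pvalue_from_z(z) == pytest.approx(p, abs=tol)


class TestDecorrelation:
    def test_rho_value(self):
        assert estimate_rho(300, 30000, 1000, 1.0) == pytest.approx(0.05477, abs=1e-4)

    def test_rho_zero_phenotype_correlation(self):
        assert estimate_rho(500, 1000, 1000, 0.0) == 0.0

    def test_complete_overlap_is_hard_error(self):
        with pytest.raises(ValueError):
            estimate_rho(1000, 1000, 1000, 1.0)

    def test_identity_at_rho_zero(self):
        assert decorrelate(1.234, -0.7, 0.0) == pytest.approx(1.234)

    def test_hand_value(self):
        assert decorrelate(2.0, 2.0, 0.5) == pytest.approx(1.0 / np.sqrt(0.75), rel=1e-9)

    def test_monte_carlo_nulls_correlation(self):
        rho = 0.3
        rng = np.random.default_rng(11)
        cov = [[1, rho], [rho, 1]]
        z = rng.multivariate_normal([0, 0], cov, size=100_000)
        zeta = decorrelate(z[:, 0], z[:, 1], rho)
        assert abs(np.corrcoef(zeta, z[:, 1])[0, 1]) < 0.01
        assert np.var(zeta) == pytest.approx(1.0, abs=0.02)


def _split_meta_tables(n=100, seed=3):
    """Two disjoint sub-GWAS and their exact IVW meta ("consortium")."""
    sub_a = make_table(n, seed=seed)
    sub_b = make_table(n, seed=seed + 1)
    b, se = ivw_meta(
        sub_a.df["beta"].to_numpy(),
        sub_a.df["se"].to_numpy(),
        sub_b.df["beta"].to_numpy(),
        sub_b.df["se"].to_numpy(),
    )
    cons_df = sub_a.df.copy()
    cons_df["beta"], cons_df["se"] = b, se
    cons_df["zscore"] = np.nan
    cons_df["pvalue"] = np.nan
    cons_df["n"] = sub_a.df["n"] + sub_b.df["n"]
    return SumStatsTable.from_dataframe(cons_df), sub_a, sub_b


class TestAdjustTable:
    def test_ivw_recovers_held_out_subgwas_exactly(self):
        """Consortium built as exact IVW meta of two disjoint sub-GWAS:
        removing one recovers the other."""
        cons, sub_a, sub_b = _split_meta_tables()
        res = adjust_table(cons, sub_b, method="ivw")
        adj = res.adjusted.df.set_index("variant_id")
        ref = sub_a.df.set_index("variant_id")
        np.testing.assert_allclose(adj["beta"], ref.loc[adj.index, "beta"], rtol=1e-8)
        np.testing.assert_allclose(adj["se"], ref.loc[adj.index, "se"], rtol=1e-8)

    def test_zscore_roundtrip_on_table(self):
        cons = make_table(100, seed=20, n_samples=5000.0)
        ovl = make_table(100, seed=21, n_samples=800.0)
        res = adjust_table(cons, ovl, method="zscore")
        adj = res.adjusted.df
        z_back = z_meta(
            ovl.df["zscore"].to_numpy(),
            ovl.df["n"].to_numpy(),
            adj["zscore"].to_numpy(),
            adj["n"].to_numpy(),
        )
        np.testing.assert_allclose(z_back, cons.df["zscore"].to_numpy(), atol=1e-10)
        assert (adj["n"] == 4200).all()

    def test_unstable_variants_flagged_not_emitted(self):
        cons = make_table(10, seed=1)
        ovl = cons.copy()  # identical precision everywhere -> all unstable
        res = adjust_table(cons, ovl, method="ivw")
        assert res.status_counts.get("dropped_unstable") == 10
        assert len(res.adjusted) == 0

    def test_passthrough_rows_unchanged(self):
        cons = make_table(8, seed=2)
        ovl = make_table(5, seed=3, n_samples=200.0)
        res = adjust_table(cons, ovl, method="zscore")
        out = res.table
        passthrough = out[out["status"] == "passthrough"].set_index("variant_id")
        orig = cons.df.set_index("variant_id")
        for vid in passthrough.index:
            assert passthrough.at[vid, "beta"] == orig.at[vid, "beta"]
        assert len(passthrough) == 3

    def test_decorrelation_method_runs(self):
        cons = make_table(50, seed=4, n_samples=10_000.0)
        ovl = make_table(50, seed=5, n_samples=1000.0)
        params = DecorrelationParams(n_c=500, n_all=10_000, n_o=1000)
        res = adjust_table(cons, ovl, method="decorrelation", params=params)
        assert res.status_counts["adjusted"] == 50
        zeta = decorrelate(
            res.model.pairs.pairs["zscore_all"].to_numpy(),
            res.model.pairs.pairs["zscore_o"].to_numpy(),
            params.rho,
        )
        np.testing.assert_allclose(res.table["zscore"].to_numpy()[:50], zeta)

    def test_decorrelation_without_params_errors(self):
        cons, _, sub_b = _split_meta_tables(10)
        with pytest.raises(ValueError):
            OverlapAdjustment(cons, sub_b, method="decorrelation")

    def test_mean_se_inflation_above_one_for_ivw(self):
        cons, _, sub_b = _split_meta_tables(50)
        res = adjust_table(cons, sub_b, method="ivw")
        assert res.mean_se_inflation > 1.0

    def test_summary_reports_counts(self):
        cons, _, sub_b = _split_meta_tables(10)
        text = adjust_table(cons, sub_b, method="ivw").summary()
        assert "adjusted:" in text and "ivw" in text


class TestAgreementWithDirectGwas:
    def test_zscore_adjustment_matches_direct_nonoverlap_gwas(self, medium_sim, medium_gwas):
        """Removing the overlap GWAS from the train∪overlap GWAS recovers the
        association statistics of the train-only samples (loose tolerance:
        a joint regression is not exactly a fixed-effect meta of its parts)."""
        res = adjust_table(medium_gwas["consortium"], medium_gwas["overlap"], method="zscore")
        direct = medium_gwas["train_only"].df.set_index("variant_id")
        adj = res.adjusted.df.set_index("variant_id")
        common = adj.index.intersection(direct.index)
        z_adj = adj.loc[common, "zscore"].to_numpy()
        z_dir = direct.loc[common, "zscore"].to_numpy()
        r = np.corrcoef(z_adj, z_dir)[0, 1]
        slope = np.polyfit(z_dir, z_adj, 1)[0]
        assert r > 0.95
        assert 0.9 < slope < 1.1
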