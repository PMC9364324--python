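"""Nanomaterial comparison statistics: Bray-Curtis, dbRDA, Dunn, Spearman."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nanosorb import bray_curtis, dbrda_marginal, kruskal_dunn, min_shift, spearman


class TestMinShift:
    def test_shifts_global_minimum_to_zero(self):
        m = np.array([[-1.0, 2.0], [0.5, 1.0]])
        out = min_shift(m)
        assert out.min() == 0.0
        np.testing.assert_allclose(out, m + 1.0)

    def test_identity_when_min_already_zero(self):
        m = np.array([[0.0, 2.0], [1.0, 3.0]])
        np.testing.assert_allclose(min_shift(m), m)

    def test_idempotent(self, rng):
        m = rng.normal(size=(5, 7))
        once = min_shift(m)
        np.testing.assert_allclose(min_shift(once), once)


class TestBrayCurtis:
    def test_identical_rows_zero_disjoint_rows_one(self):
        X = pd.DataFrame([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        D = bray_curtis(X)
        assert D.iloc[0, 1] == pytest.approx(0.0)
        assert D.iloc[0, 2] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        D = bray_curtis(pd.DataFrame([[2.0, 1.0], [1.0, 1.0]]))
        assert D.iloc[0, 1] == pytest.approx(0.2)  # (1+0)/(3+2)

    def test_symmetric_zero_diagonal_unit_interval(self, rng):
        X = pd.DataFrame(rng.uniform(0, 5, size=(6, 4)))
        D = bray_curtis(X).to_numpy()
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(D), 0.0)
        assert ((D >= 0) & (D <= 1)).all()

    def test_row_permutation_equivariance(self, rng):
        X = rng.uniform(0, 5, size=(6, 4))
        perm = rng.permutation(6)
        D = bray_curtis(pd.DataFrame(X)).to_numpy()
        Dp = bray_curtis(pd.DataFrame(X[perm])).to_numpy()
        np.testing.assert_allclose(Dp, D[np.ix_(perm, perm)], atol=1e-12)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="min_shift"):
            bray_curtis(pd.DataFrame([[-0.1, 1.0], [1.0, 1.0]]))

    def test_all_zero_row_pair_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))


def _dbrda_fixture(seed=42, n=19):
    rng = np.random.default_rng(seed)
    logk = pd.DataFrame(rng.normal(3, 1.5, size=(n, 8)))
    pred = pd.DataFrame(
        rng.normal(size=(n, 5)), columns=["r_e", "p_s", "a", "b", "v"]
    )
    return min_shift(logk), pred


class TestDbrdaMarginal:
    def test_denominator_df_is_n_minus_p_minus_1(self):
        shifted, pred = _dbrda_fixture()
        res = dbrda_marginal(bray_curtis(shifted), pred, n_perm=49, seed=0)
        assert [r.df_den for r in res] == [13] * 5
        assert [r.df_num for r in res] == [1] * 5

    def test_best_possible_p_is_one_over_nperm_plus_one(self):
        # a predictor that *is* the gradient of the data: F huge, p at floor
        rng = np.random.default_rng(3)
        grad = np.linspace(0, 1, 15)
        logk = pd.DataFrame(np.outer(grad, np.ones(6)) + rng.normal(0, 0.01, (15, 6)))
        pred = pd.DataFrame({"g": grad})
        res = dbrda_marginal(bray_curtis(min_shift(logk)), pred, n_perm=999, seed=1)
        assert res[0].p_value == pytest.approx(1 / 1000)

    def test_matches_vegan_dbrda_f_statistics(self, tmp_path):
        """Cross-check the marginal F and dfs against the vegan reference
        implementation (R) on a fixed fixture."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        shifted, pred = _dbrda_fixture()
        res = dbrda_marginal(bray_curtis(shifted), pred, n_perm=49, seed=0)
        shifted.to_csv(tmp_path / "logk.csv", index=False)
        pred.to_csv(tmp_path / "pred.csv", index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(vegan))
            logk <- read.csv("{tmp_path}/logk.csv")
            pred <- read.csv("{tmp_path}/pred.csv")
            m <- dbrda(vegdist(logk, method="bray") ~ r_e + p_s + a + b + v, data=pred)
            a <- anova(m, by="margin", permutations=19)
            write.csv(data.frame(term=rownames(a), F=a$F, df=a$Df), "{tmp_path}/out.csv")
            """
        )
        (tmp_path / "check.R").write_text(script)
        proc = subprocess.run(
            ["Rscript", str(tmp_path / "check.R")], capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(tmp_path / "out.csv").set_index("term")
        for r in res:
            assert r.F == pytest.approx(ref.loc[r.predictor, "F"], rel=1e-4)
            assert r.df_num == ref.loc[r.predictor, "df"]

    def test_null_p_values_roughly_uniform(self):
        """Calibration: a pure-noise predictor yields ~uniform permutation
        p-values over replicates of exchangeable data."""
        rng = np.random.default_rng(2024)
        pvals = []
        for _ in range(60):
            data = rng.normal(size=(12, 5))
            D = np.sqrt(((data[:, None, :] - data[None, :, :]) ** 2).sum(-1))
            pred = pd.DataFrame({"noise": rng.normal(size=12)})
            res = dbrda_marginal(D, pred, n_perm=99, seed=int(rng.integers(2**31)))
            pvals.append(res[0].p_value)
        d, p_ks = stats.kstest(pvals, "uniform")
        assert p_ks > 0.01

    def test_collinear_predictors_rejected(self):
        shifted, pred = _dbrda_fixture()
        pred["dup"] = pred["a"]
        with pytest.raises(ValueError, match="collinear"):
            dbrda_marginal(bray_curtis(shifted), pred, n_perm=9)


class TestKruskalDunn:
    def test_identical_groups_adjusted_p_one(self):
        values = np.array([1.0, 2, 3, 1, 2, 3])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        (_, _), pairs = kruskal_dunn(values, groups)
        assert pairs["p_holm"].iloc[0] == pytest.approx(1.0)

    def test_separated_groups_monotone_z_signs(self):
        values = np.array([1.0, 2, 3, 101, 102, 103, 201, 202, 203])
        groups = np.array(["lo"] * 3 + ["mid"] * 3 + ["hi"] * 3)
        (H, p), pairs = kruskal_dunn(values, groups)
        z = pairs.set_index(["group_a", "group_b"])["z"]
        assert z[("lo", "mid")] < 0 and z[("mid", "hi")] < 0 and z[("lo", "hi")] < 0
        assert abs(z[("lo", "hi")]) > abs(z[("lo", "mid")])
        assert p < 0.05

    def test_matches_rank_sum_oracle_with_ties(self, rng):
        """Dunn z recomputed from first principles (average ranks, tie
        correction) on a random 3-group case with ties."""
        values = np.round(rng.normal(0, 2, size=24), 0)  # rounding forces ties
        groups = np.array(["a"] * 8 + ["b"] * 8 + ["c"] * 8)
        (_, _), pairs = kruskal_dunn(values, groups)

        ranks = stats.rankdata(values)
        N = len(values)
        _, t = np.unique(values, return_counts=True)
        tie = (t**3 - t).sum() / (12 * (N - 1))
        for _, row in pairs.iterrows():
            ra = ranks[groups == row["group_a"]]
            rb = ranks[groups == row["group_b"]]
            sigma = np.sqrt(
                (N * (N + 1) / 12 - tie) * (1 / len(ra) + 1 / len(rb))
            )
            assert row["z"] == pytest.approx((ra.mean() - rb.mean()) / sigma, abs=1e-10)

    def test_holm_never_decreases_raw_p(self, rng):
        values = rng.normal(size=30)
        groups = rng.choice(list("abcde"), size=30)
        if len(np.unique(groups)) < 2:
            pytest.skip("degenerate draw")
        (_, _), pairs = kruskal_dunn(values, groups)
        assert (pairs["p_holm"] >= pairs["p_raw"] - 1e-15).all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn(np.array([1.0, 2.0]), np.array(["a", "a"]))


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2, 3, 5, 8])
        assert spearman(x, x**3)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_tied_data_matches_rank_pearson_oracle(self, rng):
        x = np.round(rng.normal(size=20), 0)
        y = np.round(rng.normal(size=20), 0)
        if stats.rankdata(x).std() == 0 or stats.rankdata(y).std() == 0:
            pytest.skip("degenerate draw")
        rho, _ = spearman(x, y)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])
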