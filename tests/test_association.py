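import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_random_panel
from ssrpop import association, diversity, kinship_ld, simulate
from ssrpop.errors import DataError, ParameterError
from ssrpop.io import TRAITS, PhenotypeTable, SSRPanel


def make_pheno(rows):
    return PhenotypeTable(pd.DataFrame(rows, columns=["accession", "environment", *TRAITS]))


class TestNormalizeImpute:
    def test_zscore_and_impute(self):
        rows = [
            ("a1", "E1", 1.2, 38.0, 4.1, 84.0),
            ("a2", "E1", 1.3, np.nan, 4.3, 85.0),
            ("a3", "E1", 1.4, 40.0, 4.5, 86.0),
        ]
        norm = association.normalize_impute(make_pheno(rows))
        env = norm.env("E1")
        for t in TRAITS:
            assert env[t].mean() == pytest.approx(0.0, abs=1e-12)
            assert env[t].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        # the imputed cell sat at the mean, hence exactly 0 after z-scoring
        assert norm.env("E1").loc["a2", "FS"] == pytest.approx(0.0, abs=1e-12)

    def test_entirely_missing_trait_rejected(self):
        rows = [("a1", "E1", 1.2, np.nan, 4.1, 84.0), ("a2", "E1", 1.3, np.nan, 4.2, 85.0)]
        with pytest.raises(DataError, match="FS"):
            association.normalize_impute(make_pheno(rows))


class TestGLM:
    def test_matches_closed_form_ols(self, rng):
        """10-observation scan against the textbook OLS/F formulas."""
        n = 10
        x = rng.integers(0, 2, n).astype(float)
        y_vals = 0.8 * x + rng.normal(0, 1, n)
        panel = SSRPanel([f"a{i}" for i in range(n)], ["M_1"], x[:, None])
        y = pd.Series(y_vals, index=panel.accession_ids)
        res = association.glm_scan(panel, y)
        X = np.column_stack([np.ones(n), x])
        beta, rss1, *_ = np.linalg.lstsq(X, y_vals, rcond=None)
        rss1 = float(rss1[0])
        rss0 = float(np.sum((y_vals - y_vals.mean()) ** 2))
        F = (rss0 - rss1) / (rss1 / (n - 2))
        assert res.table.loc["M_1", "beta"] == pytest.approx(beta[1], abs=1e-10)
        assert res.table.loc["M_1", "F"] == pytest.approx(F, abs=1e-8)
        assert res.table.loc["M_1", "p"] == pytest.approx(stats.f.sf(F, 1, n - 2), abs=1e-10)

    def test_null_pvalues_uniformish(self, rng):
        panel = make_random_panel(rng, n=120, n_markers=40, missing_rate=0.0)
        y = pd.Series(rng.normal(size=120), index=panel.accession_ids)
        res = association.glm_scan(panel, y)
        p = res.table["p"].dropna()
        assert abs((p <= 0.05).mean() - 0.05) < 0.05
        assert p.mean() == pytest.approx(0.5, abs=0.1)

    def test_planted_effect_detected(self, rng):
        n = 288
        x = (rng.random(n) < 0.3).astype(float)
        y_vals = 1.0 * x + rng.normal(0, 1, n)
        panel = SSRPanel([f"a{i}" for i in range(n)], ["Q_1"], x[:, None])
        res = association.glm_scan(panel, pd.Series(y_vals, index=panel.accession_ids))
        assert res.table.loc["Q_1", "p"] < 1e-6

    def test_collinear_marker_skipped(self, rng):
        n = 12
        calls = np.column_stack([np.ones(n), rng.integers(0, 2, n)]).astype(float)
        panel = SSRPanel([f"a{i}" for i in range(n)], ["C_1", "M_1"], calls)
        res = association.glm_scan(panel, pd.Series(rng.normal(size=n), index=panel.accession_ids))
        assert "C_1" in res.skipped
        assert np.isnan(res.table.loc["C_1", "p"])


def dense_reml_oracle(y, W, K, deltas):
    """Brute-force REML profile over delta with explicit dense algebra."""
    n, p = W.shape
    best = (None, np.inf)
    for d in deltas:
        V = K + d * np.eye(n)
        Vi = np.linalg.inv(V)
        WtViW = W.T @ Vi @ W
        beta = np.linalg.solve(WtViW, W.T @ Vi @ y)
        r = y - W @ beta
        rss = float(r @ Vi @ r)
        sigma_g2 = rss / (n - p)
        _, ld_v = np.linalg.slogdet(V)
        _, ld_w = np.linalg.slogdet(WtViW)
        nll = 0.5 * ((n - p) * math.log(2 * math.pi * sigma_g2) + ld_v + ld_w + (n - p))
        if nll < best[1]:
            best = (d, nll)
    return best[0]


class TestMLM:
    def test_reduces_to_glm_with_identity_kinship(self, rng):
        panel = make_random_panel(rng, n=60, n_markers=15, missing_rate=0.0)
        y = pd.Series(rng.normal(size=60), index=panel.accession_ids)
        glm = association.glm_scan(panel, y)
        mlm = association.mlm_scan(panel, y, K=np.eye(60), variance_mode="per_marker")
        both = glm.table["p"].notna() & mlm.table["p"].notna()
        np.testing.assert_allclose(
            mlm.table.loc[both, "p"], glm.table.loc[both, "p"], atol=1e-6
        )

    def test_delta_and_f_match_dense_grid_oracle(self, structured_sim):
        filt = diversity.maf_filter(structured_sim["panel"], 0.05)
        filt = filt.select_loci(filt.locus_ids[:1])
        norm = association.normalize_impute(structured_sim["pheno"])
        y = norm.env("UZB")["FS"]
        Kt = structured_sim["truth"].kinship + 1e-8 * np.eye(filt.n_accessions)
        scan = association.MixedLMScan(filt, y, K=Kt)
        res = scan.fit(variance_mode="per_marker")
        delta_hat = res.table["delta"].iloc[0]
        # dense-matrix brute force on a fine log grid around the optimum
        yv = y.loc[filt.accession_ids].to_numpy()
        X = np.nan_to_num(filt.calls, nan=np.nanmean(filt.calls))
        W = np.column_stack([np.ones(filt.n_accessions), X[:, 0]])
        grid = np.exp(np.linspace(math.log(delta_hat) - 1, math.log(delta_hat) + 1, 4001))
        d_star = dense_reml_oracle(yv, W, Kt, grid)
        assert math.log(delta_hat) == pytest.approx(math.log(d_star), abs=1e-3)

    def test_f_invariant_to_affine_trait_rescale(self, structured_sim):
        filt = diversity.maf_filter(structured_sim["panel"], 0.05)
        norm = association.normalize_impute(structured_sim["pheno"])
        y = norm.env("UZB")["FS"]
        Kt = structured_sim["truth"].kinship
        f1 = association.mlm_scan(filt, y, K=Kt, variance_mode="P3D").table["F"]
        f2 = association.mlm_scan(filt, 3.0 * y + 7.0, K=Kt, variance_mode="P3D").table["F"]
        both = f1.notna() & f2.notna()
        np.testing.assert_allclose(f1[both], f2[both], rtol=1e-4, atol=1e-6)

    def test_permutation_p_tracks_parametric(self, rng):
        panel = make_random_panel(rng, n=50, n_markers=4, missing_rate=0.0)
        y = pd.Series(rng.normal(size=50), index=panel.accession_ids)
        res = association.mlm_scan(panel, y, K=np.eye(50), variance_mode="P3D",
                                   n_perm=200, seed=9)
        both = res.table[["p", "p_perm"]].dropna()
        assert (np.abs(both["p"] - both["p_perm"]) < 0.15).all()


class TestAdjustments:
    def test_sidak(self):
        p = np.array([0.01, 0.2, 1.0])
        out = association.adjust_pvalues(p, "sidak")
        np.testing.assert_allclose(out, 1 - (1 - p) ** 3)
        assert association.adjust_pvalues(np.array([0.3]), "sidak")[0] == pytest.approx(0.3)
        assert (out >= p).all()

    def test_storey_pi0_on_uniform_null(self, rng):
        p = rng.uniform(size=1000)
        q = association.adjust_pvalues(p, "storey_q")
        assert ((q >= 0) & (q <= 1)).all()
        # under the full null q should roughly equal the BH-with-pi0 values
        lam = 0.95
        pi0 = np.mean(p > lam) / (1 - lam)
        assert 0.8 <= min(pi0, 1.0) <= 1.0

    def test_empty_vector_rejected(self):
        with pytest.raises(ParameterError):
            association.adjust_pvalues(np.array([]), "sidak")


class TestMinBayesFactor:
    def test_exact_values(self):
        assert association.min_bayes_factor(1 / math.e) == pytest.approx(1.0, abs=1e-12)
        assert association.min_bayes_factor(0.05) == pytest.approx(-math.e * 0.05 * math.log(0.05), abs=1e-12)
        assert association.min_bayes_factor(0.05) == pytest.approx(0.4072, abs=1e-4)

    def test_monotone_on_domain(self):
        ps = np.linspace(1e-6, 1 / math.e - 1e-6, 200)
        bf = association.min_bayes_factor(ps)
        assert (np.diff(bf) > 0).all()
        assert ((bf > 0) & (bf <= 1)).all()

    def test_clamped_above_1_over_e(self):
        assert association.min_bayes_factor(0.5) == 1.0

    def test_domain_error(self):
        with pytest.raises(ParameterError):
            association.min_bayes_factor(0.0)


class TestConsensus:
    def make_result(self, loci, ps, env):
        table = pd.DataFrame(
            {"beta": 0.1, "F": 5.0, "p": ps, "p_sidak": ps, "q": ps,
             "bfmin": association.min_bayes_factor(np.asarray(ps))},
            index=pd.Index(loci, name="locus"),
        )
        return association.AssociationResult(table=table, model="MLM", trait="FS",
                                             environment=env, n_obs=100)

    def test_idempotent_and_commutative(self):
        res = self.make_result(["A_1", "B_1", "C_1"], [0.01, 0.2, 0.04], "E1")
        res2 = self.make_result(["A_1", "B_1", "C_1"], [0.01, 0.2, 0.04], "E2")
        cons = association.cross_environment_consensus(res, res2, alpha=0.05)
        assert set(cons.index) == {"A_1", "C_1"}
        swapped = association.cross_environment_consensus(res2, res, alpha=0.05)
        assert set(swapped.index) == set(cons.index)

    def test_zero_alpha_empty(self):
        res = self.make_result(["A_1"], [0.001], "E1")
        out = association.cross_environment_consensus(res, res, alpha=0.0)
        assert out.empty

    def test_bf_filter(self):
        res = self.make_result(["A_1", "B_1"], [0.001, 0.04], "E1")
        out = association.cross_environment_consensus(res, res, alpha=0.05, bf_max=0.13)
        assert list(out.index) == ["A_1"]  # BFmin(0.04) ~ 0.35 > 0.13

    def test_disjoint_loci_error(self):
        a = self.make_result(["A_1"], [0.01], "E1")
        b = self.make_result(["B_1"], [0.01], "E2")
        with pytest.raises(DataError):
            association.cross_environment_consensus(a, b)

    def test_shared_qtl_enters_consensus(self, structured_sim):
        filt = diversity.maf_filter(structured_sim["panel"], 0.05)
        norm = association.normalize_impute(structured_sim["pheno"])
        Kt = structured_sim["truth"].kinship
        res = {}
        for env in ("UZB", "USA"):
            res[env] = association.mlm_scan(filt, norm.env(env)["FS"], K=Kt,
                                            variance_mode="P3D", trait="FS", environment=env)
        cons = association.cross_environment_consensus(res["UZB"], res["USA"], alpha=0.05)
        assert "M005_150" in cons.index


class TestCatalogJoin:
    def test_empty_catalog_all_novel(self):
        cons = pd.DataFrame({"trait": ["FS"]}, index=pd.Index(["A_1"], name="locus"))
        out = association.known_qtl_join(cons, None)
        assert out.attrs["n_matched"] == 0 and out.attrs["n_novel"] == 1

    def test_exact_join_counts(self):
        cons = pd.DataFrame({"trait": ["FS", "FL"]}, index=pd.Index(["A_1", "B_1"], name="locus"))
        catalog = pd.DataFrame({"locus": ["A_1", "X_9"], "trait": ["FS", "FM"],
                                "reference": ["ref1", "ref2"]})
        out = association.known_qtl_join(cons, catalog)
        assert out.loc["A_1", "match"] and out.loc["A_1", "reference"] == "ref1"
        assert not out.loc["B_1", "match"]
        assert out.attrs["n_matched"] == 1 and out.attrs["n_novel"] == 1
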