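"""RSF estimation: designs, screening, the Laplace GLMM, AICc machinery."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest

from fisherhab import rsf


def _sim_mixed(seed, n_groups=6, n_per=400, beta=(-1.5, 0.8, -0.5), sigma=0.5):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), n_per)
    u = rng.normal(0, sigma, n_groups)
    X = rng.standard_normal((n_groups * n_per, 2))
    eta = beta[0] + X @ np.asarray(beta[1:]) + u[g]
    y = (rng.random(len(g)) < 1 / (1 + np.exp(-eta))).astype(float)
    return pd.DataFrame({"individual_id": g, "response": y,
                         "a": X[:, 0], "b": X[:, 1]})


class TestBuildDesign:
    def _frames(self):
        used = pd.DataFrame({"individual_id": ["F1"] * 100, "cov": 1.0})
        avail = pd.DataFrame({"individual_id": ["F1"] * 2000, "cov": 0.0})
        return used, avail

    def test_row_counts_and_ratio(self):
        used, avail = self._frames()
        d = rsf.build_design(used, avail, "moving")
        assert len(d) == 2100
        assert d["response"].sum() == 100

    def test_behaviors_share_availability(self):
        used, avail = self._frames()
        m = rsf.build_design(used, avail, "moving")
        r = rsf.build_design(used, avail, "resting")
        pd.testing.assert_frame_equal(
            m[m.response == 0].drop(columns="behavior").reset_index(drop=True),
            r[r.response == 0].drop(columns="behavior").reset_index(drop=True))

    def test_empty_used_and_missing_pool_errors(self):
        used, avail = self._frames()
        with pytest.raises(ValueError, match="no used rows"):
            rsf.build_design(used.iloc[:0], avail, "moving")
        with pytest.raises(ValueError, match="availability"):
            rsf.build_design(used.assign(individual_id="F9"), avail, "moving")


class TestStandardize:
    def test_zero_mean_unit_sd_and_roundtrip(self, rng):
        df = pd.DataFrame({"individual_id": "F1", "response": 0,
                           "u": rng.uniform(5, 9, 200),
                           "v": rng.normal(-3, 7, 200)})
        std, rec = rsf.standardize(df)
        assert std["u"].mean() == pytest.approx(0, abs=1e-12)
        assert std["v"].std(ddof=0) == pytest.approx(1, abs=1e-12)
        back = rsf.inverse_standardize(std, rec)
        assert np.allclose(back["u"], df["u"], atol=1e-12)

    def test_constant_column_error_names_column(self):
        df = pd.DataFrame({"individual_id": "F1", "response": 0,
                           "flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            rsf.standardize(df, columns=["flat"])


class TestCorrelationScreen:
    def test_duplicate_column_flagged(self, rng):
        x = rng.normal(size=300)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=300)})
        flagged = rsf.screen_correlation(df, ["a", "b", "c"])
        assert flagged.loc["a", "b"]
        assert not flagged.loc["a", "c"]
        with pytest.raises(ValueError, match="co-occur"):
            rsf.check_admissible(["a", "b"], flagged)
        rsf.check_admissible(["a", "c"], flagged)

    def test_exactly_at_threshold_is_admissible(self):
        # constructed pair with Pearson r exactly 0.6
        x = np.array([1.0, 1.0, -1.0, -1.0] * 25)
        z = np.array([1.0, -1.0, 1.0, -1.0] * 25)
        y = 0.6 * x + 0.8 * z
        df = pd.DataFrame({"x": x, "y": y})
        assert df.corr().loc["x", "y"] == pytest.approx(0.6, abs=1e-12)
        assert not rsf.screen_correlation(df, ["x", "y"]).loc["x", "y"]

    def test_independent_columns_rarely_flagged(self):
        """n = 10,000 independent normals: flagged in <1% of replicates."""
        hits = 0
        for s in range(50):
            r = np.random.default_rng(s)
            df = pd.DataFrame(r.standard_normal((10_000, 2)), columns=["p", "q"])
            hits += bool(rsf.screen_correlation(df, ["p", "q"]).loc["p", "q"])
        assert hits == 0


class TestMixedLogistic:
    def test_single_group_matches_plain_logistic(self):
        import statsmodels.api as sm
        d = _sim_mixed(1, n_groups=1, n_per=2000, sigma=0.0)
        fit = rsf.fit_mixed_logistic("response ~ a + b", d)
        ref = sm.Logit(d["response"],
                       sm.add_constant(d[["a", "b"]])).fit(disp=0)
        assert np.allclose(fit.beta.to_numpy(), ref.params.to_numpy(), atol=1e-4)
        assert fit.ll == pytest.approx(ref.llf, abs=1e-3)
        assert fit.sigma < 0.01

    def test_matches_lme4_glmer_laplace(self, tmp_path):
        """Independent oracle: the same Laplace objective fitted by lme4."""
        d = _sim_mixed(7)
        fit = rsf.fit_mixed_logistic("response ~ a + b", d)
        csv = tmp_path / "d.csv"
        d.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(response ~ a + b + (1|individual_id), data=d,
                       family=binomial, nAGQ=1)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep=",")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.strip().split(",")]
        assert np.allclose(fit.beta.to_numpy(), vals[:3], atol=2e-3)
        assert fit.sigma == pytest.approx(vals[3], abs=2e-3)
        assert fit.ll == pytest.approx(vals[4], abs=0.01)

    def test_null_covariate_ci_coverage(self):
        """CI for an unrelated covariate covers 0 at roughly the 95% rate."""
        cover = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            n = 2000
            d = pd.DataFrame({
                "individual_id": np.repeat([0, 1], n // 2),
                "response": (rng.random(n) < 0.1).astype(float),
                "a": rng.standard_normal(n)})
            fit = rsf.fit_mixed_logistic("response ~ a", d)
            row = fit.estimates.set_index("term").loc["a"]
            cover += row["lo95"] <= 0 <= row["hi95"]
        assert 0.91 <= cover / 200 <= 0.985

    def test_complete_separation_error(self):
        d = pd.DataFrame({"individual_id": 0,
                          "response": [1.0] * 50 + [0.0] * 50,
                          "a": [1.0] * 50 + [-1.0] * 50})
        with pytest.raises(rsf.ConvergenceError):
            rsf.fit_mixed_logistic("response ~ a", d)

    def test_recovers_random_intercept_sd(self):
        d = _sim_mixed(3, n_groups=12, n_per=1500, sigma=0.5)
        fit = rsf.fit_mixed_logistic("response ~ a + b", d)
        assert 0.25 < fit.sigma < 0.9
        assert fit.k == 4  # intercept + 2 slopes + variance


class TestAICc:
    def test_large_n_limit_is_plain_aic(self):
        ll, k = -1234.5, 5
        assert rsf.aicc(ll, k, 10 ** 9) == pytest.approx(-2 * ll + 2 * k,
                                                         abs=1e-3)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            rsf.aicc(-10.0, 5, 6)

    def test_compare_models_table(self):
        fits = {}
        for name, ll, k in [("a", -100.0, 3), ("b", -101.0, 3), ("c", -99.0, 8)]:
            fits[name] = rsf.ModelFit(formula=f"response ~ {name}", n=500, k=k,
                                      ll=ll, aicc=rsf.aicc(ll, k, 500),
                                      estimates=pd.DataFrame(
                                          columns=["term", "beta", "se",
                                                   "lo95", "hi95"]),
                                      sigma=0.0, sigma_ci=(0, 0), converged=True)
        tab = rsf.compare_models(fits)
        assert tab["dAICc"].iloc[0] == 0.0
        assert tab["hypothesis"].iloc[0] == "a"
        assert tab["w"].sum() == pytest.approx(1.0)

    def test_compare_models_requires_identical_data(self):
        f1 = rsf.ModelFit("response ~ 1", 500, 2, -10, rsf.aicc(-10, 2, 500),
                          pd.DataFrame(), 0.0, (0, 0), True)
        f2 = rsf.ModelFit("response ~ 1", 600, 2, -10, rsf.aicc(-10, 2, 600),
                          pd.DataFrame(), 0.0, (0, 0), True)
        with pytest.raises(ValueError, match="identical data"):
            rsf.compare_models([f1, f2])


class TestScaleSelection:
    def test_generative_scale_wins(self):
        """Response driven by the 400-m covariate: that scale should win."""
        wins = 0
        for s in range(50):
            rng = np.random.default_rng(1000 + s)
            n = 1500
            base = rng.standard_normal(n)
            c400 = base
            c100 = 0.75 * base + np.sqrt(1 - 0.75 ** 2) * rng.standard_normal(n)
            eta = -2.0 + 1.2 * c400
            d = pd.DataFrame({
                "individual_id": np.repeat(np.arange(3), n // 3),
                "response": (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float),
                "canopy_100": c100, "canopy_400": c400})
            best, _ = rsf.select_scale_univariate("canopy", (100, 400), d)
            wins += best == 400
        assert wins >= 40

    def test_tie_prefers_smallest_scale(self):
        d = _sim_mixed(2, n_groups=2, n_per=200)
        d["canopy_100"] = d["a"]
        d["canopy_400"] = d["a"]
        best, _ = rsf.select_scale_univariate("canopy", (400, 100), d)
        assert best == 100

    def test_single_scale_passthrough(self):
        best, aiccs = rsf.select_scale_univariate("canopy", (400,), None)
        assert best == 400 and aiccs == {}


class TestInteractionsAndPrediction:
    @staticmethod
    def _combined(seed=5):
        rng = np.random.default_rng(seed)
        rows = []
        for iid in range(4):
            for behavior, n_used in (("moving", 150), ("resting", 60)):
                for response, n in ((1, n_used), (0, 20 * n_used // 10)):
                    cats = rng.choice(["dense", "moderate", "open", "sparse"],
                                      size=n, p=[0.7, 0.2, 0.07, 0.03]
                                      if response else [0.5, 0.3, 0.13, 0.07])
                    rows.append(pd.DataFrame({
                        "individual_id": iid, "behavior": behavior,
                        "response": float(response), "patch_category": cats,
                        "edge_density_400": rng.normal(size=n),
                        "patch_size_ha": rng.normal(size=n),
                        "dist_to_edge": rng.normal(size=n)}))
        return pd.concat(rows, ignore_index=True)

    def test_reference_levels_and_terms(self):
        fits = rsf.fit_behavior_interactions(self._combined())
        est = fits["canopy_category"].estimates
        terms = set(est["term"])
        # sparse/open/moderate reported relative to dense; moving is reference
        for cat in ("sparse", "open", "moderate"):
            assert any(f"[T.{cat}]" in t for t in terms)
        assert not any("[T.dense]" in t for t in terms)
        assert any("[T.resting]" in t for t in terms)
        assert set(fits) == {"canopy_category", "edge_density", "patch_size",
                             "distance_to_edge"}

    def test_sparse_resting_cell_warns(self):
        d = self._combined()
        drop = (d["behavior"] == "resting") & (d["response"] == 1) & \
               (d["patch_category"] == "sparse")
        with pytest.warns(UserWarning, match="wide"):
            rsf.fit_behavior_interactions(
                d[~drop], formulas={"canopy_category":
                                    rsf.BEHAVIOR_INTERACTION_FORMULAS[
                                        "canopy_category"]})

    def test_predict_relative_selection(self):
        d = _sim_mixed(11, n_groups=4, n_per=800, beta=(-2.0, 1.0, 0.0))
        fit = rsf.fit_mixed_logistic("response ~ a + b", d)
        grid = pd.DataFrame({"a": np.linspace(-2, 2, 21), "b": 0.0})
        pred = rsf.predict_relative_selection(fit, grid)
        assert pred.max() == pytest.approx(1.0)
        assert np.all(np.diff(pred) > 0)  # monotone in the positive covariate

    def test_predict_doubled_availability_invariance(self):
        d = _sim_mixed(13, n_groups=3, n_per=600, beta=(-1.5, 0.9, -0.4))
        doubled = pd.concat([d, d[d["response"] == 0]], ignore_index=True)
        grid = pd.DataFrame({"a": np.linspace(-2, 2, 9), "b": 0.0})
        p1 = rsf.predict_relative_selection(
            rsf.fit_mixed_logistic("response ~ a + b", d), grid)
        p2 = rsf.predict_relative_selection(
            rsf.fit_mixed_logistic("response ~ a + b", doubled), grid)
        assert np.max(np.abs(p1 - p2)) < 0.02

    def test_unknown_grid_covariate_error(self):
        d = _sim_mixed(11, n_groups=2, n_per=300)
        fit = rsf.fit_mixed_logistic("response ~ a", d)
        with pytest.raises(KeyError):
            rsf.predict_relative_selection(fit, pd.DataFrame({"zzz": [0.0]}))
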