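"""Use-availability resource selection functions with AICc model competition.

The estimation target is the exponential RSF w(x) = exp(beta'x): used
locations are contrasted with availability samples in a binomial GLMM with a
per-individual random intercept, the standard third-order (within home range)
design.  The module covers the full model-building protocol:

* stacking used/available rows into behavior-specific designs (1:20 ratio,
  availability shared between behavior datasets);
* z-scoring covariates with an invertible scaling record;
* a pairwise |r| > 0.6 collinearity screen;
* univariate selection of the most predictive spatial scale per covariate;
* maximum-likelihood fitting of the random-intercept logistic model by a
  Laplace approximation (the same objective glmmTMB and lme4 optimize);
* AICc, delta-AICc and Akaike weights over a candidate set;
* behavior-interaction models (selection x movement state, including
  three-way interactions with categorical canopy, dense as reference);
* relative-selection prediction surfaces.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy.optimize import minimize
from scipy.special import expit

logger = logging.getLogger(__name__)

CORRELATION_THRESHOLD = 0.6
AVAILABILITY_RATIO = 20


class ConvergenceError(RuntimeError):
    """Raised when the mixed-model optimizer fails or the fit is degenerate."""


@dataclass
class ModelFit:
    """A fitted random-intercept logistic RSF.

    ``k`` counts fixed effects (including the intercept) plus the random-
    intercept variance parameter.  ``estimates`` holds Wald summaries for the
    fixed effects; ``sigma`` is the random-intercept SD.
    """

    formula: str
    n: int
    k: int
    ll: float
    aicc: float
    estimates: pd.DataFrame        # term, beta, se, lo95, hi95
    sigma: float
    sigma_ci: tuple[float, float]
    converged: bool
    group_col: str = "individual_id"
    design_info: object = field(default=None, repr=False)
    scaling: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def beta(self) -> pd.Series:
        return self.estimates.set_index("term")["beta"]


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(used: pd.DataFrame, available: pd.DataFrame,
                 behavior: str) -> pd.DataFrame:
    """Stack used (response 1) and available (response 0) covariate rows.

    Both frames need ``individual_id`` plus covariate columns.  Every
    individual with used rows must also have available rows.  The same
    ``available`` frame can (and should) be reused across behavior designs.
    """
    if used.empty:
        raise ValueError("no used rows supplied")
    missing = set(used["individual_id"]) - set(available["individual_id"])
    if missing:
        raise ValueError(f"individuals {sorted(missing)} have used rows but no "
                         "availability sample")
    u = used.copy()
    a = available[available["individual_id"].isin(set(used["individual_id"]))].copy()
    u["response"], a["response"] = 1, 0
    out = pd.concat([u, a], ignore_index=True)
    out["behavior"] = behavior
    return out


def build_combined_design(used_moving: pd.DataFrame, used_resting: pd.DataFrame,
                          pool: pd.DataFrame, ratio: int = AVAILABILITY_RATIO,
                          seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Behavior-interaction design: both behaviors against one shared pool.

    For each individual and state, ``ratio`` x (used fixes in that state)
    available rows are drawn without replacement from the individual's shared
    availability pool and tagged with that state, so each state keeps the 1:20
    used:available balance and the state main effect is not confounded with
    sample size.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts = []
    for behavior, used in (("moving", used_moving), ("resting", used_resting)):
        u = used.copy()
        u["response"] = 1
        u["behavior"] = behavior
        parts.append(u)
        for iid, g in used.groupby("individual_id", sort=False):
            p = pool[pool["individual_id"] == iid]
            need = ratio * len(g)
            if len(p) == 0:
                raise ValueError(f"no availability pool for individual {iid}")
            replace = need > len(p)
            if replace:
                warnings.warn(f"availability pool for {iid} smaller than "
                              f"{need}; sampling with replacement")
            a = p.sample(n=need, replace=replace, random_state=rng)
            a = a.copy()
            a["response"] = 0
            a["behavior"] = behavior
            parts.append(a)
    return pd.concat(parts, ignore_index=True)


def standardize(table: pd.DataFrame, columns: list[str] | None = None,
                record: pd.DataFrame | None = None):
    """Z-score covariate columns; returns (table, scaling record).

    The record (column, mean, sd) supports the inverse transform and scoring
    of new data on the fitted scale.  Zero-variance columns are an error.
    """
    out = table.copy()
    if record is None:
        if columns is None:
            columns = [c for c in table.columns
                       if pd.api.types.is_numeric_dtype(table[c])
                       and c not in ("response", "x", "y")]
        stats = []
        for c in columns:
            m, s = float(table[c].mean()), float(table[c].std(ddof=0))
            if not np.isfinite(s) or s == 0:
                raise ValueError(f"column '{c}' has zero variance; cannot standardize")
            stats.append((c, m, s))
        record = pd.DataFrame(stats, columns=["column", "mean", "sd"])
    for _, row in record.iterrows():
        out[row["column"]] = (out[row["column"]] - row["mean"]) / row["sd"]
    return out, record


def inverse_standardize(table: pd.DataFrame, record: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for _, row in record.iterrows():
        out[row["column"]] = out[row["column"]] * row["sd"] + row["mean"]
    return out


def screen_correlation(table: pd.DataFrame, columns: list[str] | None = None,
                       threshold: float = CORRELATION_THRESHOLD) -> pd.DataFrame:
    """Pairwise admissibility: True marks pairs with |Pearson r| > threshold.

    Flagged pairs must not occur in the same model (strict inequality: a pair
    at exactly the threshold stays admissible).
    """
    if columns is None:
        columns = [c for c in table.columns
                   if pd.api.types.is_numeric_dtype(table[c])
                   and c not in ("response", "x", "y")]
    if len(columns) < 2:
        raise ValueError("need >= 2 numeric columns to screen")
    r = table[columns].corr()
    flagged = r.abs() > threshold
    np.fill_diagonal(flagged.values, False)
    return flagged


def check_admissible(formula_terms: list[str], flagged: pd.DataFrame) -> None:
    """Refuse covariate pairs the correlation screen flagged."""
    present = [t for t in formula_terms if t in flagged.columns]
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            if bool(flagged.loc[a, b]):
                raise ValueError(f"covariates '{a}' and '{b}' exceed the "
                                 "correlation screen and cannot co-occur")


# ---------------------------------------------------------------------------
# Laplace random-intercept logistic likelihood
# ---------------------------------------------------------------------------

def _bernoulli_ll(eta, y):
    return y * eta - np.logaddexp(0.0, eta)


def _laplace_ll(params, X, y, gidx, n_groups):
    """Marginal log-likelihood, Laplace-approximated over the random intercepts."""
    beta, log_sigma = params[:-1], params[-1]
    eta = X @ beta
    sigma2 = np.exp(2.0 * log_sigma)
    if sigma2 < 1e-12:
        return float(np.sum(_bernoulli_ll(eta, y)))
    u = np.zeros(n_groups)
    for _ in range(100):
        mu = expit(eta + u[gidx])
        grad = np.bincount(gidx, weights=y - mu, minlength=n_groups) - u / sigma2
        hess = np.bincount(gidx, weights=mu * (1 - mu), minlength=n_groups) + 1.0 / sigma2
        step = grad / hess
        u += np.clip(step, -5.0, 5.0)
        if np.max(np.abs(grad)) < 1e-10:
            break
    eta_u = eta + u[gidx]
    mu = expit(eta_u)
    w = np.bincount(gidx, weights=mu * (1 - mu), minlength=n_groups)
    ll = (np.sum(_bernoulli_ll(eta_u, y))
          - np.sum(u ** 2) / (2.0 * sigma2)
          - 0.5 * np.sum(np.log1p(sigma2 * w)))
    return float(ll)


def aicc(ll: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion.

    AICc = -2 LL + 2K + 2K(K+1)/(n - K - 1); requires n > K + 1.  As n grows
    the correction vanishes and AICc tends to plain AIC.
    """
    if n <= k + 1:
        raise ValueError("AICc undefined: n must exceed K + 1")
    return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_mixed_logistic(formula: str, data: pd.DataFrame,
                       group_col: str = "individual_id",
                       scaling: pd.DataFrame | None = None) -> ModelFit:
    """ML fit of a binomial GLMM with a per-individual random intercept.

    ``formula`` is a patsy right-hand-side style model description
    ("response ~ canopy_400 + tpi_100").  The marginal likelihood is
    integrated by a Laplace approximation (inner Newton solve for the
    random-effect modes, outer L-BFGS-B over fixed effects and log sigma);
    Wald 95% CIs come from the numerical Hessian at the optimum.

    Raises :class:`ConvergenceError` on optimizer failure or (quasi-)complete
    separation.
    """
    y_mat, X_mat = patsy.dmatrices(formula, data, return_type="dataframe")
    y = y_mat.values.ravel()
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    X = X_mat.values
    terms = list(X_mat.columns)
    groups, gidx = np.unique(data[group_col].to_numpy(), return_inverse=True)
    n, p = X.shape
    k = p + 1  # fixed effects (incl. intercept) + random-intercept variance

    # starting values from the fixed-effects logistic fit
    import statsmodels.api as sm
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            start = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        beta0 = start.params
    except Exception:
        beta0 = np.zeros(p)
        beta0[terms.index("Intercept")] = np.log(max(y.mean(), 1e-6) /
                                                 max(1 - y.mean(), 1e-6))
    if np.max(np.abs(beta0)) > 30:
        raise ConvergenceError("complete separation suspected: fixed-effects "
                               f"logistic coefficients exploded (max |b| = "
                               f"{np.max(np.abs(beta0)):.1f})")
    x0 = np.concatenate([beta0, [np.log(0.3)]])

    def negll(params):
        return -_laplace_ll(params, X, y, gidx, len(groups))

    bounds = [(None, None)] * p + [(-8.0, 5.0)]
    res = minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-6,
                            "eps": 1e-6})
    grad_ok = np.max(np.abs(res.jac)) < 1e-2 * (1.0 + abs(res.fun))
    if not (res.success or res.status == 1 or grad_ok):
        raise ConvergenceError(f"mixed-logistic optimizer failed: {res.message}; "
                               f"|grad| ~ {np.max(np.abs(res.jac)):.2e}")
    # complete separation: the fitted linear score perfectly splits the classes
    eta_hat = X @ res.x[:-1]
    if np.max(np.abs(res.x[:-1])) > 50 or (
            eta_hat[y == 1].size and eta_hat[y == 0].size
            and np.max(np.abs(res.x[:-1])) > 10
            and eta_hat[y == 1].min() > eta_hat[y == 0].max()):
        raise ConvergenceError("complete separation: fitted coefficients diverged")

    # Wald SEs conditional on the fitted variance parameter (inverting the
    # beta block only): the joint Hessian degenerates in the log-sigma
    # direction when sigma sits at the boundary
    from statsmodels.tools.numdiff import approx_hess2
    H = approx_hess2(res.x, negll)
    se_all = np.full(p + 1, np.nan)
    try:
        cov_beta = np.linalg.inv(H[:p, :p])
        se_all[:p] = np.sqrt(np.clip(np.diag(cov_beta), 0, None))
    except np.linalg.LinAlgError:
        pass
    if H[p, p] > 0:
        se_all[p] = 1.0 / np.sqrt(H[p, p])
    zcrit = 1.959963984540054
    beta = res.x[:-1]
    se = se_all[:-1]
    est = pd.DataFrame({"term": terms, "beta": beta, "se": se,
                        "lo95": beta - zcrit * se, "hi95": beta + zcrit * se})
    sigma = float(np.exp(res.x[-1]))
    se_ls = se_all[-1]
    if np.isfinite(se_ls) and zcrit * se_ls < 50:
        spread = zcrit * se_ls
        sigma_ci = (sigma * np.exp(-spread), sigma * np.exp(spread))
    else:  # sigma at the zero boundary: the variance is unidentified
        sigma_ci = (0.0, np.inf)
    ll = -res.fun
    fit = ModelFit(formula=formula, n=n, k=k, ll=ll, aicc=aicc(ll, k, n),
                   estimates=est, sigma=sigma, sigma_ci=sigma_ci,
                   converged=bool(res.success), group_col=group_col,
                   design_info=X_mat.design_info, scaling=scaling)
    logger.debug("fit %s: LL=%.2f K=%d AICc=%.2f sigma=%.3f",
                 formula, ll, k, fit.aicc, sigma)
    return fit


# ---------------------------------------------------------------------------
# model protocol
# ---------------------------------------------------------------------------

def select_scale_univariate(covariate: str, scales, table: pd.DataFrame):
    """Most predictive spatial scale by univariate mixed-model AICc.

    Fits one single-covariate model per scale (columns named
    ``{covariate}_{scale}``); the lowest AICc wins, ties going to the
    smallest scale.  Returns (chosen scale, per-scale AICc dict).
    """
    scales = list(scales)
    if len(scales) == 1:
        return scales[0], {}
    results = {}
    for s in sorted(scales):
        col = f"{covariate}_{int(s)}"
        if col not in table.columns:
            raise KeyError(f"column '{col}' not in table")
        try:
            fit = fit_mixed_logistic(f"response ~ {col}", table)
            results[s] = fit.aicc
        except ConvergenceError as err:
            logger.warning("scale %s for %s failed to fit: %s", s, covariate, err)
    if not results:
        raise ConvergenceError(f"no scale of '{covariate}' could be fitted")
    best = min(sorted(results), key=lambda s: results[s])  # sorted => ties -> smallest
    return best, results


def compare_models(fits: dict[str, ModelFit] | list[ModelFit]) -> pd.DataFrame:
    """Model-selection table: AICc, delta-AICc and Akaike weights.

    All fits must be on the same data (identical n).  Weights are
    w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2).
    """
    if not isinstance(fits, dict):
        named = {}
        for i, f in enumerate(fits):
            key = f.formula if f.formula not in named else f"{f.formula}#{i}"
            named[key] = f
        fits = named
    ns = {f.n for f in fits.values()}
    if len(ns) > 1:
        raise ValueError(f"fits are not on identical data: row counts {sorted(ns)}")
    df = pd.DataFrame({
        "hypothesis": list(fits.keys()),
        "covariates": [f.formula.split("~", 1)[1].strip() for f in fits.values()],
        "K": [f.k for f in fits.values()],
        "AICc": [f.aicc for f in fits.values()],
        "LL": [f.ll for f in fits.values()],
    }).sort_values("AICc", kind="stable", ignore_index=True)
    df["dAICc"] = df["AICc"] - df["AICc"].iloc[0]
    rel = np.exp(-0.5 * df["dAICc"].to_numpy())
    df["w"] = rel / rel.sum()
    return df[["hypothesis", "covariates", "K", "AICc", "dAICc", "w", "LL"]]


def behavior_interaction_formulas(edge_scale: int = 400) -> dict[str, str]:
    """The four management-covariate x movement-state model formulas.

    ``edge_scale`` names the edge-density scale column (the hourly-movement
    400-m scale by default).
    """
    return {
        "canopy_category":
            "response ~ C(patch_category, Treatment('dense')) * C(behavior, Treatment('moving'))",
        "edge_density":
            f"response ~ edge_density_{edge_scale} * C(behavior, Treatment('moving'))",
        "patch_size":
            "response ~ patch_size_ha * C(patch_category, Treatment('dense'))"
            " * C(behavior, Treatment('moving'))",
        "distance_to_edge":
            "response ~ dist_to_edge * C(patch_category, Treatment('dense'))"
            " * C(behavior, Treatment('moving'))",
    }


BEHAVIOR_INTERACTION_FORMULAS = behavior_interaction_formulas()


def fit_behavior_interactions(combined: pd.DataFrame,
                              formulas: dict[str, str] | None = None
                              ) -> dict[str, ModelFit]:
    """The four management-covariate x movement-state interaction models.

    Dense canopy is the reference category throughout, so category terms are
    the selection of sparse/open/moderate patches relative to dense, and the
    state main effect is the resting-vs-moving contrast within dense canopy.
    Sparse category-state cells are allowed to be nearly empty (the fit
    proceeds; expect very wide CIs there, which is flagged with a warning).
    """
    formulas = formulas or BEHAVIOR_INTERACTION_FORMULAS
    cats = combined["patch_category"].unique()
    behaviors = combined["behavior"].unique()
    cells = combined[combined["response"] == 1].groupby(
        ["patch_category", "behavior"], observed=True).size()
    cells = cells.reindex(pd.MultiIndex.from_product([cats, behaviors]),
                          fill_value=0)
    thin = cells[cells < 5]
    if len(thin):
        warnings.warn("category-state cells with < 5 used fixes: "
                      f"{thin.to_dict()}; expect wide interaction CIs")
    fits = {}
    for name, f in formulas.items():
        fits[name] = fit_mixed_logistic(f, combined)
    return fits


def predict_relative_selection(fit: ModelFit, grid: pd.DataFrame,
                               scaling: pd.DataFrame | None = None) -> np.ndarray:
    """Relative selection strength over a covariate grid.

    exp(fixed-effects linear predictor; random intercept at 0), normalized to
    the grid maximum.  ``scaling`` (or the record stored on the fit) is
    applied first so the grid can be given in natural units.  Values outside
    the fitted covariate range trigger an extrapolation warning.
    """
    scaling = scaling if scaling is not None else fit.scaling
    g = grid.copy()
    if scaling is not None:
        cols = [c for c in scaling["column"] if c in g.columns]
        g, _ = standardize(g, record=scaling[scaling["column"].isin(cols)])
        out_of_range = (g[cols].abs() > 6).any().any()
        if out_of_range:
            warnings.warn("grid extends far beyond the fitted covariate range "
                          "(|z| > 6); predictions are extrapolations")
    try:
        (X,) = patsy.build_design_matrices([fit.design_info], g)
    except patsy.PatsyError as err:
        raise KeyError(f"grid is missing or misnames model covariates: {err}") from err
    eta = np.asarray(X) @ fit.beta.to_numpy()
    w = np.exp(eta - eta.max())
    return w / w.max()
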