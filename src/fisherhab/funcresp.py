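"""Functional responses in habitat selection: specialist vs. generalist use.

A functional response is a change in selection of a resource as its
availability changes.  Following the cross-individual design used in the
wildlife literature, each individual contributes one point: its mean
covariate value over used locations versus over available locations.  An
ordinary least-squares regression of log(mean use) on log(mean availability)
with t-based 90% confidence intervals classifies the response:

* proportional (generalist): slope CI contains 1 AND intercept CI contains 0;
* decreasing functional response (the specialist signature): slope CI
  entirely below 1 -- disproportionately high use where availability is low;
* increasing functional response: slope CI entirely above 1;
* indeterminate otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABELS = ("proportional", "decreasing_FR", "increasing_FR", "indeterminate")


@dataclass
class FunctionalResponseResult:
    covariate: str
    behavior: str
    n_individuals: int
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    offset: float = 0.0            # shift applied before the log transform
    label: str | None = None

    def __post_init__(self):
        lo, hi = self.slope_ci
        if not (lo <= self.slope <= hi or np.isnan(self.slope)):
            raise ValueError("slope must lie within its CI")
        lo, hi = self.intercept_ci
        if not (lo <= self.intercept <= hi or np.isnan(self.intercept)):
            raise ValueError("intercept must lie within its CI")


def per_individual_means(table: pd.DataFrame, covariate: str,
                         min_used: int = 1) -> pd.DataFrame:
    """Per-individual mean use and mean availability of a covariate.

    ``table`` is a use-availability design (response 1/0, unstandardized
    covariate columns).  Individuals lacking used or available rows, or with
    fewer than ``min_used`` used rows, are excluded with a warning.
    """
    if table["individual_id"].nunique() < 2:
        raise ValueError("need >= 2 individuals")
    rows, dropped = [], []
    for iid, g in table.groupby("individual_id", sort=False):
        used = g.loc[g["response"] == 1, covariate].dropna()
        avail = g.loc[g["response"] == 0, covariate].dropna()
        if len(used) < max(min_used, 1) or len(avail) == 0:
            dropped.append(iid)
            continue
        rows.append((iid, used.mean(), avail.mean(), len(used), len(avail)))
    if dropped:
        warnings.warn(f"individuals excluded from functional response for "
                      f"'{covariate}': {dropped}")
    return pd.DataFrame(rows, columns=["individual_id", "mean_use",
                                       "mean_avail", "n_used", "n_avail"])


def fit_functional_response(means: pd.DataFrame, covariate: str = "",
                            behavior: str = "", offset_policy: str = "none",
                            conf: float = 0.90) -> FunctionalResponseResult:
    """OLS of log mean use on log mean availability across individuals.

    ``offset_policy``: "none" errors on non-positive means; "shift" first
    subtracts (global minimum - epsilon) so covariates with negative support
    (e.g. the topographic position index) become loggable.  The applied shift
    is recorded on the result.
    """
    if len(means) < 3:
        raise ValueError("functional response needs >= 3 individuals")
    mu = means["mean_use"].to_numpy(dtype=float)
    ma = means["mean_avail"].to_numpy(dtype=float)
    offset = 0.0
    if offset_policy == "shift":
        lo = min(mu.min(), ma.min())
        if lo <= 0:
            span = max(mu.max(), ma.max()) - lo
            offset = -lo + max(1e-6 * max(span, 1.0), 1e-9)
            mu, ma = mu + offset, ma + offset
    elif offset_policy != "none":
        raise ValueError("offset_policy must be 'none' or 'shift'")
    if (mu <= 0).any() or (ma <= 0).any():
        raise ValueError("non-positive means under offset_policy='none'; "
                         "use offset_policy='shift'")

    import statsmodels.api as sm
    X = sm.add_constant(np.log(ma))
    fit = sm.OLS(np.log(mu), X).fit()
    ci = fit.conf_int(alpha=1.0 - conf)
    return FunctionalResponseResult(
        covariate=covariate, behavior=behavior, n_individuals=len(means),
        slope=float(fit.params[1]), slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept=float(fit.params[0]),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        offset=offset)


def classify_response(fit: FunctionalResponseResult) -> str:
    """Label a fitted response from its confidence intervals alone."""
    s_lo, s_hi = fit.slope_ci
    i_lo, i_hi = fit.intercept_ci
    if s_lo <= 1.0 <= s_hi and i_lo <= 0.0 <= i_hi:
        return "proportional"
    if s_hi < 1.0:
        return "decreasing_FR"
    if s_lo > 1.0:
        return "increasing_FR"
    return "indeterminate"


def functional_response_suite(designs: dict[str, pd.DataFrame],
                              covariates: list[str],
                              offset_policy: str = "shift",
                              min_used: int = 5,
                              out_dir=None) -> pd.DataFrame:
    """One labeled functional response per (covariate, behavior).

    ``designs`` maps behavior name to its use-availability table.  Covariates
    are analysed on their natural (unstandardized) scale.  With ``out_dir``
    set, a natural-scale use-vs-availability scatter with the 1:1 proportional
    reference line and the fitted power curve is saved per pair.
    """
    rows = []
    for behavior, table in designs.items():
        for cov in covariates:
            try:
                means = per_individual_means(table, cov, min_used=min_used)
                fit = fit_functional_response(means, covariate=cov,
                                              behavior=behavior,
                                              offset_policy=offset_policy)
            except ValueError as err:
                logger.warning("functional response %s/%s not estimable: %s",
                               behavior, cov, err)
                rows.append({"covariate": cov, "behavior": behavior,
                             "n": np.nan, "slope": np.nan, "slope_lo90": np.nan,
                             "slope_hi90": np.nan, "intercept": np.nan,
                             "intercept_lo90": np.nan, "intercept_hi90": np.nan,
                             "label": "not_estimable"})
                continue
            fit = replace(fit, label=classify_response(fit))
            rows.append({"covariate": cov, "behavior": behavior,
                         "n": fit.n_individuals, "slope": fit.slope,
                         "slope_lo90": fit.slope_ci[0],
                         "slope_hi90": fit.slope_ci[1],
                         "intercept": fit.intercept,
                         "intercept_lo90": fit.intercept_ci[0],
                         "intercept_hi90": fit.intercept_ci[1],
                         "label": fit.label})
            if out_dir is not None:
                _plot_response(means, fit, out_dir)
    return pd.DataFrame(rows)


def _plot_response(means, fit, out_dir):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(means["mean_avail"], means["mean_use"], color="k", zorder=3)
    lim = np.linspace(means["mean_avail"].min(), means["mean_avail"].max(), 100)
    ax.plot(lim, lim, "k-", lw=1, label="proportional (1:1)")
    pred = np.exp(fit.intercept + fit.slope * np.log(lim + fit.offset)) - fit.offset
    ax.plot(lim, pred, "r-", lw=1.5,
            label=f"fitted (slope {fit.slope:.2f}, {fit.label})")
    ax.set_xlabel(f"mean availability: {fit.covariate}")
    ax.set_ylabel("mean use")
    ax.set_title(f"{fit.behavior}", fontsize=10)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(Path(out_dir) / f"fr_{fit.covariate}_{fit.behavior}.png", dpi=100)
    plt.close(fig)
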