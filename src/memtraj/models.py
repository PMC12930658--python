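"""Mixed-effects interaction models, descriptives, and median regression.

The primary model is a linear mixed model with a random intercept per
participant, fit by REML:

    memory_change ~ biomarker_change * sex * group + age_c + educ_c + apoe

with female, preclinical AD and APOE-e4 non-carrier as reference levels, so
the three-way coefficient is the male x MCI x biomarker-change contrast.
Confidence intervals and p-values use the Wald normal approximation.
Standardized effect sizes come from refitting with the outcome and all
continuous predictors z-scored (binary predictors left 0/1), labeled
small (< 0.20), moderate (0.20-0.39) or large (>= 0.40) by |weight|.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

CONTINUOUS = {"biomarker_change", "age_c", "educ_c", "income"}


@dataclass
class ModelSpec:
    outcome: str = "memory_change"
    biomarker: str = "biomarker_change"
    interaction: str = "three_way"     # "three_way", "sex", "group", "none"
    covariates: list[str] = field(default_factory=lambda: ["age_c", "educ_c", "apoe_carrier"])
    include_income: bool = False
    reml: bool = True
    standardized: bool = True      # also compute standardized effect sizes

    def formula(self) -> str:
        if self.interaction == "three_way":
            fixed = f"{self.biomarker} * sex_male * group_mci"
        elif self.interaction == "sex":
            fixed = f"{self.biomarker} * sex_male"
        elif self.interaction == "group":
            fixed = f"{self.biomarker} * group_mci"
        elif self.interaction == "none":
            fixed = self.biomarker
        else:
            raise ValueError(f"unknown interaction spec: {self.interaction}")
        cov = list(self.covariates)
        if self.include_income:
            cov.append("income")
        rhs = " + ".join([fixed] + cov)
        return f"{self.outcome} ~ {rhs}"


@dataclass
class ModelResult:
    """Fixed effects with Wald CIs, standardized weights, and variance
    components of a random-intercept model."""

    params: pd.DataFrame          # term, b, ci_low, ci_high, p, std_b, std_ci_*, magnitude
    sigma2: float                 # residual variance
    tau00: float                  # random-intercept variance
    icc: float
    n_participants: int
    n_obs: int
    r2_marginal: float
    method: str                   # "lmm-reml" or "ols-fallback"
    converged: bool
    formula: str
    notes: str = ""

    def coef(self, term: str) -> pd.Series:
        hit = self.params[self.params["term"] == term]
        if hit.empty:
            raise KeyError(f"no term '{term}'; have {list(self.params['term'])}")
        return hit.iloc[0]

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("sigma2", "tau00", "icc", "n_participants", "n_obs",
              "r2_marginal", "method", "converged", "formula", "notes")}
        d["params"] = self.params.to_dict(orient="records")
        return d


def effect_size_label(std_weight: float) -> str:
    """Magnitude bands on the absolute standardized weight:
    0.00-0.19 small, 0.20-0.39 moderate, >= 0.40 large."""
    a = abs(std_weight)
    if a >= 0.40:
        return "large"
    if a >= 0.20:
        return "moderate"
    return "small"


def _fit_mixed(formula: str, data: pd.DataFrame, reml: bool):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, data, groups=data["participant_id"])
        try:
            res = model.fit(reml=reml)
            if not res.converged:
                res = model.fit(reml=reml, method="powell", maxiter=2000)
        except Exception:
            res = model.fit(reml=reml, method="powell", maxiter=2000)
    return res


def _standardized_refit(data: pd.DataFrame, spec: ModelSpec, reml: bool) -> pd.DataFrame:
    """Refit with outcome and continuous predictors z-scored; binary 0/1
    predictors untouched. Product terms are rebuilt from the standardized
    components by the formula machinery."""
    sdata = data.copy()
    for col in [spec.outcome] + [c for c in sdata.columns if c in CONTINUOUS]:
        x = sdata[col].to_numpy(float)
        sd = x.std(ddof=1)
        if sd > 0:
            sdata[col] = (x - x.mean()) / sd
    res = _fit_mixed(spec.formula(), sdata, reml)
    ci = res.conf_int()
    fe = res.fe_params
    return pd.DataFrame({
        "term": fe.index,
        "std_b": fe.to_numpy(),
        "std_ci_low": ci.loc[fe.index, 0].to_numpy(),
        "std_ci_high": ci.loc[fe.index, 1].to_numpy(),
    })


def fit_interaction_model(table: pd.DataFrame,
                          spec: ModelSpec | None = None) -> ModelResult:
    """Fit the random-intercept interaction model on the analysis table.

    Falls back to OLS (flagged in ``method``) when no participant has two
    or more rows, in which case tau00 is unidentified.
    """
    spec = spec or ModelSpec()
    formula = spec.formula()
    data = table.dropna(subset=[spec.outcome, spec.biomarker]).copy()
    n_part = data["participant_id"].nunique()
    max_rows = data.groupby("participant_id").size().max()

    if max_rows < 2:
        logger.warning("no participant has >= 2 rows; tau00 unidentified, "
                       "falling back to OLS")
        return _ols_fallback(data, spec, formula, n_part)

    res = _fit_mixed(formula, data, spec.reml)
    sigma2 = float(res.scale)
    tau00 = float(np.asarray(res.cov_re)[0, 0])
    icc = tau00 / (tau00 + sigma2)
    notes = ""
    if tau00 < 1e-8 * max(sigma2, 1e-12):
        notes = "singular fit: random-intercept variance is ~0"
        logger.warning(notes)
    if not res.converged:
        notes = (notes + "; " if notes else "") + "optimizer did not converge"

    fe = res.fe_params
    ci = res.conf_int().loc[fe.index]
    pvals = res.pvalues.loc[fe.index]
    params = pd.DataFrame({
        "term": fe.index,
        "b": fe.to_numpy(),
        "ci_low": ci[0].to_numpy(),
        "ci_high": ci[1].to_numpy(),
        "p": pvals.to_numpy(),
    })
    if spec.standardized:
        std = _standardized_refit(data, spec, spec.reml)
        params = params.merge(std, on="term", how="left")
        params["magnitude"] = params["std_b"].map(effect_size_label)
    else:
        params["std_b"] = np.nan
        params["std_ci_low"] = np.nan
        params["std_ci_high"] = np.nan
        params["magnitude"] = ""

    # marginal (fixed-effects) R^2: var(Xb) / (var(Xb) + tau00 + sigma2)
    fitted_fixed = res.model.exog @ fe.to_numpy()
    var_f = float(np.var(fitted_fixed, ddof=0))
    r2_marg = var_f / (var_f + tau00 + sigma2)

    return ModelResult(params=params, sigma2=sigma2, tau00=tau00, icc=icc,
                       n_participants=n_part, n_obs=len(data),
                       r2_marginal=r2_marg, method="lmm-reml",
                       converged=bool(res.converged), formula=formula,
                       notes=notes)


def _ols_fallback(data, spec, formula, n_part) -> ModelResult:
    res = smf.ols(formula, data).fit()
    ci = res.conf_int()
    params = pd.DataFrame({
        "term": res.params.index,
        "b": res.params.to_numpy(),
        "ci_low": ci[0].to_numpy(),
        "ci_high": ci[1].to_numpy(),
        "p": res.pvalues.to_numpy(),
    })
    params["std_b"] = np.nan
    params["std_ci_low"] = np.nan
    params["std_ci_high"] = np.nan
    params["magnitude"] = ""
    sigma2 = float(res.mse_resid)
    return ModelResult(params=params, sigma2=sigma2, tau00=0.0, icc=0.0,
                       n_participants=n_part, n_obs=len(data),
                       r2_marginal=float(res.rsquared), method="ols-fallback",
                       converged=True, formula=formula,
                       notes="OLS fallback: random intercept unidentified")


def fit_stratified_models(table: pd.DataFrame,
                          by: str = "group",
                          spec: ModelSpec | None = None) -> dict[str, ModelResult]:
    """Two-way interaction models within strata of diagnostic group or sex.

    ``by='group'`` fits biomarker x sex within preclinical and MCI;
    ``by='sex'`` fits biomarker x group within females and males.
    """
    spec = spec or ModelSpec()
    if by == "group":
        col, interaction = "group_mci", "sex"
        names = {0: "preclinical", 1: "mci"}
    elif by == "sex":
        col, interaction = "sex_male", "group"
        names = {0: "female", 1: "male"}
    else:
        raise ValueError("by must be 'group' or 'sex'")

    out: dict[str, ModelResult] = {}
    for value, name in names.items():
        sub = table[table[col] == value]
        if sub.empty:
            logger.warning("stratum %s empty; skipped", name)
            continue
        s = ModelSpec(outcome=spec.outcome, biomarker=spec.biomarker,
                      interaction=interaction, covariates=spec.covariates,
                      include_income=spec.include_income, reml=spec.reml,
                      standardized=spec.standardized)
        out[name] = fit_interaction_model(sub, s)
    return out


# ---------------------------------------------------------------------------
# descriptive comparisons (Table-1/2-shaped)
# ---------------------------------------------------------------------------

def descriptive_comparisons(df: pd.DataFrame,
                            continuous: list[str],
                            categorical: list[str] | None = None,
                            by: str = "sex",
                            within: str | None = None,
                            equal_var: bool = False) -> pd.DataFrame:
    """Group comparisons: Welch t-tests (default) for continuous variables,
    chi-square for categorical, optionally within strata.

    Returns a tidy frame with per-level mean (SD) or N (%) plus the test
    statistic and p-value; empty or single-observation cells skip the test
    with a warning.
    """
    categorical = categorical or []
    strata = [(None, df)] if within is None else list(df.groupby(within))
    rows = []
    for stratum, d in strata:
        levels = sorted(d[by].dropna().unique())
        if len(levels) != 2:
            logger.warning("comparison needs exactly 2 levels of %r, got %s; "
                           "skipped", by, levels)
            continue
        a = d[d[by] == levels[0]]
        b = d[d[by] == levels[1]]
        for var in continuous:
            x, y = a[var].dropna(), b[var].dropna()
            row = {"stratum": stratum, "variable": var, "kind": "continuous",
                   f"{levels[0]}_summary": f"{x.mean():.3f} ({x.std(ddof=1):.3f})" if len(x) else "",
                   f"{levels[1]}_summary": f"{y.mean():.3f} ({y.std(ddof=1):.3f})" if len(y) else ""}
            if len(x) >= 2 and len(y) >= 2:
                t, p = stats.ttest_ind(x, y, equal_var=equal_var)
                row.update(statistic=float(t), p=float(p))
            else:
                logger.warning("cell too small for t-test: %s", var)
                row.update(statistic=np.nan, p=np.nan)
            rows.append(row)
        for var in categorical:
            ct = pd.crosstab(d[by], d[var])
            row = {"stratum": stratum, "variable": var, "kind": "categorical"}
            for lev in levels:
                if lev in ct.index:
                    counts = ct.loc[lev]
                    tot = counts.sum()
                    row[f"{lev}_summary"] = "; ".join(
                        f"{k}: {v} ({100 * v / tot:.1f}%)" for k, v in counts.items())
            if ct.shape == (2, 2) and (ct.to_numpy() > 0).all() or ct.size > 0:
                try:
                    chi2, p, _, _ = stats.chi2_contingency(ct)
                    row.update(statistic=float(chi2), p=float(p))
                except ValueError:
                    logger.warning("chi-square skipped for %s (empty cell)", var)
                    row.update(statistic=np.nan, p=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# median (quantile) regression with participant bootstrap
# ---------------------------------------------------------------------------

def fit_median_regression(table: pd.DataFrame,
                          outcome: str,
                          spec: ModelSpec | None = None,
                          n_boot: int = 500,
                          seed: int = 0) -> ModelResult:
    """Median (tau = 0.5) regression with the same fixed-effect structure,
    cluster-robust CIs/p-values by participant-level percentile bootstrap."""
    spec = spec or ModelSpec()
    spec = ModelSpec(outcome=outcome, biomarker=spec.biomarker,
                     interaction=spec.interaction, covariates=spec.covariates,
                     include_income=spec.include_income)
    formula = spec.formula()
    data = table.dropna(subset=[outcome, spec.biomarker]).copy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.quantreg(formula, data).fit(q=0.5)
    point = res.params

    rng = np.random.default_rng(seed)
    ids = data["participant_id"].unique()
    groups = {pid: g for pid, g in data.groupby("participant_id")}
    boots = np.full((n_boot, len(point)), np.nan)
    failures = 0
    for b in range(n_boot):
        take = rng.choice(ids, size=len(ids), replace=True)
        sample = pd.concat([groups[pid] for pid in take], ignore_index=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bres = smf.quantreg(formula, sample).fit(q=0.5)
            boots[b] = bres.params.reindex(point.index).to_numpy()
        except Exception:
            failures += 1
    if failures:
        logger.warning("median regression bootstrap: %d of %d replicates "
                       "failed to converge", failures, n_boot)
    ci_low = np.nanpercentile(boots, 2.5, axis=0)
    ci_high = np.nanpercentile(boots, 97.5, axis=0)
    # symmetric bootstrap p: fraction of replicates crossing zero, doubled
    pvals = []
    for j in range(len(point)):
        col = boots[:, j]
        col = col[np.isfinite(col)]
        if len(col) == 0:
            pvals.append(np.nan)
            continue
        frac = min((col <= 0).mean(), (col >= 0).mean())
        pvals.append(min(1.0, 2.0 * frac))
    params = pd.DataFrame({
        "term": point.index,
        "b": point.to_numpy(),
        "ci_low": ci_low,
        "ci_high": ci_high,
        "p": pvals,
    })
    params["std_b"] = np.nan
    params["std_ci_low"] = np.nan
    params["std_ci_high"] = np.nan
    params["magnitude"] = ""
    return ModelResult(params=params, sigma2=float(np.var(res.resid, ddof=1)),
                       tau00=0.0, icc=0.0,
                       n_participants=data["participant_id"].nunique(),
                       n_obs=len(data), r2_marginal=np.nan,
                       method=f"quantreg-0.5-boot{n_boot}", converged=True,
                       formula=formula,
                       notes=f"participant bootstrap, B={n_boot}, seed={seed}")
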