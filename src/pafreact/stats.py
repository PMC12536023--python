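"""Condition-by-diagnosis reactivity statistics.

Implements the analysis battery applied to the macro-region PAF table:

* descriptive group comparisons from printed summaries (pooled two-sample
  t from mean/SE/n, Pearson chi-square for sex);
* per-region linear mixed-effects models of PAF with fixed effects for
  diagnosis, condition, their interaction, age and sex and a random
  intercept per participant (ML fit, Wald z);
* diagnostic-subgroup mixed models (condition + age + sex);
* Bonferroni gating (p < 0.05/n, strict inequality);
* change-score regressions of EO-DR reactivity on the DR baseline with
  heteroscedasticity-robust (HC1) standard errors;
* log-SRS association models predicting social responsiveness from the
  temporal reactivity.

Coding conventions: TD = 0 / ASD = 1, DR = 0 / EO = 1, female = 0 /
male = 1; age in months.  Missing macro-region PAF values are dropped
per model (complete case).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ModelResult",
    "pooled_two_sample_t",
    "chi_square_2x2",
    "prepare_model_frame",
    "fit_reactivity_lmm",
    "fit_subgroup_lmm",
    "bonferroni_gate",
    "change_scores",
    "change_score_regression",
    "srs_association",
]


@dataclass(frozen=True)
class ModelResult:
    """Coefficient table of one fitted model.

    ``table`` columns: term, coef, se, stat, p, ci_low, ci_high.
    ``stat_label`` is "z" for Wald tests from mixed models and "t" for
    OLS; ``metadata`` records region, subgroup, estimator and covariance
    flavor.
    """

    table: pd.DataFrame
    stat_label: str
    df_resid: float | None = None
    metadata: dict = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self) -> None:
        t = self.table
        if not ((t["p"] >= 0) & (t["p"] <= 1)).all():
            raise ValueError("p-values must lie in [0, 1]")
        ok = (t["ci_low"] <= t["coef"] + 1e-12) & (t["coef"] <= t["ci_high"] + 1e-12)
        if not ok.all():
            raise ValueError("confidence bounds must bracket coefficients")

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "coef"])

    def p(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])

    def se(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "se"])


def pooled_two_sample_t(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> tuple[float, int]:
    """Pooled-variance Student t from per-group (mean, SE, n) summaries.

    Standard errors are converted back to SDs (sd = se * sqrt(n)); the
    statistic tests group2 - group1 with df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    var1 = (se1 * np.sqrt(n1)) ** 2
    var2 = (se2 * np.sqrt(n2)) ** 2
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * var1 + (n2 - 1) * var2) / df
    t = (mean2 - mean1) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    return float(t), int(df)


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for a 2x2 table."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined with a zero marginal")
    stat, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def prepare_model_frame(table: pd.DataFrame, region: str) -> pd.DataFrame:
    """Region subset with numeric codings and missing PAF rows dropped."""
    sub = table[table["region"] == region].copy()
    sub = sub.dropna(subset=["paf_hz"])
    sub["asd"] = (sub["diagnosis"] == "ASD").astype(float)
    sub["eo"] = (sub["condition"] == "EO").astype(float)
    sub["male"] = pd.to_numeric(sub["sex"]).astype(float)
    sub["age"] = pd.to_numeric(sub["age_months"]).astype(float)
    return sub


_CI_Z = scipy.stats.norm.ppf(0.975)


def _wald_table(params, bse, names) -> pd.DataFrame:
    params = np.asarray(params, float)
    bse = np.asarray(bse, float)
    z = params / bse
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "term": names,
            "coef": params,
            "se": bse,
            "stat": z,
            "p": p,
            "ci_low": params - _CI_Z * bse,
            "ci_high": params + _CI_Z * bse,
        }
    )


def _fit_mixedlm(sub: pd.DataFrame, formula: str, names: dict, reml: bool, meta: dict) -> ModelResult:
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, data=sub, groups=sub["subject"])
        try:
            res = model.fit(reml=reml)
        except np.linalg.LinAlgError:
            res = model.fit(reml=reml, method="powell")
    converged = bool(getattr(res, "converged", True))
    singular = any("singular" in str(w.message).lower() for w in caught)
    fe = res.fe_params
    table = _wald_table(
        fe.to_numpy(), res.bse.loc[fe.index].to_numpy(), [names.get(t, t) for t in fe.index]
    )
    meta = dict(meta, estimator="MixedLM-" + ("REML" if reml else "ML"), singular=singular)
    return ModelResult(
        table=table, stat_label="z", df_resid=None, metadata=meta, converged=converged
    )


def fit_reactivity_lmm(
    table: pd.DataFrame, region: str, reml: bool = False
) -> ModelResult:
    """Mixed model: PAF ~ diagnosis * condition + age + sex + (1 | subject).

    Fitted by maximum likelihood with Wald z tests on the fixed effects.
    Rows with missing PAF are dropped; non-convergence and singular random
    effects are reported on the result, never silently swallowed.
    """
    sub = prepare_model_frame(table, region)
    for g in ("TD", "ASD"):
        if sub.loc[sub["diagnosis"] == g, "subject"].nunique() < 2:
            raise ValueError(f"need >= 2 subjects with data in group {g} for {region}")
    names = {
        "Intercept": "intercept",
        "asd": "diagnosis",
        "eo": "condition",
        "asd:eo": "diagnosis_x_condition",
        "age": "age",
        "male": "sex",
    }
    return _fit_mixedlm(
        sub, "paf_hz ~ asd * eo + age + male", names, reml, {"region": region}
    )


def fit_subgroup_lmm(
    table: pd.DataFrame, region: str, diagnosis: str, reml: bool = False
) -> ModelResult:
    """Within-group mixed model: PAF ~ condition + age + sex + (1 | subject)."""
    sub = prepare_model_frame(table, region)
    sub = sub[sub["diagnosis"] == diagnosis]
    if sub["subject"].nunique() < 2:
        raise ValueError(f"need >= 2 subjects in subgroup {diagnosis} for {region}")
    names = {"Intercept": "intercept", "eo": "condition", "age": "age", "male": "sex"}
    return _fit_mixedlm(
        sub,
        "paf_hz ~ eo + age + male",
        names,
        reml,
        {"region": region, "subgroup": diagnosis},
    )


def bonferroni_gate(p_values, n_comparisons: int) -> np.ndarray:
    """Significance flags at the Bonferroni-corrected level 0.05/n (strict)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return p < 0.05 / n_comparisons


def change_scores(table: pd.DataFrame, region: str) -> pd.DataFrame:
    """Per-subject EO - DR change and DR baseline for one region.

    Subjects missing either condition in the region are dropped.
    """
    sub = prepare_model_frame(table, region)
    wide = sub.pivot_table(index="subject", columns="condition", values="paf_hz")
    if "DR" not in wide.columns or "EO" not in wide.columns:
        raise ValueError(f"both conditions required in region {region}")
    wide = wide.dropna(subset=["DR", "EO"])
    covs = sub.drop_duplicates("subject").set_index("subject")[
        ["diagnosis", "asd", "age", "male", "srs_total"]
    ]
    out = wide.join(covs, how="inner").reset_index()
    out["delta_paf"] = out["EO"] - out["DR"]
    out = out.rename(columns={"DR": "baseline_paf"})
    return out[
        ["subject", "diagnosis", "asd", "age", "male", "srs_total", "baseline_paf", "delta_paf"]
    ]


def _ols_hc1(formula: str, data: pd.DataFrame, names: dict, meta: dict) -> ModelResult:
    model = smf.ols(formula, data=data)
    if model.exog.shape[0] <= model.exog.shape[1]:
        raise ValueError("fewer observations than parameters")
    res = model.fit(cov_type="HC1")
    params = res.params
    ci = res.conf_int()
    table = pd.DataFrame(
        {
            "term": [names.get(t, t) for t in params.index],
            "coef": params.to_numpy(),
            "se": res.bse.loc[params.index].to_numpy(),
            "stat": res.tvalues.loc[params.index].to_numpy(),
            "p": res.pvalues.loc[params.index].to_numpy(),
            "ci_low": ci.loc[params.index, 0].to_numpy(),
            "ci_high": ci.loc[params.index, 1].to_numpy(),
        }
    )
    meta = dict(meta, estimator="OLS", cov="HC1")
    return ModelResult(
        table=table, stat_label="t", df_resid=float(res.df_resid), metadata=meta
    )


def change_score_regression(
    table: pd.DataFrame, region: str, include_interaction: bool = False
) -> ModelResult:
    """OLS of the EO-DR change on baseline PAF, diagnosis, age and sex.

    Standard errors are heteroscedasticity-consistent (HC1); t statistics
    carry the OLS residual degrees of freedom.  With
    ``include_interaction`` a diagnosis x baseline term tests whether the
    baseline dependence differs between groups.
    """
    cs = change_scores(table, region)
    names = {
        "Intercept": "intercept",
        "baseline_paf": "baseline_paf",
        "asd": "diagnosis",
        "age": "age",
        "male": "sex",
        "baseline_paf:asd": "baseline_x_diagnosis",
    }
    formula = "delta_paf ~ baseline_paf + asd + age + male"
    if include_interaction:
        formula += " + baseline_paf:asd"
    return _ols_hc1(formula, cs, names, {"region": region})


def srs_association(table: pd.DataFrame, region: str) -> ModelResult:
    """OLS of log-transformed raw SRS totals on the EO-DR change, age, sex.

    Raw SRS scores must be strictly positive; HC1 robust standard errors.
    The natural log is used (base changes coefficients by a constant
    factor only).
    """
    cs = change_scores(table, region).dropna(subset=["srs_total"])
    if (cs["srs_total"] <= 0).any():
        raise ValueError("raw SRS scores must be positive for the log transform")
    cs = cs.assign(log_srs=np.log(cs["srs_total"].astype(float)))
    names = {
        "Intercept": "intercept",
        "delta_paf": "delta_paf",
        "age": "age",
        "male": "sex",
    }
    return _ols_hc1("log_srs ~ delta_paf + age + male", cs, names, {"region": region, "response": "log_srs"})
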