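"""Period-wise statistical battery over the night-record table.

This module is a thin, declarative layer over established mixed-model
machinery: gaussian responses go through :class:`statsmodels` ``MixedLM``
(bird as random intercept), binomial responses through the variational
``BinomialBayesMixedGLM``, the repeated-measures correlation through
``pingouin.rm_corr``, and pairwise period contrasts use Tukey-adjusted
estimated marginal means.  Candidate fixed-effect structures are compared by
AIC (maximum-likelihood fits); a model must beat the alternatives by at
least two AIC points, otherwise the simpler model is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

__all__ = [
    "ModelSpec",
    "FitReport",
    "fit_mixed",
    "select_by_aic",
    "fit_battery",
    "pairwise_contrasts",
    "repeated_measures_corr",
    "default_battery",
]

ALPHA = 0.05


@dataclass
class ModelSpec:
    """One response in the battery: a global formula plus nested candidates."""

    name: str
    formula: str
    family: str = "gaussian"           # gaussian | binomial
    groups: str = "bird_id"
    candidates: list[str] = field(default_factory=list)
    subset: str | None = None          # pandas query applied before fitting

    def all_formulas(self) -> list[str]:
        return [self.formula] + [c for c in self.candidates
                                 if c != self.formula]


@dataclass
class FitReport:
    name: str
    selected_formula: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series | None
    aic_table: pd.DataFrame | None
    n_obs: int
    n_groups: int
    family: str
    diagnostics: dict = field(default_factory=dict)
    emmeans: pd.DataFrame | None = None
    contrasts: pd.DataFrame | None = None
    result: object | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name, "selected_formula": self.selected_formula,
            "family": self.family, "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "pvalues": None if self.pvalues is None else self.pvalues.to_dict(),
            "diagnostics": self.diagnostics,
        }


def fit_mixed(formula: str, data: pd.DataFrame, groups: str = "bird_id",
              family: str = "gaussian", reml: bool = True):
    """Fit one mixed model with a random intercept per group."""
    if groups not in data.columns:
        raise ValueError(f"grouping column {groups!r} not in data")
    if data[groups].nunique() < 2:
        raise ValueError("need at least 2 grouping levels")
    if family == "gaussian":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return smf.mixedlm(formula, data, groups=data[groups]).fit(
                reml=reml)
    if family == "binomial":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return BinomialBayesMixedGLM.from_formula(
                formula, {"grp": f"0 + C({groups})"}, data).fit_vb()
    raise ValueError(f"unknown family {family!r}")


def _n_fixed(formula: str, data: pd.DataFrame) -> int:
    return patsy.dmatrix(formula.split("~", 1)[1], data).shape[1]


def select_by_aic(formulas: list[str], data: pd.DataFrame,
                  groups: str = "bird_id") -> tuple[str, pd.DataFrame]:
    """AIC selection over gaussian candidates (ML fits).

    The model with the lowest AIC is selected only when it beats every other
    candidate by at least two points; otherwise the most parsimonious model
    within two points of the minimum is retained.
    """
    rows = []
    for f in formulas:
        try:
            res = fit_mixed(f, data, groups=groups, reml=False)
            rows.append({"formula": f, "aic": float(res.aic),
                         "n_fixed": _n_fixed(f, data),
                         "converged": bool(res.converged)})
        except Exception as err:  # singular fits are reported, then dropped
            rows.append({"formula": f, "aic": np.nan,
                         "n_fixed": _n_fixed(f, data), "converged": False,
                         "error": str(err)})
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    ok = table.dropna(subset=["aic"])
    if ok.empty:
        raise RuntimeError("no candidate model converged")
    best_aic = ok["aic"].min()
    eligible = ok[ok["aic"] <= best_aic + 2.0]
    chosen = eligible.sort_values(["n_fixed", "aic"]).iloc[0]["formula"]
    table["selected"] = table["formula"] == chosen
    return chosen, table


def _gaussian_report(spec: ModelSpec, data: pd.DataFrame) -> FitReport:
    if spec.candidates:
        chosen, table = select_by_aic(spec.all_formulas(), data, spec.groups)
    else:
        chosen, table = spec.formula, None
    res = fit_mixed(chosen, data, groups=spec.groups, reml=True)
    diag = {}
    try:
        resid = np.asarray(res.resid)
        if 3 <= len(resid) <= 4999:
            diag["residual_normality_p"] = float(stats.shapiro(resid)[1])
        rho = stats.spearmanr(np.abs(resid), np.asarray(res.fittedvalues))[0]
        diag["heteroscedasticity_rho"] = float(rho)
        diag["flags"] = [f for f, bad in [
            ("nonnormal_residuals",
             diag.get("residual_normality_p", 1) < 0.01),
            ("heteroscedastic", abs(rho) > 0.3)] if bad]
    except Exception as err:  # singular random-effect structure
        diag["flags"] = [f"diagnostics_unavailable: {err}"]
    fe = res.fe_params.index
    return FitReport(
        name=spec.name, selected_formula=chosen,
        params=res.params[fe], bse=res.bse[fe], pvalues=res.pvalues[fe],
        aic_table=table, n_obs=int(res.nobs),
        n_groups=data[spec.groups].nunique(), family="gaussian",
        diagnostics=diag, result=res)


def _binomial_report(spec: ModelSpec, data: pd.DataFrame) -> FitReport:
    res = fit_mixed(spec.formula, data, groups=spec.groups, family="binomial")
    names = list(res.model.exog_names)
    params = pd.Series(res.fe_mean, index=names)
    bse = pd.Series(res.fe_sd, index=names)
    z = params / bse
    pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)
    return FitReport(
        name=spec.name, selected_formula=spec.formula, params=params,
        bse=bse, pvalues=pvals, aic_table=None,
        n_obs=len(data), n_groups=data[spec.groups].nunique(),
        family="binomial", result=res)


def fit_battery(data: pd.DataFrame,
                specs: list[ModelSpec]) -> dict[str, FitReport]:
    """Fit every model spec on the (optionally subset) night-record table."""
    reports: dict[str, FitReport] = {}
    for spec in specs:
        sub = data.query(spec.subset) if spec.subset else data
        sub = sub.dropna(
            subset=[v for v in _formula_vars(spec.formula) if v in sub.columns])
        bool_cols = sub.select_dtypes(include=[bool]).columns
        if len(bool_cols):
            sub = sub.assign(**{c: sub[c].astype(int) for c in bool_cols})
        try:
            if spec.family == "binomial":
                reports[spec.name] = _binomial_report(spec, sub)
            else:
                reports[spec.name] = _gaussian_report(spec, sub)
        except Exception as err:
            warnings.warn(f"model {spec.name!r} failed: {err}", stacklevel=2)
    return reports


def _formula_vars(formula: str) -> list[str]:
    import re
    return list({w for w in re.findall(r"[A-Za-z_][A-Za-z0-9_]*", formula)
                 if w not in {"C", "np", "log", "I"}})


def pairwise_contrasts(report: FitReport, data: pd.DataFrame,
                       margin: str = "period") -> pd.DataFrame:
    """Estimated marginal means per level of ``margin`` and Tukey-adjusted
    pairwise differences, computed from the fitted fixed effects."""
    res = report.result
    if res is None or report.family != "gaussian":
        raise ValueError("contrasts need a fitted gaussian mixed model")
    design_info = res.model.data.design_info
    if not any(margin in f for f in design_info.column_names):
        raise ValueError(f"{margin!r} is not a fixed effect of the model")
    levels = sorted(data[margin].dropna().unique())
    numeric = data.select_dtypes(include=[np.number]).mean(numeric_only=True)
    grid = pd.DataFrame([{**numeric.to_dict(), margin: lev} for lev in levels])
    X = np.asarray(patsy.build_design_matrices([design_info], grid)[0])
    beta = np.asarray(res.fe_params)
    k = len(beta)
    V = np.asarray(res.cov_params())[:k, :k]
    means = X @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, V, X))
    em = pd.DataFrame({margin: levels, "emmean": means, "se": se})
    df_resid = max(int(res.nobs) - k, 2)
    rows = []
    for i, j in combinations(range(len(levels)), 2):
        L = X[i] - X[j]
        d = float(L @ beta)
        sed = float(np.sqrt(L @ V @ L))
        q = abs(d) / sed * np.sqrt(2.0)
        p = float(stats.studentized_range.sf(q, len(levels), df_resid))
        rows.append({"contrast": f"{levels[i]} - {levels[j]}",
                     "estimate": d, "se": sed, "p_tukey": p})
    report.emmeans = em
    report.contrasts = pd.DataFrame(rows)
    return report.contrasts


def repeated_measures_corr(data: pd.DataFrame, x: str, y: str,
                           subject: str) -> dict:
    """Within-subject correlation (subject-centred ANCOVA), with 95% CI."""
    counts = data.groupby(subject)[x].count()
    good = counts[counts >= 2].index
    if len(good) < len(counts):
        warnings.warn(f"dropping {len(counts) - len(good)} subject(s) with "
                      "fewer than 2 observations", stacklevel=2)
    sub = data[data[subject].isin(good)]
    if sub[subject].nunique() < 3:
        raise ValueError("need at least 3 subjects with repeated measures")
    import pingouin as pg
    res = pg.rm_corr(data=sub, x=x, y=y, subject=subject)
    return {"r": float(res["r"].iloc[0]), "dof": int(res["dof"].iloc[0]),
            "pval": float(res["pval"].iloc[0]),
            "ci95": list(res["CI95"].iloc[0])}


def default_battery() -> list[ModelSpec]:
    """The standard period-wise battery over the night-record table."""
    per = "C(period)"
    return [
        ModelSpec("torpor_occurrence_vs_fat_breeding",
                  "torpid ~ evening_fat_content", family="binomial",
                  subset="period == 'breeding'"),
        ModelSpec("torpor_occurrence_vs_fat_migration",
                  "torpid ~ evening_fat_content", family="binomial",
                  subset="period == 'migration'"),
        ModelSpec("duration_vs_fat_by_period",
                  f"torpor_duration_h ~ evening_fat_content * {per}",
                  candidates=[f"torpor_duration_h ~ evening_fat_content + {per}",
                              f"torpor_duration_h ~ {per}"],
                  subset="torpid"),
        ModelSpec("duration_vs_night_length_by_period",
                  f"torpor_duration_h ~ night_length_h * {per}",
                  candidates=[f"torpor_duration_h ~ night_length_h + {per}",
                              f"torpor_duration_h ~ {per}"],
                  subset="torpid"),
        ModelSpec("entry_time_vs_fat_by_period",
                  f"entry_time_h ~ evening_fat_content * {per}",
                  candidates=[f"entry_time_h ~ evening_fat_content + {per}",
                              f"entry_time_h ~ {per}"],
                  subset="torpid"),
        ModelSpec("pre_torpor_energy_vs_fat_by_period",
                  f"pre_torpor_energy_kj ~ evening_fat_content * {per}",
                  candidates=[f"pre_torpor_energy_kj ~ evening_fat_content + {per}",
                              f"pre_torpor_energy_kj ~ {per}"],
                  subset="torpid"),
        ModelSpec("fat_loss_vs_duration_by_period",
                  f"overnight_fat_loss_mg ~ torpor_duration_h * {per}",
                  candidates=[f"overnight_fat_loss_mg ~ torpor_duration_h + {per}"],
                  subset="torpid"),
        ModelSpec("fat_at_entry_vs_entry_time",
                  "fat_at_entry_pct ~ entry_time_h + night_length_h",
                  candidates=["fat_at_entry_pct ~ entry_time_h"],
                  subset="torpid"),
    ]
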