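"""Association layer: annualized change, standardized OLS, mixed models,
stepwise selection and Benjamini-Hochberg FDR.

All continuous variables are z-scored against the *baseline-visit*
mean/SD (so longitudinal effects are expressed in baseline-SD units);
categorical covariates (gender, treatment class) enter dummy-coded and
unstandardized; time stays in raw years since baseline.  Cross-sectional
models are OLS on baseline rows; longitudinal models are linear mixed
models with a random intercept per subject, fitted by maximum likelihood
with Wald confidence intervals (statsmodels MixedLM).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "ModelResult",
    "AnalysisConfig",
    "annualized_change",
    "zscore",
    "standardize_columns",
    "fit_cross_sectional",
    "fit_longitudinal",
    "stepwise_select",
    "bh_fdr",
    "run_associations",
]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "gender", "disease_duration", "dmt_class")

MRI_OUTCOMES = ("nbv", "ncgmv", "ndgmv", "nwmv", "lesion_ml")
CLINICAL_OUTCOMES = ("edss", "sdmt", "bvmtr", "cvlt2")


@dataclass
class ModelResult:
    """One fitted term: standardized beta, Wald CI, p-values."""

    term: str
    beta_std: float
    se: float
    ci_lo: float
    ci_hi: float
    p: float
    p_fdr: float | None = None
    adj_r2: float | None = None

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "beta_std": self.beta_std,
            "se": self.se,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
            "p": self.p,
            "p_fdr": self.p_fdr,
            "adj_r2": self.adj_r2,
        }


@dataclass(frozen=True)
class AnalysisConfig:
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    fdr_q: float = 0.05
    stepwise_enter_p: float = 0.05
    stepwise_remove_p: float = 0.10
    ventricle_adjust: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        if not self.stepwise_enter_p < self.stepwise_remove_p:
            raise ValueError("enter_p must be < remove_p")


def annualized_change(visits) -> float | None:
    """Mean of per-interval annualized changes; ``None`` for a single
    visit.

    ``visits`` is an ordered sequence of (time_years, value) pairs with
    strictly increasing times.
    """
    visits = list(visits)
    times = np.asarray([t for t, _ in visits], dtype=float)
    values = np.asarray([v for _, v in visits], dtype=float)
    if not (np.all(np.isfinite(times)) and np.all(np.isfinite(values))):
        raise ValueError("times and values must be finite")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if len(visits) < 2:
        return None
    return float(np.mean(np.diff(values) / np.diff(times)))


def zscore(values) -> np.ndarray:
    """Center to mean 0 and scale to sample SD 1 (ddof=1)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to z-score")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score values with zero spread")
    return (values - values.mean()) / sd


def _is_continuous(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s)


def standardize_columns(df: pd.DataFrame, cols,
                        anchor: pd.DataFrame | None = None) -> pd.DataFrame:
    """Return a copy with ``<col>_z`` columns for the continuous ``cols``,
    centred/scaled by ``anchor`` rows (default: baseline visit if a
    ``visit`` column exists, else all rows)."""
    out = df.copy()
    if anchor is None:
        anchor = df[df["visit"] == 0] if "visit" in df.columns else df
    for col in cols:
        if not _is_continuous(df[col]):
            continue
        mu = anchor[col].mean()
        sd = anchor[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot standardize {col!r}: zero spread")
        out[col + "_z"] = (df[col] - mu) / sd
    return out


def _covariate_terms(df: pd.DataFrame, covariates) -> list[str]:
    terms = []
    for c in covariates:
        terms.append(c + "_z" if _is_continuous(df[c]) else f"C({c})")
    return terms


def _check_rank(res) -> None:
    exog = res.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        names = res.model.exog_names
        raise ValueError(
            f"rank-deficient design ({rank} < {exog.shape[1]}); "
            f"collinear terms among {names}")


def fit_cross_sectional(table: pd.DataFrame, outcome: str, predictor: str,
                        covariates=DEFAULT_COVARIATES,
                        config: AnalysisConfig | None = None) -> ModelResult:
    """Adjusted OLS of z-scored outcome on z-scored predictor (baseline
    rows), returning the predictor's standardized coefficient."""
    config = config or AnalysisConfig()
    covariates = tuple(covariates)
    df = table[table["visit"] == 0] if "visit" in table.columns else table
    cols = [outcome, predictor, *covariates]
    if config.ventricle_adjust and "nlvv" not in cols:
        cols.append("nlvv")
    df = df[cols].dropna()
    n_params = 2 + len(covariates) + config.ventricle_adjust
    if len(df) < 10 + n_params:
        raise ValueError(f"too few complete cases ({len(df)})")
    df = standardize_columns(df, [c for c in cols if _is_continuous(df[c])],
                             anchor=df)
    rhs = [predictor + "_z"] + _covariate_terms(df, covariates)
    if config.ventricle_adjust:
        rhs.append("nlvv_z")
    res = smf.ols(f"{outcome}_z ~ {' + '.join(rhs)}", data=df).fit()
    _check_rank(res)
    term = predictor + "_z"
    lo, hi = res.conf_int().loc[term]
    return ModelResult(
        term=predictor, beta_std=float(res.params[term]),
        se=float(res.bse[term]), ci_lo=float(lo), ci_hi=float(hi),
        p=float(res.pvalues[term]), adj_r2=float(res.rsquared_adj),
    )


def _baseline_column(table: pd.DataFrame, var: str) -> pd.Series:
    base = table[table["visit"] == 0].set_index("subject_id")[var]
    return table["subject_id"].map(base)


def fit_longitudinal(table: pd.DataFrame, outcome: str,
                     covariates=DEFAULT_COVARIATES,
                     baseline_interaction: str | None = None,
                     config: AnalysisConfig | None = None
                     ) -> list[ModelResult]:
    """Random-intercept mixed model of the outcome over follow-up time.

    Fixed effects: time (years since baseline), optional baseline-measure
    main effect and baseline x time interaction, plus the adjustment
    covariates.  ML estimation; Wald CIs.  Returns results for the time
    term and (if requested) the baseline and interaction terms.
    """
    config = config or AnalysisConfig()
    covariates = tuple(covariates)
    cols = [outcome, "time_years", "subject_id", "visit", *covariates]
    if baseline_interaction:
        cols.append(baseline_interaction)
    if config.ventricle_adjust and "nlvv" not in cols:
        cols.append("nlvv")
    df = table[list(dict.fromkeys(cols))].dropna().copy()

    visit_counts = df.groupby("subject_id").size()
    if (visit_counts >= 2).sum() < 20:
        raise ValueError("need >= 2 visits for at least 20 subjects")

    # covariates enter at their baseline value: disease duration at
    # assessment is baseline duration + time, which is within-subject
    # collinear with the time effect and would absorb part of the slope
    for c in covariates:
        df[c] = _baseline_column(df, c)

    zcols = [outcome, *[c for c in covariates if _is_continuous(df[c])]]
    if config.ventricle_adjust:
        zcols.append("nlvv")
    df = standardize_columns(df, zcols)

    rhs = ["time_years"] + _covariate_terms(df, covariates)
    wanted = {"time_years": "time"}
    if baseline_interaction:
        base = _baseline_column(df, baseline_interaction)
        mu, sd = base[df["visit"] == 0].mean(), base[df["visit"] == 0].std(ddof=1)
        df["baseline_mod_z"] = (base - mu) / sd
        rhs += ["baseline_mod_z", "time_years:baseline_mod_z"]
        wanted["baseline_mod_z"] = f"{baseline_interaction}_baseline"
        wanted["time_years:baseline_mod_z"] = f"time:{baseline_interaction}_baseline"
    if config.ventricle_adjust:
        rhs.append("nlvv_z")

    formula = f"{outcome}_z ~ {' + '.join(rhs)}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=df, groups=df["subject_id"])
        fit = model.fit(reml=False)
    if getattr(fit, "converged", True) is False:
        logger.warning("mixed model for %s did not fully converge", outcome)
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    if re_var <= 1e-8:
        logger.warning("singular random-intercept variance for %s; "
                       "fit retained", outcome)

    results = []
    ci = fit.conf_int()
    for key, label in wanted.items():
        results.append(ModelResult(
            term=label, beta_std=float(fit.params[key]),
            se=float(fit.bse[key]), ci_lo=float(ci.loc[key, 0]),
            ci_hi=float(ci.loc[key, 1]), p=float(fit.pvalues[key]),
        ))
    return results


def stepwise_select(table: pd.DataFrame, outcome: str, candidates,
                    covariates=DEFAULT_COVARIATES,
                    config: AnalysisConfig | None = None
                    ) -> list[ModelResult]:
    """Bidirectional p-value stepwise selection over candidate predictors.

    Enter if p < enter_p (most significant first), remove if p > remove_p;
    the adjustment covariates are always retained.  Returns the selected
    candidates' results from the final model (empty list if none survive).
    """
    config = config or AnalysisConfig()
    candidates = list(candidates)
    covariates = tuple(covariates)
    df = table[table["visit"] == 0] if "visit" in table.columns else table
    cols = list(dict.fromkeys([outcome, *candidates, *covariates]))
    df = df[cols].dropna()
    df = standardize_columns(df, [c for c in cols if _is_continuous(df[c])],
                             anchor=df)
    cov_terms = _covariate_terms(df, covariates)

    def _fit(included):
        rhs = [c + "_z" for c in included] + cov_terms
        return smf.ols(f"{outcome}_z ~ {' + '.join(rhs) if rhs else '1'}",
                       data=df).fit()

    included: list[str] = []
    changed = True
    while changed:
        changed = False
        # forward: scan excluded candidates by ascending p in the enlarged model
        trial_p = {}
        for c in candidates:
            if c in included:
                continue
            res = _fit(included + [c])
            trial_p[c] = float(res.pvalues[c + "_z"])
        if trial_p:
            best = min(sorted(trial_p), key=lambda c: trial_p[c])
            if trial_p[best] < config.stepwise_enter_p:
                included.append(best)
                changed = True
        # backward: drop the worst included candidate above remove_p
        if included:
            res = _fit(included)
            pvals = {c: float(res.pvalues[c + "_z"]) for c in included}
            worst = max(sorted(pvals), key=lambda c: pvals[c])
            if pvals[worst] > config.stepwise_remove_p:
                included.remove(worst)
                changed = True

    if not included:
        return []
    res = _fit(included)
    _check_rank(res)
    out = []
    for c in included:
        term = c + "_z"
        lo, hi = res.conf_int().loc[term]
        out.append(ModelResult(
            term=c, beta_std=float(res.params[term]), se=float(res.bse[term]),
            ci_lo=float(lo), ci_hi=float(hi), p=float(res.pvalues[term]),
            adj_r2=float(res.rsquared_adj),
        ))
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adj_(i) = min_(j>=i) p_(j) * m / j`` over the ascending order
    statistics, capped at 1, returned in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _attach_fdr(results: list[ModelResult]) -> None:
    if not results:
        return
    adj = bh_fdr([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_fdr = float(a)


def run_associations(table: pd.DataFrame,
                     config: AnalysisConfig | None = None,
                     tables=("chp_time", "cross_sectional", "stepwise",
                             "mri_longitudinal", "clinical_longitudinal"),
                     ) -> dict:
    """Drive the full association analysis over one cohort table.

    Mirrors the study's reporting layout: baseline cross-sectional
    associations of ChP measures with MRI outcomes, multivariable stepwise
    models for clinical scores, and mixed-model time / baseline x time
    analyses for MRI and clinical outcomes.  BH-FDR is applied within each
    results family (one family per table); stepwise results are exempt.
    """
    config = config or AnalysisConfig()
    out: dict = {"config": {
        "covariates": list(config.covariates),
        "fdr_q": config.fdr_q,
        "ventricle_adjust": config.ventricle_adjust,
        "fdr_families": "one per results table",
    }}

    if "chp_time" in tables:
        fam = []
        block = {}
        for oc in ("nchpv", "t1t2"):
            res = fit_longitudinal(table, oc, config.covariates, config=config)
            block[oc] = [r.to_dict() for r in res]
            fam.extend(res)
        _attach_fdr(fam)
        # refresh dicts with FDR-adjusted values
        i = 0
        for oc in ("nchpv", "t1t2"):
            for d in block[oc]:
                d["p_fdr"] = fam[i].p_fdr
                i += 1
        out["chp_time"] = block

    if "cross_sectional" in tables:
        fam = []
        block = {}
        for pred in ("nchpv", "t1t2"):
            block[pred] = {}
            for oc in MRI_OUTCOMES:
                r = fit_cross_sectional(table, oc, pred, config.covariates,
                                        config=config)
                fam.append(r)
                block[pred][oc] = r.to_dict()
        _attach_fdr(fam)
        i = 0
        for pred in ("nchpv", "t1t2"):
            for oc in MRI_OUTCOMES:
                block[pred][oc]["p_fdr"] = fam[i].p_fdr
                i += 1
        out["cross_sectional"] = block

    if "stepwise" in tables:
        block = {}
        mri_vars = ("nchpv", "t1t2", "lesion_ml", "nbv", "ncgmv", "ndgmv",
                    "nwmv")
        for oc in CLINICAL_OUTCOMES:
            sel = stepwise_select(table, oc, mri_vars, config.covariates,
                                  config=config)
            block[oc] = [r.to_dict() for r in sel]
        out["stepwise"] = block

    if "mri_longitudinal" in tables:
        fam = []
        block = {}
        for oc in MRI_OUTCOMES:
            entry = {}
            res_t = fit_longitudinal(table, oc, config.covariates,
                                     config=config)
            entry["time"] = res_t[0].to_dict()
            fam.append(res_t[0])
            for mod in ("nchpv", "t1t2"):
                res_i = fit_longitudinal(table, oc, config.covariates,
                                         baseline_interaction=mod,
                                         config=config)
                inter = res_i[-1]
                entry[f"time_x_baseline_{mod}"] = inter.to_dict()
                fam.append(inter)
            block[oc] = entry
        _attach_fdr(fam)
        i = 0
        for oc in MRI_OUTCOMES:
            for key in ("time", "time_x_baseline_nchpv", "time_x_baseline_t1t2"):
                block[oc][key]["p_fdr"] = fam[i].p_fdr
                i += 1
        out["mri_longitudinal"] = block

    if "clinical_longitudinal" in tables:
        fam = []
        block = {}
        for oc in CLINICAL_OUTCOMES:
            entry = {}
            res_t = fit_longitudinal(table, oc, config.covariates,
                                     config=config)
            entry["time"] = res_t[0].to_dict()
            fam.append(res_t[0])
            for mod in ("nchpv", "t1t2"):
                res_i = fit_longitudinal(table, oc, config.covariates,
                                         baseline_interaction=mod,
                                         config=config)
                inter = res_i[-1]
                entry[f"time_x_baseline_{mod}"] = inter.to_dict()
                fam.append(inter)
            block[oc] = entry
        _attach_fdr(fam)
        i = 0
        for oc in CLINICAL_OUTCOMES:
            for key in ("time", "time_x_baseline_nchpv", "time_x_baseline_t1t2"):
                block[oc][key]["p_fdr"] = fam[i].p_fdr
                i += 1
        out["clinical_longitudinal"] = block

    return out
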