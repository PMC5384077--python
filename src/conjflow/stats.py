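"""Group comparisons across retinopathy stages.

Two granularities, as in the analysis protocol: one-way ANOVA on
per-subject mean descriptors, and Gaussian linear mixed models on
vessel-level rows with a random intercept per subject (fitted by REML, Wald
95% CIs and two-sided P-values, significance at P <= 0.05).  Unadjusted
models carry only the stage factor (reference group C); adjusted models add
age, race, sex, MAP, HR, HCT and HbA1c as fixed effects.  The V-on-D
association is fitted per group via a group x D interaction; per-group
slopes are reported in 1/s (V in mm/s per D in um, scaled by 1000) with a
Wald interaction test against the control group's slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .config import StatsConfig

GROUP_ORDER = ("C", "NDR", "NPDR", "PDR")


@dataclass
class ModelResult:
    """Fixed effects of one descriptor/model fit."""

    descriptor: str
    model_tag: str                      # "unadjusted" | "adjusted"
    intercept: float
    group_effects: pd.DataFrame         # index: group; beta, ci_low, ci_high, p
    covariate_effects: pd.DataFrame | None
    random_intercept_var: float
    residual_var: float
    n_subjects: int
    n_vessels: int
    converged: bool = True
    warnings: list = field(default_factory=list)


@dataclass
class SlopeResult:
    """Per-group V-on-D slope (1/s) with comparison to control."""

    group: str
    slope: float
    ci_low: float
    ci_high: float
    p_slope: float
    p_vs_control: float | None
    model_tag: str


def _check_table(df: pd.DataFrame, descriptor: str) -> None:
    for col in ("subject_id", "group", descriptor):
        if col not in df.columns:
            raise ValueError(f"vessel table missing column {col!r}")


def group_anova(vessels: pd.DataFrame, descriptor: str):
    """One-way ANOVA across groups on per-subject mean descriptors.

    Returns ``(p_value, summary)`` where summary has one row per group with
    subject count, vessel count, and the mean +/- SD of per-subject means.
    """
    _check_table(vessels, descriptor)
    per_subject = (vessels.groupby(["group", "subject_id"], observed=True)[descriptor]
                   .mean().reset_index())
    groups = [g for g in GROUP_ORDER if g in set(per_subject["group"])]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    samples = []
    for g in groups:
        x = per_subject.loc[per_subject["group"] == g, descriptor].to_numpy()
        if len(x) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        samples.append(x)
    _, p = sps.f_oneway(*samples)
    summary = pd.DataFrame({
        "group": groups,
        "n_subjects": [len(s) for s in samples],
        "n_vessels": [int((vessels["group"] == g).sum()) for g in groups],
        "mean": [s.mean() for s in samples],
        "sd": [s.std(ddof=1) for s in samples],
    }).set_index("group")
    return float(p), summary


def _prepare(df: pd.DataFrame, descriptor: str, adjusted: bool,
             cfg: StatsConfig):
    df = df.copy()
    needed = ["subject_id", "group", descriptor]
    if adjusted:
        needed += [c for c in cfg.covariates if c != "group"]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValueError(f"vessel table missing columns {missing_cols}")
    n0 = len(df)
    df = df.dropna(subset=needed)
    n_dropped = n0 - len(df)
    # categorical covariates: largest observed level as reference
    for cat in ("race", "sex"):
        if adjusted and cat in cfg.covariates and cat in df.columns:
            ref = df[cat].value_counts().idxmax()
            levels = [ref] + sorted(x for x in df[cat].unique() if x != ref)
            df[cat] = pd.Categorical(df[cat], categories=levels)
    return df, n_dropped


def _formula(descriptor: str, adjusted: bool, cfg: StatsConfig,
             interaction_with: str | None = None) -> str:
    group_term = f"C(group, Treatment('{cfg.reference_group}'))"
    if interaction_with:
        rhs = [f"{interaction_with} * {group_term}"]
    else:
        rhs = [group_term]
    if adjusted:
        for cov in cfg.covariates:
            if cov in ("race", "sex"):
                rhs.append(f"C({cov})")
            else:
                rhs.append(cov)
    return f"{descriptor} ~ " + " + ".join(rhs)


def _fit_mixedlm(formula: str, df: pd.DataFrame):
    """REML random-intercept fit with an OLS fallback for singular designs."""
    warns: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            model = smf.mixedlm(formula, df, groups=df["subject_id"])
            fit = model.fit(reml=True)
            singular = not np.isfinite(fit.params).all()
        except (np.linalg.LinAlgError, ValueError):
            fit, singular = None, True
        warns = [str(w.message) for w in caught]
    if fit is None or singular:
        ols = smf.ols(formula, df).fit()
        warns.append("mixed-model fit singular; fell back to ordinary regression")
        return ols, 0.0, float(ols.mse_resid), warns, False
    re_var = float(np.asarray(fit.cov_re)[0, 0]) if fit.cov_re.size else 0.0
    return fit, re_var, float(fit.scale), warns, True


def fit_mixed_model(vessels: pd.DataFrame, descriptor: str,
                    adjusted: bool = False,
                    cfg: StatsConfig | None = None) -> ModelResult:
    """Random-intercept linear mixed model of one descriptor on DR stage."""
    cfg = cfg or StatsConfig()
    _check_table(vessels, descriptor)
    df, n_dropped = _prepare(vessels, descriptor, adjusted, cfg)
    if cfg.reference_group not in set(df["group"]):
        raise ValueError(f"reference group {cfg.reference_group!r} absent")

    formula = _formula(descriptor, adjusted, cfg)
    fit, re_var, resid_var, warns, mixed = _fit_mixedlm(formula, df)
    if n_dropped:
        warns.append(f"dropped {n_dropped} rows with missing values")

    params = fit.params
    ci = fit.conf_int()
    pvals = fit.pvalues

    group_rows, cov_rows = {}, {}
    for name in params.index:
        if name in ("Group Var", "groups Var"):
            continue
        entry = {"beta": float(params[name]), "ci_low": float(ci.loc[name, 0]),
                 "ci_high": float(ci.loc[name, 1]), "p": float(pvals[name])}
        if name.startswith("C(group"):
            grp = name.split("[T.")[1].rstrip("]")
            group_rows[grp] = entry
        elif name != "Intercept":
            cov_rows[name] = entry

    return ModelResult(
        descriptor=descriptor,
        model_tag="adjusted" if adjusted else "unadjusted",
        intercept=float(params.get("Intercept", np.nan)),
        group_effects=pd.DataFrame(group_rows).T,
        covariate_effects=pd.DataFrame(cov_rows).T if cov_rows else None,
        random_intercept_var=re_var,
        residual_var=resid_var,
        n_subjects=df["subject_id"].nunique(),
        n_vessels=len(df),
        converged=mixed,
        warnings=warns,
    )


def velocity_diameter_slopes(vessels: pd.DataFrame, adjusted: bool = False,
                             cfg: StatsConfig | None = None,
                             velocity: str = "V",
                             diameter: str = "D") -> list[SlopeResult]:
    """Per-group slope of V on D from a group x D interaction mixed model.

    Slopes are reported in 1/s (mm/s per um x 1000).  The control group's
    ``p_vs_control`` is None; other groups carry the Wald P-value of their
    interaction term (difference in slope from control).
    """
    cfg = cfg or StatsConfig()
    _check_table(vessels, velocity)
    if diameter not in vessels.columns:
        raise ValueError(f"vessel table missing column {diameter!r}")
    if np.ptp(vessels[diameter].to_numpy()) <= 1e-12:
        raise ValueError("no diameter variation")
    df, _ = _prepare(vessels, velocity, adjusted, cfg)
    if diameter in cfg.covariates:
        raise ValueError("diameter cannot be both regressor and covariate")
    df = df.dropna(subset=[diameter])

    formula = _formula(velocity, adjusted, cfg, interaction_with=diameter)
    fit, _, _, _, _ = _fit_mixedlm(formula, df)
    params = fit.params
    cov = fit.cov_params()
    if "Group Var" in params.index:
        keep = [n for n in params.index if n != "Group Var"]
        params = params[keep]
        cov = cov.loc[keep, keep]

    zcrit = sps.norm.ppf(1 - cfg.alpha / 2)
    base = diameter
    results = []
    groups = [g for g in GROUP_ORDER if g in set(df["group"])]
    for g in groups:
        inter = f"{base}:C(group, Treatment('{cfg.reference_group}'))[T.{g}]"
        if g == cfg.reference_group:
            est = params[base]
            var = cov.loc[base, base]
            p_vs = None
        else:
            est = params[base] + params[inter]
            var = (cov.loc[base, base] + cov.loc[inter, inter]
                   + 2 * cov.loc[base, inter])
            p_vs = float(fit.pvalues[inter])
        se = np.sqrt(max(var, 0.0))
        z = est / se if se > 0 else np.inf
        results.append(SlopeResult(
            group=g,
            slope=float(est * 1000.0),
            ci_low=float((est - zcrit * se) * 1000.0),
            ci_high=float((est + zcrit * se) * 1000.0),
            p_slope=float(2 * sps.norm.sf(abs(z))),
            p_vs_control=p_vs,
            model_tag="adjusted" if adjusted else "unadjusted",
        ))
    return results


def model_result_frame(results: list[ModelResult]) -> pd.DataFrame:
    """Flatten ModelResults into a tidy beta/CI/P table."""
    rows = []
    for r in results:
        for grp, row in r.group_effects.iterrows():
            rows.append({"descriptor": r.descriptor, "model": r.model_tag,
                         "group": grp, **row.to_dict()})
    return pd.DataFrame(rows)


def slope_result_frame(results: list[SlopeResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
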