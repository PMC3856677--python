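"""Mixed-effects analysis of breathing-cycle parameters.

The condition analysis fits a linear mixed model with Condition, Order
and Reader (plus their interactions) as fixed factors and crossed random
intercepts for Listener and Text; the trial-progression analysis fits,
within each Reader × Order split, Trial (levels 1, 5, 6, 10) as a fixed
factor with a Listener random intercept and tests the 1–5, 5–6 and 6–10
pairwise contrasts.

statsmodels' MixedLM has no native crossed-grouping interface, so the
crossed intercepts are expressed as variance components on a single
all-encompassing group — algebraically the same model.  Term p-values
default to a seeded parametric bootstrap: responses are simulated from
the fitted null (intercept + random effects + residual), the full model
is refit on each replicate, and the observed |t| of each fixed term is
ranked in its null distribution.  Asymptotic Wald p-values are available
via ``p_method="wald"`` when speed matters.  Treatment coding uses the
normal condition, normal-first order and female reader as references.

When residuals of a duration model stray from normality (quantile–quantile
correlation below threshold) the response is log-transformed, mirroring
standard practice for positive, right-skewed durations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sstats

from .types import ParameterError

__all__ = [
    "ModelSpec",
    "ModelFit",
    "DesignError",
    "TransformError",
    "fit_condition_model",
    "check_residuals_and_transform",
    "progression_contrasts",
    "summarize_by_condition",
    "drop_flagged",
]

QQ_CORR_THRESHOLD = 0.98

_REFERENCES = {"condition": "N", "reader": "F"}


class DesignError(ValueError):
    """Design matrix unusable (missing levels, rank deficiency)."""


class TransformError(ValueError):
    """Requested transform incompatible with the response values."""


@dataclass
class ModelSpec:
    """What to fit: response, fixed factors, random intercepts, transform."""

    response: str = "durC"
    fixed: tuple[str, ...] = ("condition", "order", "reader")
    interactions: bool = True
    random: tuple[str, ...] = ("listener", "text")
    transform: str = "none"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ParameterError(f"alpha must be in (0,1), got {self.alpha}")
        if self.transform not in ("none", "log"):
            raise ParameterError(f"unknown transform {self.transform!r}")


@dataclass
class ModelFit:
    """Fitted fixed terms with Wald and (optionally) resampled p-values."""

    terms: list[str]
    estimates: pd.Series
    t_values: pd.Series
    wald_p: pd.Series
    resampled_p: pd.Series | None
    n_resamples: int
    transform_applied: str
    qq_corr: float
    converged: bool

    def p(self, term: str) -> float:
        """Preferred p-value for a term: resampled when available."""
        if self.resampled_p is not None and term in self.resampled_p.index:
            return float(self.resampled_p[term])
        return float(self.wald_p[term])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            dict(
                term=self.terms,
                estimate=self.estimates.values,
                t=self.t_values.values,
                p_wald=self.wald_p.values,
            )
        )
        df["p_resampled"] = (
            self.resampled_p.reindex(self.terms).values
            if self.resampled_p is not None
            else np.nan
        )
        df["n_resamples"] = self.n_resamples
        df["transform"] = self.transform_applied
        return df


def drop_flagged(table: pd.DataFrame) -> pd.DataFrame:
    """Remove artifact- and outlier-flagged cycles from an analysis table."""
    if "flags" not in table.columns:
        return table
    bad = table["flags"].fillna("").str.contains("artifact|outlier", regex=True)
    return table.loc[~bad]


def _factor(col: str) -> str:
    ref = _REFERENCES.get(col)
    if ref is not None:
        return f"C({col}, Treatment('{ref}'))"
    return f"C({col})"


def _response_column(table: pd.DataFrame, response: str) -> str:
    if response in table.columns:
        return response
    alias = {"ampI": "ampI_pctMD", "durC": "durC"}
    col = alias.get(response)
    if col and col in table.columns:
        return col
    raise ParameterError(f"response {response!r} not found in table")


def _check_levels(table: pd.DataFrame, factors: tuple[str, ...]) -> None:
    for f in factors:
        if f not in table.columns:
            raise DesignError(f"fixed factor {f!r} missing from table")
        n = table[f].nunique()
        if n < 2:
            raise DesignError(
                f"fixed factor {f!r} has {n} level(s); need at least 2"
            )


def _vc_formula(random: tuple[str, ...]) -> dict[str, str]:
    return {r: f"0 + C({r})" for r in random}


def _fit_crossed(formula: str, data: pd.DataFrame, random: tuple[str, ...]):
    model = smf.mixedlm(
        formula,
        data=data,
        groups=np.ones(len(data)),
        vc_formula=_vc_formula(random),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # lbfgs is fastest; fall back on the occasional numerical failure
        for method, maxiter in (("lbfgs", 200), (None, 200), ("powell", 500)):
            try:
                if method is None:
                    return model, model.fit(reml=True, maxiter=maxiter)
                return model, model.fit(reml=True, method=method, maxiter=maxiter)
            except np.linalg.LinAlgError:
                continue
    raise DesignError("mixed-model fit failed under all optimizers")


def _qq_corr(resid: np.ndarray) -> float:
    (osm, osr), _ = sstats.probplot(np.asarray(resid, dtype=float))
    return float(np.corrcoef(osm, osr)[0, 1])


def _simulate_null(
    rng: np.random.Generator,
    data: pd.DataFrame,
    random: tuple[str, ...],
    intercept: float,
    vcomps: dict[str, float],
    scale: float,
) -> np.ndarray:
    y = np.full(len(data), intercept) + rng.normal(0.0, np.sqrt(scale), len(data))
    for r in random:
        levels = data[r].unique()
        draws = dict(zip(levels, rng.normal(0.0, np.sqrt(max(vcomps[r], 0.0)), len(levels))))
        y += data[r].map(draws).to_numpy()
    return y


def fit_condition_model(
    table: pd.DataFrame,
    spec: ModelSpec | None = None,
    n_resamples: int = 1000,
    seed: int = 0,
    p_method: str = "bootstrap",
) -> ModelFit:
    """Fit the condition/order/reader mixed model on retained cycles.

    Fixed factors (with all interactions when ``spec.interactions``) are
    treatment-coded against the reference levels; Listener and Text enter
    as crossed random intercepts.  With ``p_method="bootstrap"`` each
    fixed term's p-value is its |t| ranked within ``n_resamples`` null
    refits (responses simulated from the intercept + random-effects +
    residual fit); ``"wald"`` reports asymptotic normal p-values only.
    """
    spec = spec or ModelSpec()
    if p_method not in ("bootstrap", "wald"):
        raise ParameterError(f"unknown p_method {p_method!r}")
    data = drop_flagged(table).copy()
    _check_levels(data, spec.fixed)
    resp = _response_column(data, spec.response)
    data = data.rename(columns={resp: "_y"}) if resp != "_y" else data
    if spec.transform == "log":
        if (data["_y"] <= 0).any():
            raise TransformError("log transform requires strictly positive response")
        data["_y"] = np.log(data["_y"])

    op = " * " if spec.interactions else " + "
    formula = "_y ~ " + op.join(_factor(f) for f in spec.fixed)
    model, result = _fit_crossed(formula, data, spec.random)
    fe = result.fe_params
    terms = [t for t in fe.index if t != "Intercept"]
    tvals = result.tvalues[fe.index]
    wald = result.pvalues[fe.index]
    qq = _qq_corr(result.resid)

    resampled = None
    if p_method == "bootstrap":
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x42])
        _, null_fit = _fit_crossed("_y ~ 1", data, spec.random)
        vc_names = list(_vc_formula(spec.random).keys())
        vcomps = dict(zip(vc_names, np.asarray(null_fit.vcomp, dtype=float)))
        intercept = float(null_fit.fe_params["Intercept"])
        scale = float(null_fit.scale)
        obs_t = np.abs(tvals[terms].to_numpy())
        exceed = np.zeros(len(terms))
        n_ok = 0
        sim = data.copy()
        for _ in range(n_resamples):
            sim["_y"] = _simulate_null(
                rng, data, spec.random, intercept, vcomps, scale
            )
            try:
                _, rfit = _fit_crossed(formula, sim, spec.random)
            except Exception:
                continue
            null_t = np.abs(rfit.tvalues[fe.index][terms].to_numpy())
            exceed += null_t >= obs_t
            n_ok += 1
        if n_ok == 0:
            raise DesignError("all bootstrap refits failed")
        resampled = pd.Series((1.0 + exceed) / (1.0 + n_ok), index=terms)

    return ModelFit(
        terms=list(fe.index),
        estimates=fe,
        t_values=tvals,
        wald_p=wald,
        resampled_p=resampled,
        n_resamples=n_resamples if p_method == "bootstrap" else 0,
        transform_applied=spec.transform,
        qq_corr=qq,
        converged=bool(result.converged),
    )


def check_residuals_and_transform(
    table: pd.DataFrame, spec: ModelSpec | None = None
) -> ModelSpec:
    """Decide whether the response needs a log transform.

    Fits the untransformed model and correlates ordered residuals with
    normal quantiles; below ``QQ_CORR_THRESHOLD`` the returned spec has
    ``transform="log"`` (requiring a strictly positive response).
    """
    from dataclasses import replace

    spec = spec or ModelSpec()
    fit = fit_condition_model(table, replace(spec, transform="none"), p_method="wald")
    if fit.qq_corr >= QQ_CORR_THRESHOLD:
        return replace(spec, transform="none")
    data = drop_flagged(table)
    resp = _response_column(data, spec.response)
    if (data[resp] <= 0).any():
        raise TransformError(
            "residual diagnostic failed but response has non-positive values; "
            "cannot log-transform"
        )
    return replace(spec, transform="log")


def progression_contrasts(
    table: pd.DataFrame,
    pairs: tuple[tuple[int, int], ...] = ((1, 5), (5, 6), (6, 10)),
    split_by: tuple[str, ...] = ("reader", "order"),
    response: str = "durC",
    seed: int = 0,
    p_method: str = "wald",
    n_resamples: int = 1000,
    aggregate: bool = True,
) -> pd.DataFrame:
    """Trial-progression contrasts within Reader × Order splits.

    Within each split, a mixed model with Trial (the levels appearing in
    ``pairs``) as fixed factor and Listener as random intercept; each pair
    (a, b) is tested as the difference of the level-b and level-a
    coefficients.  1 vs 5 probes adaptation over the first condition,
    5 vs 6 the reset at the condition change, 6 vs 10 adaptation over the
    second condition.  Splits missing a trial level skip the affected
    pairs (with a warning); ``split_by=()`` pools everything into one fit.

    ``aggregate`` (default) first averages cycles to one value per
    listener and trial: cycles within a trial share the trial's text and
    state, so cycle-level fits would overstate the effective sample size.
    """
    levels = sorted({t for p in pairs for t in p})
    data = drop_flagged(table)
    resp = _response_column(data, response)
    if aggregate:
        keys_agg = [*split_by, "listener", "trial_index"]
        data = data.groupby(keys_agg, as_index=False)[resp].mean()
    rows = []
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x77])
    grouped = (
        data.groupby(list(split_by)) if split_by else [((), data)]
    )
    for keys, grp in grouped:
        keys = keys if isinstance(keys, tuple) else (keys,)
        sub = grp[grp["trial_index"].isin(levels)].copy()
        present = set(sub["trial_index"].unique())
        usable_pairs = [p for p in pairs if set(p) <= present]
        skipped = [p for p in pairs if p not in usable_pairs]
        if skipped:
            warnings.warn(f"split {keys}: missing trial levels, skipping {skipped}")
        if not usable_pairs:
            continue
        sub["_y"] = sub[resp].astype(float)
        cat_levels = sorted(present & set(levels))
        sub["_trial"] = pd.Categorical(sub["trial_index"], categories=cat_levels)
        model = smf.mixedlm("_y ~ C(_trial)", data=sub, groups=sub["listener"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = model.fit(reml=True, maxiter=200)
            except np.linalg.LinAlgError:
                fit = model.fit(reml=True, method="powell", maxiter=500)
        est, se, zval = _pair_contrasts(fit, cat_levels, usable_pairs)
        pvals = 2.0 * sstats.norm.sf(np.abs(zval))
        if p_method == "bootstrap":
            pvals = _bootstrap_contrast_p(
                rng, sub, cat_levels, usable_pairs, fit, zval, n_resamples
            )
        for (a, b), e, s, z, p in zip(usable_pairs, est, se, zval, pvals):
            rows.append(
                dict(
                    **dict(zip(split_by, keys)),
                    pair=f"{a}:{b}",
                    estimate=e,
                    se=s,
                    t=z,
                    p=p,
                    n=len(sub),
                )
            )
    return pd.DataFrame(rows)


def _coef_name(level, levels) -> str | None:
    if level == levels[0]:
        return None  # reference level
    return f"C(_trial)[T.{level}]"


def _pair_contrasts(fit, levels, pairs):
    names = list(fit.fe_params.index)
    cov = np.asarray(fit.cov_params())[: len(names), : len(names)]
    est, se, z = [], [], []
    for a, b in pairs:
        vec = np.zeros(len(names))
        for lvl, sign in ((b, 1.0), (a, -1.0)):
            cn = _coef_name(lvl, levels)
            if cn is not None:
                vec[names.index(cn)] += sign
        e = float(vec @ fit.fe_params.to_numpy())
        s = float(np.sqrt(vec @ cov @ vec))
        est.append(e)
        se.append(s)
        z.append(e / s if s > 0 else np.nan)
    return np.array(est), np.array(se), np.array(z)


def _bootstrap_contrast_p(rng, sub, levels, pairs, fit, obs_z, n_resamples):
    """Null z-distributions for the pairwise contrasts, by simulation from
    the intercept + listener-intercept + residual fit."""
    var_listener = float(np.asarray(fit.cov_re)[0, 0])
    scale = float(fit.scale)
    intercept = float(fit.fe_params["Intercept"])
    listeners = sub["listener"].unique()
    exceed = np.zeros(len(pairs))
    n_ok = 0
    sim = sub.copy()
    for _ in range(n_resamples):
        draws = dict(zip(listeners, rng.normal(0, np.sqrt(max(var_listener, 0)), len(listeners))))
        sim["_y"] = (
            intercept
            + sub["listener"].map(draws).to_numpy()
            + rng.normal(0, np.sqrt(scale), len(sub))
        )
        model = smf.mixedlm("_y ~ C(_trial)", data=sim, groups=sim["listener"])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rfit = model.fit(reml=True, maxiter=200)
        except Exception:
            continue
        _, _, z = _pair_contrasts(rfit, levels, pairs)
        exceed += np.abs(z) >= np.abs(obs_z)
        n_ok += 1
    if n_ok == 0:
        return np.full(len(pairs), np.nan)
    return (1.0 + exceed) / (1.0 + n_ok)


def summarize_by_condition(
    table: pd.DataFrame,
    group_by: tuple[str, ...] = ("condition", "order", "reader"),
    values: tuple[str, ...] = ("durC", "ampI"),
) -> pd.DataFrame:
    """Group means with standard errors and counts.

    SE is undefined (NaN) for single-observation groups.  Columns present
    in the table but absent from ``values`` (e.g. rSyll for readers) can
    be added by the caller.
    """
    if len(table) == 0:
        raise ParameterError("empty table")
    data = drop_flagged(table)
    cols = [_response_column(data, v) for v in values]
    rows = []
    for keys, grp in data.groupby(list(group_by)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        row = dict(zip(group_by, keys))
        row["n"] = len(grp)
        for v, c in zip(values, cols):
            x = grp[c].to_numpy(dtype=float)
            row[f"{v}_mean"] = float(np.mean(x))
            row[f"{v}_se"] = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
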