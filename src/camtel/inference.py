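"""Detection models and information-theoretic model selection.

The scientific question is whether camera detections are proportional to
telemetry-based space use. The linear predictor for observation i is

    eta_i = beta_Sex,i + beta_UD * log(UD_i) [+ other terms] [+ offsets]

so the capture rate is lambda_i = exp(beta_Sex,i) * UD_i ** beta_UD and,
through the complementary log-log link, the probability of at least one
capture over exposure T is pi_i = 1 - exp(-lambda_i * T). The *simple
model* forces beta_UD = 1 by moving log(UD) into an offset; comparing the
offset fit with a free-exponent fit is the proportionality test.

GLMs are fit by iteratively reweighted least squares (via statsmodels);
quasi-variants share the same point estimates with Pearson-scaled
standard errors; random-intercept GLMMs come from the Laplace machinery
in :mod:`camtel.glmm`. Model comparison uses AIC/AICc/QAICc with Akaike
weights, and conditional R^2 (fixed + random variance over total latent
variance) summarizes mixed fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats

from .glmm import fit_glmm_arrays

__all__ = [
    "ModelSpec",
    "FitResult",
    "prepare_design_frame",
    "fit_glm",
    "fit_glmm",
    "fit_model",
    "quasi_dispersion",
    "information_criteria",
    "selection_table",
    "conditional_r2",
    "likelihood_ratio_test",
    "offset_consistency_check",
]

_LINKS = {
    "cloglog": sm.families.links.CLogLog,
    "logit": sm.families.links.Logit,
    "log": sm.families.links.Log,
}

VALID_RANDOM = ("Fisher", "Camera", "Fisher/Camera")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model.

    terms is a patsy-style fixed-effects formula over the vocabulary
    Sex, Season, NLocs250, NLocs500, logUD, Isopleth (isopleth
    percentile / 100), Core (0/1); "1" for intercept-only.
    offset_log_ud forces a unit coefficient on log(UD) into the linear
    predictor; exposure_offset adds log(exposure_days) the same way.
    random lists random-intercept factors ("Fisher", "Camera",
    "Fisher/Camera" for animal-within-camera pairs).
    """

    response: str = "binary"  # binary | count
    link: str = "cloglog"
    family: str = "binomial"  # binomial|quasibinomial|poisson|quasipoisson
    terms: str = "1"
    offset_log_ud: bool = False
    exposure_offset: bool = True
    random: tuple[str, ...] = ()
    label: str | None = None

    def __post_init__(self) -> None:
        if self.response not in ("binary", "count"):
            raise ValueError(f"bad response {self.response!r}")
        if self.response == "binary" and self.link not in ("cloglog", "logit"):
            raise ValueError("binary response needs cloglog or logit link")
        if self.response == "count" and self.link != "log":
            raise ValueError("count response needs log link")
        fam_ok = (
            ("binomial", "quasibinomial")
            if self.response == "binary"
            else ("poisson", "quasipoisson")
        )
        if self.family not in fam_ok:
            raise ValueError(f"family {self.family!r} invalid for {self.response}")
        if self.offset_log_ud and "logUD" in self.terms.replace(" ", "").split("+"):
            raise ValueError("logUD cannot be both free term and offset")
        if self.is_quasi and self.random:
            raise ValueError("quasi families cannot carry random effects")
        for r in self.random:
            if r not in VALID_RANDOM:
                raise ValueError(f"unknown random factor {r!r}")

    @property
    def is_quasi(self) -> bool:
        return self.family.startswith("quasi")

    @property
    def is_mixed(self) -> bool:
        return bool(self.random)

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        parts = [self.terms]
        if self.offset_log_ud:
            parts.append("offset(logUD)")
        s = " + ".join(parts)
        if self.random:
            s += " + " + " + ".join(f"[1|{r}]" for r in self.random)
        return s


@dataclass
class FitResult:
    """A fitted detection model.

    llf is the (approximate, for mixed models) maximized log-likelihood
    of the underlying non-quasi family; K counts every estimated
    quantity: fixed coefficients plus one per random-effect variance
    (the quasi dispersion is added inside QAICc, not here).
    """

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    llf: float
    deviance: float
    pearson_chi2: float
    df_resid: int
    n: int
    K: int
    eta: np.ndarray
    fitted: np.ndarray
    converged: bool
    re_var: dict[str, float] = field(default_factory=dict)
    boundary: bool = False
    dispersion: float | None = None  # Pearson chi2 / df
    eta_fixed: np.ndarray | None = None  # X beta + offsets, random modes excluded
    cov_params: np.ndarray | None = None

    @property
    def is_mixed(self) -> bool:
        return bool(self.re_var)


def prepare_design_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Map an encounter table to the modelling vocabulary.

    Adds Sex/Season categoricals, NLocs counts, logUD, Isopleth scaled to
    [0, 1] and Core as 0/1, whichever inputs are present.
    """
    df = pd.DataFrame(index=table.index)
    df["Sex"] = table["sex"].astype(str)
    if "season" in table:
        df["Season"] = table["season"].astype(str)
    for col, name in (("n_locs_250", "NLocs250"), ("n_locs_500", "NLocs500")):
        if col in table:
            df[name] = table[col].astype(float)
    if "ud" in table:
        if (table["ud"] <= 0).any():
            raise ValueError(
                f"{int((table['ud'] <= 0).sum())} rows have non-positive UD; "
                "drop them before fitting log(UD) models"
            )
        df["logUD"] = np.log(table["ud"].astype(float))
    if "isopleth_pct" in table:
        df["Isopleth"] = table["isopleth_pct"].astype(float) / 100.0
    if "core" in table:
        df["Core"] = table["core"].astype(int)
    df["_exposure"] = table["exposure_days"].astype(float)
    df["_animal"] = table["animal_id"].astype(str)
    if "camera_id" in table:
        df["_camera"] = table["camera_id"].astype(str)
        df["_pair"] = df["_animal"] + ":" + df["_camera"]
    df["_detected"] = table["detected"].astype(float)
    if "photo_count" in table:
        df["_count"] = table["photo_count"].astype(float)
    elif "count" in table:
        df["_count"] = table["count"].astype(float)
    return df


def _design(table: pd.DataFrame, spec: ModelSpec):
    df = prepare_design_frame(table)
    y = (df["_detected"] if spec.response == "binary" else df["_count"]).to_numpy()
    X = patsy.dmatrix(spec.terms, df, return_type="dataframe")
    offset = np.zeros(len(df))
    if spec.offset_log_ud:
        offset = offset + df["logUD"].to_numpy()
    if spec.exposure_offset:
        offset = offset + np.log(df["_exposure"].to_numpy())
    return y, X, offset, df


def _family(spec: ModelSpec):
    link = _LINKS[spec.link]()
    if spec.response == "binary":
        return sm.families.Binomial(link=link)
    return sm.families.Poisson(link=link)


def fit_glm(table: pd.DataFrame, spec: ModelSpec, c_hat: float | None = None) -> FitResult:
    """Fit a fixed-effects GLM (IRLS) for one candidate model.

    For quasi families the point estimates are those of the parent
    binomial/Poisson fit and standard errors are scaled by sqrt(c_hat)
    (Pearson dispersion of this fit when `c_hat` is not supplied).
    """
    if spec.is_mixed:
        raise ValueError("spec has random terms; use fit_glmm")
    y, X, offset, _ = _design(table, spec)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"design matrix rank-deficient for model {spec.name!r}")
    model = sm.GLM(y, X, family=_family(spec), offset=offset)
    res = model.fit(maxiter=100, tol=1e-10, scale=1.0)
    converged = bool(res.converged)
    eta = np.asarray(model.predict(res.params, which="linear"))
    if np.max(np.abs(eta)) > 30:
        import logging

        logging.getLogger(__name__).warning(
            "possible separation in %s: |eta| up to %.1f", spec.name, np.max(np.abs(eta))
        )
    disp = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else np.nan
    bse = res.bse
    if spec.is_quasi:
        scale = c_hat if c_hat is not None else max(disp, 1.0)
        bse = bse * math.sqrt(scale)
    return FitResult(
        spec=spec,
        params=pd.Series(res.params, index=X.columns),
        bse=pd.Series(bse, index=X.columns),
        llf=float(res.llf),
        deviance=float(res.deviance),
        pearson_chi2=float(res.pearson_chi2),
        df_resid=int(res.df_resid),
        n=len(y),
        K=X.shape[1],
        eta=eta,
        fitted=np.asarray(res.fittedvalues),
        converged=converged,
        dispersion=disp,
        cov_params=np.asarray(res.cov_params()),
    )


def _group_codes(df: pd.DataFrame, factor: str) -> np.ndarray:
    col = {"Fisher": "_animal", "Camera": "_camera", "Fisher/Camera": "_pair"}[factor]
    return pd.Categorical(df[col]).codes.astype(int)


def fit_glmm(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit a random-intercept GLMM (Laplace ML) for one candidate model.

    "Fisher/Camera" expands to nested intercepts: (1|Fisher) is included
    explicitly in `random` when wanted; the factor itself indexes the
    animal x camera pair.
    """
    if not spec.is_mixed:
        raise ValueError("spec has no random terms; use fit_glm")
    y, X, offset, df = _design(table, spec)
    groups = {r: _group_codes(df, r) for r in spec.random}
    kind = "binomial" if spec.response == "binary" else "poisson"
    fit = fit_glmm_arrays(
        y, X.to_numpy(), groups, kind=kind, link=spec.link, offset=offset
    )
    mu = fit.fitted
    var = mu * (1 - mu) if kind == "binomial" else mu
    pearson = float(np.sum((y - mu) ** 2 / np.clip(var, 1e-12, None)))
    return FitResult(
        spec=spec,
        params=pd.Series(fit.beta, index=X.columns),
        bse=pd.Series(fit.beta_se, index=X.columns),
        llf=fit.loglik,
        deviance=np.nan,
        pearson_chi2=pearson,
        df_resid=len(y) - fit.k,
        n=len(y),
        K=fit.k,
        eta=fit.eta,
        fitted=mu,
        converged=fit.converged,
        re_var={g: s**2 for g, s in fit.re_sd.items()},
        boundary=fit.boundary,
        eta_fixed=X.to_numpy() @ fit.beta + offset,
        cov_params=fit.beta_cov,
    )


def fit_model(table: pd.DataFrame, spec: ModelSpec, c_hat: float | None = None) -> FitResult:
    return fit_glmm(table, spec) if spec.is_mixed else fit_glm(table, spec, c_hat)


def quasi_dispersion(fit: FitResult) -> float:
    """Pearson dispersion c-hat = chi^2 / residual df of a saturated fit.

    Values below 1 are reported as estimated but floored at 1 when used
    in QAICc (underdispersion is not rewarded).
    """
    if not fit.converged:
        raise ValueError("dispersion from a non-converged fit")
    if fit.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    return float(fit.pearson_chi2 / fit.df_resid)


def information_criteria(
    fit: FitResult, criterion: str = "AICc", c_hat: float = 1.0
) -> tuple[float, int]:
    """(criterion value, K) for one fit.

    AIC = -2l + 2K; AICc adds the small-sample correction
    2K(K+1)/(n-K-1); QAICc divides -2l by c-hat and counts c-hat itself
    as a parameter (K includes it in both penalty terms).
    """
    K = fit.K
    n = fit.n
    if criterion == "AIC":
        return -2.0 * fit.llf + 2.0 * K, K
    if criterion == "AICc":
        if n <= K + 1:
            raise ValueError(f"n={n} too small for AICc of {fit.spec.name!r} (K={K})")
        aic = -2.0 * fit.llf + 2.0 * K
        return aic + 2.0 * K * (K + 1) / (n - K - 1), K
    if criterion == "QAICc":
        c = max(float(c_hat), 1.0)
        Kq = K + 1  # c-hat is estimated
        if n <= Kq + 1:
            raise ValueError(f"n={n} too small for QAICc of {fit.spec.name!r}")
        return (
            -2.0 * fit.llf / c + 2.0 * Kq + 2.0 * Kq * (Kq + 1) / (n - Kq - 1),
            Kq,
        )
    raise ValueError(f"unknown criterion {criterion!r}")


def conditional_r2(fit: FitResult) -> float:
    """Nakagawa-Schielzeth conditional R^2 of a mixed fit.

    (var(fixed predictor) + sum of random-intercept variances) over the
    same plus the distribution-specific latent variance: pi^2/3 (logit),
    pi^2/6 (cloglog), ln(1 + 1/mean(fitted)) (Poisson log link,
    lognormal approximation).
    """
    if not fit.is_mixed:
        raise ValueError("conditional R^2 requires a mixed fit")
    if fit.eta_fixed is None:
        raise ValueError("fit carries no fixed-effect predictor")
    var_f = float(np.var(fit.eta_fixed))
    var_r = float(sum(fit.re_var.values()))
    if fit.spec.link == "logit":
        var_d = math.pi**2 / 3.0
    elif fit.spec.link == "cloglog":
        var_d = math.pi**2 / 6.0
    else:  # Poisson log link, lognormal approximation
        lam_bar = float(np.mean(fit.fitted))
        var_d = math.log1p(1.0 / max(lam_bar, 1e-12))
    denom = var_f + var_r + var_d
    return (var_f + var_r) / denom if denom > 0 else 0.0


def likelihood_ratio_test(nested: FitResult, full: FitResult):
    """LRT of a nested fixed-effects model against a fuller one."""
    nt = set(t.strip() for t in nested.spec.terms.split("+"))
    ft = set(t.strip() for t in full.spec.terms.split("+"))
    if not nt.issubset(ft | {"1"}):
        raise ValueError("models are not nested")
    if nested.n != full.n:
        raise ValueError("fits use different rows")
    stat = max(0.0, 2.0 * (full.llf - nested.llf))
    df = full.K - nested.K
    if df <= 0:
        return stat, 0, 1.0
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def selection_table(
    fits: Sequence[FitResult],
    criterion: str = "AICc",
    c_hat: float = 1.0,
) -> pd.DataFrame:
    """Ranked model-selection table with Akaike weights.

    Columns mirror the conventional presentation: Model, K, IC, Delta,
    weight, cumulative weight, and conditional R^2 for mixed rows. Ties
    in Delta break by smaller K then label order.
    """
    if not fits:
        raise ValueError("no fits to rank")
    ns = {f.n for f in fits}
    resp = {f.spec.response for f in fits}
    if len(ns) > 1 or len(resp) > 1:
        raise ValueError("fits mix different rows or responses")
    rows = []
    for f in fits:
        ic, K = information_criteria(f, criterion, c_hat)
        rows.append(
            dict(
                Model=f.spec.name,
                K=K,
                IC=ic,
                R2c=conditional_r2(f) if f.is_mixed else np.nan,
                converged=f.converged,
            )
        )
    df = pd.DataFrame(rows)
    df["Delta"] = df["IC"] - df["IC"].min()
    rel = np.exp(-df["Delta"] / 2.0)
    df["Weight"] = rel / rel.sum()
    df = df.sort_values(
        ["Delta", "K", "Model"], kind="mergesort", ignore_index=True
    )
    df["CumWeight"] = df["Weight"].cumsum()
    df.attrs["criterion"] = criterion
    df.attrs["c_hat"] = c_hat if criterion == "QAICc" else None
    return df[["Model", "K", "IC", "Delta", "Weight", "CumWeight", "R2c", "converged"]]


def offset_consistency_check(
    table: pd.DataFrame, base_terms: str = "Sex", spec_kwargs: dict | None = None
) -> dict:
    """The proportionality test: is the exponent on UD equal to 1?

    Fits the offset model (base_terms + offset(logUD)) and the
    free-exponent model (base_terms + logUD); verifies the definitional
    identity that the free model's likelihood evaluated at exponent 1
    (other coefficients at the offset fit's values) equals the offset
    model's likelihood, and reports the free exponent with its 95% Wald
    interval and the AICc of both fits.
    """
    kw = dict(response="binary", link="cloglog", family="binomial")
    if spec_kwargs:
        kw.update(spec_kwargs)
    spec_off = ModelSpec(terms=base_terms, offset_log_ud=True, **kw)
    spec_free = ModelSpec(terms=base_terms + " + logUD", **kw)
    fit_off = fit_glm(table, spec_off)
    fit_free = fit_glm(table, spec_free)

    # evaluate the free model's log-likelihood at beta_UD = 1 with the
    # offset fit's coefficients: the linear predictors coincide exactly
    y, Xf, offset_free, _ = _design(table, spec_free)
    params = pd.Series(0.0, index=Xf.columns)
    for name, val in fit_off.params.items():
        params[name] = val
    params["logUD"] = 1.0
    eta = Xf.to_numpy() @ params.to_numpy() + offset_free
    fam = _family(spec_free)
    mu = fam.link.inverse(eta)
    ll_at_1 = float(fam.loglike(y, mu))

    b = float(fit_free.params["logUD"])
    se = float(fit_free.bse["logUD"])
    ci = (b - 1.96 * se, b + 1.96 * se)
    return dict(
        beta_ud=b,
        se=se,
        ci=ci,
        covers_one=bool(ci[0] <= 1.0 <= ci[1]),
        llf_offset=fit_off.llf,
        llf_free_at_one=ll_at_1,
        identity_gap=abs(fit_off.llf - ll_at_1),
        aicc_offset=information_criteria(fit_off, "AICc")[0],
        aicc_free=information_criteria(fit_free, "AICc")[0],
        fit_offset=fit_off,
        fit_free=fit_free,
    )
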