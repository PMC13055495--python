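"""Model fitting for the 2x2 factorial design.

Per-date GLMs (negative binomial counts, binomial occurrence, Beta
proportion cover, Gaussian concentrations), bias-reduced logistic fits for
sparse occurrence data, a season-wide penalized additive model with plate
random intercepts, and batched per-gene negative-binomial factorial fits.
Every fit is reduced to the same contract: link-scale intercept, warming and
pollution main effects, their interaction, Wald standard errors and
two-sided normal p-values, with ambient / non-polluted as the reference
levels.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from multistress.firth import firth_logistic
from multistress.season import fit_penalized_additive
from multistress.types import (
    ConfigurationError,
    DegenerateFitError,
    InputError,
    StressorCoefficients,
)

__all__ = [
    "binarize_occurrence",
    "fit_date_glm",
    "fit_firth_logistic",
    "fit_season_model",
    "fit_gene_models",
    "SeasonFit",
]

logger = logging.getLogger(__name__)

_LN2 = math.log(2.0)

#: default family/link per response kind (configurable at every call site)
DEFAULT_FAMILIES = {
    "count_nb": "log",
    "binary": "logit",
    "proportion": "logit",
    "continuous": "identity",
}


def binarize_occurrence(observations: pd.DataFrame, response: str) -> pd.DataFrame:
    """Aggregate one response to binary presence/absence (occurrence).

    Values become 1 when strictly positive, 0 otherwise; all other rows and
    columns are unchanged.  Intended for sparse grazer counts where the high
    frequency of zeros makes count models separate or fail to converge.
    """
    out = observations.copy()
    mask = out["response"] == response
    vals = out.loc[mask, "value"]
    if (vals < 0).any():
        raise InputError(f"negative values in response {response!r}")
    binary = (vals > 0).astype(float)
    if mask.any() and binary.sum() == 0:
        warnings.warn(
            f"response {response!r} is absent everywhere; "
            "an occurrence fit will be degenerate",
            UserWarning,
            stacklevel=2,
        )
    out.loc[mask, "value"] = binary
    return out


def _design(sub: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    w = (sub["warming"] == "warmed").to_numpy(float)
    p = (sub["site"] == "polluted").to_numpy(float)
    X = np.column_stack([np.ones(len(sub)), w, p, w * p])
    return X, sub["value"].to_numpy(float)


def _check_cells(sub: pd.DataFrame, min_per_cell: int = 2) -> None:
    counts = sub.groupby(["site", "warming"], observed=True)["value"].size()
    if len(counts) < 4 or (counts < min_per_cell).any():
        raise DegenerateFitError(
            f"need >= {min_per_cell} observations in every treatment cell"
        )


def _wald(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2.0 * norm.sf(np.abs(beta) / se)


def _pack(response, date_label, link, beta, se, n_obs) -> StressorCoefficients:
    p = _wald(beta[1:4], se[1:4])
    return StressorCoefficients(
        response=response, date_label=str(date_label), link=link,
        alpha=float(beta[0]),
        beta_w=float(beta[1]), beta_p=float(beta[2]), beta_int=float(beta[3]),
        se_w=float(se[1]), se_p=float(se[2]), se_int=float(se[3]),
        p_w=float(p[0]), p_p=float(p[1]), p_int=float(p[2]),
        n_obs=int(n_obs),
    )


def _moment_nb_alpha(y: np.ndarray, mu: np.ndarray, n_params: int = 0) -> float:
    """Method-of-moments NB dispersion, df-corrected for fitted parameters."""
    den = float(np.sum(mu ** 2))
    if den <= 0:
        return 1e-8
    n = len(y)
    infl = n / (n - n_params) if n > n_params else 1.0
    return max(float(np.sum(infl * (y - mu) ** 2 - mu)) / den, 1e-8)


def _t_calibrated_se(beta: np.ndarray, se: np.ndarray, df: int) -> np.ndarray:
    """Scale Wald SEs so the normal reference reproduces t-based p-values.

    With z = |beta|/se, the effective SE is |beta| / Phi^-1(T_df(z)); then
    2(1 - Phi(|beta|/SE_eff)) equals the two-sided t p-value exactly.  Near
    z = 0 the scaling approaches the ratio of the densities at the origin.
    """
    from scipy.stats import t as t_dist

    z = np.abs(beta) / se
    z_eq = norm.isf(np.clip(t_dist.sf(z, df), 1e-300, 0.5))
    limit = norm.pdf(0.0) / t_dist.pdf(0.0, df)  # z -> 0 limit of z/z_eq
    factor = np.where(z > 1e-6, z / np.maximum(z_eq, 1e-12), limit)
    return se * np.maximum(factor, 1.0)


def _small_sample_factor(n: int, k: int) -> float:
    # scale Wald SEs so the normal reference matches the t quantile at the
    # fit's residual df; keeps p = 2(1-Phi(|b|/SE)) while restoring
    # small-sample type-I calibration
    from scipy.stats import t as t_dist

    df = max(n - k, 1)
    return float(t_dist.ppf(0.975, df) / norm.ppf(0.975))


def fit_date_glm(
    observations: pd.DataFrame,
    response: str,
    day: int,
    family: str = "count_nb",
    link: Optional[str] = None,
) -> StressorCoefficients:
    """Fit the 2x2 factorial GLM for one response on one sampling date.

    Families: ``count_nb`` (negative binomial, log link; dispersion by
    method of moments from a Poisson pilot fit), ``binary`` (binomial,
    logit), ``proportion`` (Beta regression, logit mean link), and
    ``continuous`` (Gaussian, identity or log link).  Raises
    :class:`DegenerateFitError` on constant responses, empty cells or
    separation rather than returning silent garbage.
    """
    if family not in DEFAULT_FAMILIES:
        raise ConfigurationError(f"unknown family {family!r}")
    link = link or DEFAULT_FAMILIES[family]
    sub = observations[
        (observations["response"] == response) & (observations["day"] == day)
    ]
    if sub.empty:
        raise InputError(f"no observations for {response!r} on day {day}")
    _check_cells(sub)
    X, y = _design(sub)
    if np.ptp(y) == 0:
        raise DegenerateFitError(
            f"constant response {response!r} on day {day}: zero variance"
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "count_nb":
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            alpha = 1e-8
            for _ in range(4):  # iterate dispersion and mean fits to convergence
                alpha = _moment_nb_alpha(y, res.fittedvalues, X.shape[1])
                res = sm.GLM(
                    y, X, family=sm.families.NegativeBinomial(alpha=alpha)
                ).fit()
            mu = res.fittedvalues
            pearson = float(np.sum((y - mu) ** 2 / (mu + alpha * mu ** 2)))
            overdisp = max(pearson / (len(y) - X.shape[1]), 1.0)
            beta = np.asarray(res.params)
            se = np.asarray(res.bse) * math.sqrt(overdisp) \
                * _small_sample_factor(len(y), X.shape[1])
            return _pack(response, day, "log", beta, se, len(y))
        elif family == "binary":
            if not np.all(np.isin(y, (0.0, 1.0))):
                raise InputError("binary family requires values in {0, 1}")
            try:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                    maxiter=100, tol=1e-10
                )
            except Exception as exc:  # perfect separation raises inside IRLS
                raise DegenerateFitError(
                    f"binomial fit failed for {response!r} day {day} "
                    "(likely separation; consider fit_firth_logistic)"
                ) from exc
            if np.max(np.abs(res.params)) > 15 or not np.all(np.isfinite(res.bse)):
                raise DegenerateFitError(
                    f"quasi-separation in {response!r} day {day}: "
                    "unbounded estimates; use fit_firth_logistic"
                )
        elif family == "proportion":
            from statsmodels.othermod.betareg import BetaModel

            if np.any((y <= 0) | (y >= 1)):
                # standard boundary squeeze for Beta-distributed proportions
                n = len(y)
                y = (y * (n - 1) + 0.5) / n
            res = BetaModel(y, X).fit(disp=False)
            beta = np.asarray(res.params)[:4]
            se = np.asarray(res.bse)[:4]
            return _pack(response, day, "logit", beta, se, len(y))
        elif family == "continuous":
            fam = sm.families.Gaussian(
                sm.families.links.Log() if link == "log"
                else sm.families.links.Identity()
            )
            res = sm.GLM(y, X, family=fam).fit()
            beta = np.asarray(res.params)
            se = np.asarray(res.bse) * _small_sample_factor(len(y), X.shape[1])
            return _pack(response, day, link, beta, se, len(y))
        else:
            raise ConfigurationError(f"unknown family {family!r}")

    beta = np.asarray(res.params)
    se = np.asarray(res.bse)
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise DegenerateFitError(
            f"non-finite standard errors for {response!r} on day {day}"
        )
    return _pack(response, day, link, beta, se, len(y))


def fit_firth_logistic(
    observations: pd.DataFrame, response: str, day: int
) -> StressorCoefficients:
    """Bias-reduced (Firth) logistic 2x2 fit for one date's occurrence data.

    Jeffreys-prior penalization keeps all coefficients finite even under
    complete separation (e.g. a treatment cell with no occurrences), the
    regime where the ordinary logistic MLE diverges.
    """
    sub = observations[
        (observations["response"] == response) & (observations["day"] == day)
    ]
    if sub.empty:
        raise InputError(f"no observations for {response!r} on day {day}")
    _check_cells(sub)
    X, y = _design(sub)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise InputError("fit_firth_logistic requires a binary response")
    beta, se = firth_logistic(X, y)
    return _pack(response, day, "logit", beta, se, len(y))


@dataclass
class SeasonFit:
    """Season-wide fit: factorial coefficients plus per-cell smooth summaries.

    ``smooths`` maps each treatment combination ("site|warming") to the
    smooth's fitted values at the observed days, its approximate effective
    degrees of freedom, and its range (a wiggliness summary).
    """

    coefficients: StressorCoefficients
    smooths: Dict[str, Dict[str, np.ndarray]]
    nb_dispersion: float = 0.0


def fit_season_model(
    observations: pd.DataFrame,
    response: str,
    family: str = "count_nb",
    link: Optional[str] = None,
    smooth_df: int = 4,
    random_effect: bool = True,
) -> SeasonFit:
    """Fit the season-wide factorial model with per-cell time smooths.

    Parametric warming/pollution/interaction terms are estimated jointly
    with one ridge-penalized B-spline smooth of day per treatment
    combination and (optionally) plate random intercepts, via penalized
    IRLS.  Proportion responses use quasi-binomial working weights.  The
    returned coefficients carry ``date_label="season"``.
    """
    link = link or DEFAULT_FAMILIES[family]
    sub = observations[observations["response"] == response]
    if sub.empty:
        raise InputError(f"no observations for response {response!r}")
    days = np.sort(sub["day"].unique())
    if len(days) < 3:
        raise InputError("season model needs >= 3 distinct dates")
    if smooth_df >= len(days):
        raise ConfigurationError(
            f"smooth_df={smooth_df} must be < number of distinct dates ({len(days)})"
        )
    X, y = _design(sub)
    if np.ptp(y) == 0:
        raise DegenerateFitError(f"constant response {response!r}: zero variance")
    fam_map = {"count_nb": "count_nb", "binary": "binomial",
               "proportion": "binomial", "continuous": "gaussian"}
    if family not in fam_map:
        raise ConfigurationError(f"unknown family {family!r}")
    if family == "proportion":
        y = np.clip(y, 1e-6, 1.0 - 1e-6)
    cell = (sub["site"].astype(str) + "|" + sub["warming"].astype(str)).to_numpy()
    plates = (
        pd.Categorical(sub["plate_id"]).codes.astype(int) if random_effect else None
    )
    res = fit_penalized_additive(
        y=y, Xp=X, day=sub["day"].to_numpy(float), cell_labels=cell,
        plate_codes=plates, family=fam_map[family], smooth_df=smooth_df,
    )
    coef = _pack(response, "season", link, res.beta[:4],
                 np.r_[res.se_parametric[0], res.se_parametric[1:4]], len(y))
    return SeasonFit(coefficients=coef, smooths=res.smooths,
                     nb_dispersion=res.phi_nb)


# ---------------------------------------------------------------------------
# per-gene factorial negative-binomial fits


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios normalization factors (geometric mean reference)."""
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    usable = np.all(counts > 0, axis=1)
    if not usable.any():
        raise DegenerateFitError(
            "no gene has positive counts in all samples; "
            "cannot form median-of-ratios size factors"
        )
    ref = logc[usable].mean(axis=1, keepdims=True)
    s = np.exp(np.median(logc[usable] - ref, axis=0))
    return s / np.exp(np.mean(np.log(s)))


def _batch_nb_irls(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray,
    alpha: np.ndarray, n_iter: int = 30,
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized NB (log link) IRLS across genes sharing one design."""
    G, S = y.shape
    k = X.shape[1]
    beta = np.zeros((G, k))
    beta[:, 0] = np.log(np.mean(y / np.exp(offset), axis=1) + 0.1)
    ridge = 1e-6 * np.eye(k)
    for _ in range(n_iter):
        eta = beta @ X.T + offset
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset) + (y - mu) / mu
        XtWX = np.einsum("gs,si,sj->gij", w, X, X)
        XtWz = np.einsum("gs,si,gs->gi", w, X, z)
        new = np.linalg.solve(XtWX + ridge, XtWz[..., None])[..., 0]
        delta = np.max(np.abs(new - beta))
        beta = new
        if delta < 1e-8:
            break
    eta = beta @ X.T + offset
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("gs,si,sj->gij", w, X, X)
    cov = np.linalg.inv(XtWX + ridge)
    se = np.sqrt(np.einsum("gii->gi", cov))
    return beta, se


def fit_gene_models(
    counts: pd.DataFrame, samples: pd.DataFrame, min_total_count: int = 10
) -> pd.DataFrame:
    """Per-gene factorial NB fits (~ pollution + warming + pollution:warming).

    Genes with total count below ``min_total_count`` are removed before
    fitting; remaining all-zero genes are excluded and logged.  Counts are
    modelled with a log-link NB GLM with median-of-ratios size-factor
    offsets; per-gene dispersions are moment estimates shrunk toward a
    1/mean trend (a simplified analogue of empirical-Bayes dispersion
    moderation).  Log fold-changes are reported in log2 units with Wald
    normal p-values; BH-adjusted columns are left NaN for the typing stage.
    """
    if not set(samples["sample_id"]) == set(counts.columns):
        raise InputError("sample metadata does not match count matrix columns")
    cells = samples.groupby(["site", "warming"], observed=True).size()
    if len(cells) < 4 or (cells < 2).any():
        raise InputError("need >= 2 samples in each of the 4 treatment cells")

    ordered = samples.set_index("sample_id").loc[list(counts.columns)].reset_index()
    W = (ordered["warming"] == "warmed").to_numpy(float)
    P = (ordered["site"] == "polluted").to_numpy(float)
    X = np.column_stack([np.ones(len(ordered)), W, P, W * P])

    y_all = counts.to_numpy(float)
    keep = y_all.sum(axis=1) >= min_total_count
    n_low = int((~keep).sum())
    if n_low:
        logger.info("removed %d genes with total count < %d", n_low, min_total_count)
    y = y_all[keep]
    gene_ids = counts.index[keep]
    nonzero = y.sum(axis=1) > 0
    if (~nonzero).any():
        logger.info("excluded %d all-zero genes after filtering", int((~nonzero).sum()))
        y, gene_ids = y[nonzero], gene_ids[nonzero]
    if len(y) == 0:
        raise DegenerateFitError("no genes left after filtering")

    s = _size_factors(y)
    offset = np.log(s)

    # Poisson pilot for df-corrected moment dispersions
    n_s, k = y.shape[1], X.shape[1]
    beta0, _ = _batch_nb_irls(y, X, offset, np.zeros(len(y)), n_iter=15)
    mu0 = np.exp(np.clip(beta0 @ X.T + offset, -30, 30))
    infl = n_s / (n_s - k)
    num = np.sum(infl * (y - mu0) ** 2 - mu0, axis=1)
    den = np.sum(mu0 ** 2, axis=1)
    alpha_mom = np.maximum(num / np.maximum(den, 1e-12), 1e-8)

    # dispersion trend alpha ~ a0 + a1/mean; per-gene dispersions are shrunk
    # upward to the trend (guards the far Wald tail against dispersion
    # underestimation noise, the dominant false-positive source at small n)
    mean_norm = np.mean(y / s, axis=1)
    informative = alpha_mom > 1e-6
    if informative.sum() >= 10:
        A = np.column_stack([np.ones(informative.sum()), 1.0 / mean_norm[informative]])
        coefs, *_ = np.linalg.lstsq(A, alpha_mom[informative], rcond=None)
        a0 = max(float(coefs[0]), 1e-4)
        a1 = max(float(coefs[1]), 0.0)
    else:
        a0, a1 = 0.05, 5.0
    alpha_trend = a0 + a1 / np.maximum(mean_norm, 1e-8)
    alpha = np.maximum(alpha_mom, alpha_trend)

    beta, se = _batch_nb_irls(y, X, offset, alpha)
    # t-calibrated effective SEs: scale each SE so the normal-Wald identity
    # p = 2(1 - Phi(|b|/SE)) reproduces a t reference with residual df,
    # restoring small-sample tail calibration
    se = _t_calibrated_se(beta, se, df=n_s - k)
    p = 2.0 * norm.sf(np.abs(beta) / se)

    return pd.DataFrame({
        "gene_id": gene_ids,
        "lfc_w": beta[:, 1] / _LN2, "lfc_p": beta[:, 2] / _LN2,
        "lfc_int": beta[:, 3] / _LN2,
        "se_w": se[:, 1] / _LN2, "se_p": se[:, 2] / _LN2,
        "se_int": se[:, 3] / _LN2,
        "p_w": p[:, 1], "p_p": p[:, 2], "p_int": p[:, 3],
        "padj_w": np.nan, "padj_p": np.nan, "padj_int": np.nan,
    }).reset_index(drop=True)
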