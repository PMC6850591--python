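"""Cross-species models of thermal-distribution skew.

T_skew is regressed on T_opt and habitat associations (coral, macroalgae)
within each thermal guild, with nested taxonomic random intercepts
(order/family/genus) standing in for shared evolutionary history. REML
fits are used for reported coefficients; maximum-likelihood refits for
likelihood-ratio comparisons. Models are compared by small-sample AICc,
and guild slopes by a two-sample Wald z.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist, norm
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

FIXED_FORMULA = "tskew ~ topt + coral_assoc + macroalgae_assoc"
RANDOM_LEVELS = ("family", "genus")  # variance components inside order groups


@dataclass
class SkewModelFit:
    fixed_effects: pd.DataFrame          # coef, se, z, p per term
    random_intercept_variances: dict[str, float]
    loglik: float
    aicc: float
    n_species: int
    k_params: int
    reml: bool
    include_random: bool
    formula: str = FIXED_FORMULA
    converged: bool = True
    dropped_levels: list[str] = field(default_factory=list)

    def slope(self, term: str = "topt") -> tuple[float, float]:
        row = self.fixed_effects.loc[term]
        return float(row["coef"]), float(row["se"])


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2l + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined for n <= k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _prepare(profiles: pd.DataFrame, guild: str | None) -> pd.DataFrame:
    df = profiles.copy()
    if guild is not None:
        df = df[df["guild"] == guild]
    needed = ["tskew", "topt", "coral_assoc", "macroalgae_assoc"]
    n_before = len(df)
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    if len(df) < n_before:
        logger.info("dropped %d species with missing covariates", n_before - len(df))
    if len(df) < 10:
        raise ValueError(f"need >= 10 species, got {len(df)}")
    return df.reset_index(drop=True)


def fit_skew_lmm(
    profiles: pd.DataFrame,
    guild: str | None = None,
    include_random: bool = True,
    reml: bool = True,
) -> SkewModelFit:
    """Fit tskew ~ topt + coral_assoc + macroalgae_assoc (+ taxonomy).

    With ``include_random``, nested random intercepts are modelled as an
    order-level intercept plus family- and genus-level variance
    components. A singular fit (zero or non-converging variance at some
    level) is refit without the offending level, innermost first, and the
    drops are recorded on the result.
    """
    df = _prepare(profiles, guild)
    if not include_random:
        res = smf.ols(FIXED_FORMULA, data=df).fit()
        k = len(res.params) + 1  # + residual variance
        fe = pd.DataFrame(
            {"coef": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues}
        )
        fe.index = [i.replace("Intercept", "Intercept") for i in fe.index]
        return SkewModelFit(
            fixed_effects=fe,
            random_intercept_variances={},
            loglik=float(res.llf),
            aicc=aicc(float(res.llf), k, len(df)),
            n_species=len(df),
            k_params=k,
            reml=False,
            include_random=False,
        )

    levels = list(RANDOM_LEVELS)
    dropped: list[str] = []
    while True:
        vc = {lvl: f"0 + C({lvl})" for lvl in levels}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    FIXED_FORMULA, data=df, groups=df["order"],
                    re_formula="1", vc_formula=vc if vc else None,
                )
                res = model.fit(reml=reml, method=["lbfgs", "powell"])
            singular = _singular_levels(res, levels)
            if res.converged and not singular:
                return _pack_mixed(res, df, levels, reml, dropped)
            if not levels:
                break
            drop = singular[-1] if singular else levels[-1]
        except Exception as exc:  # noqa: BLE001
            logger.warning("mixed fit failed (%s)", exc)
            if not levels:
                break
            drop = levels[-1]
        levels.remove(drop)
        dropped.append(drop)
        logger.warning("refitting without %s-level random intercept", drop)
    logger.warning("random-effects structure unusable; falling back to OLS")
    fit = fit_skew_lmm(profiles, guild=guild, include_random=False)
    fit.dropped_levels = dropped + ["order"]
    return fit


def _singular_levels(res, levels: list[str]) -> list[str]:
    out = []
    vcomp = dict(zip(res.model.exog_vc.names, np.atleast_1d(res.vcomp))) if len(levels) else {}
    for lvl in levels:
        if vcomp.get(lvl, 1.0) < 1e-8:
            out.append(lvl)
    return out


def _pack_mixed(res, df: pd.DataFrame, levels: list[str], reml: bool,
                dropped: list[str]) -> SkewModelFit:
    fe_names = res.model.exog_names
    fe = pd.DataFrame(
        {
            "coef": res.fe_params,
            "se": res.bse_fe,
            "z": res.fe_params / res.bse_fe,
        }
    )
    fe["p"] = 2 * norm.sf(np.abs(fe["z"]))
    fe.index = fe_names
    variances = {"order": float(np.asarray(res.cov_re)[0, 0])}
    if len(levels):
        for name, v in zip(res.model.exog_vc.names, np.atleast_1d(res.vcomp)):
            variances[name] = float(v)
    k = len(fe_names) + len(variances) + 1  # + residual variance
    ll = float(res.llf)
    return SkewModelFit(
        fixed_effects=fe,
        random_intercept_variances=variances,
        loglik=ll,
        aicc=aicc(ll, k, len(df)),
        n_species=len(df),
        k_params=k,
        reml=reml,
        include_random=True,
        converged=bool(res.converged),
        dropped_levels=dropped,
    )


def likelihood_ratio_test(fit_small: SkewModelFit, fit_big: SkewModelFit) -> tuple[float, int, float]:
    """LRT between nested ML fits: 2*delta-loglik vs chi-square(delta-k)."""
    if fit_small.reml or fit_big.reml:
        raise ValueError("LRT requires maximum-likelihood (not REML) fits")
    df = fit_big.k_params - fit_small.k_params
    if df <= 0:
        raise ValueError("models are not nested small-within-big")
    if fit_small.n_species != fit_big.n_species:
        raise ValueError("fits must be on identical data")
    stat = 2.0 * (fit_big.loglik - fit_small.loglik)
    return stat, df, float(chi2_dist.sf(max(stat, 0.0), df))


def compare_models(fits: list[SkewModelFit]) -> pd.DataFrame:
    """AICc selection table, sorted best-first with delta-AICc."""
    if len({f.n_species for f in fits}) != 1:
        raise ValueError("fits must be on identical data")
    tab = pd.DataFrame(
        {
            "include_random": [f.include_random for f in fits],
            "dropped_levels": ["+".join(f.dropped_levels) or "-" for f in fits],
            "k": [f.k_params for f in fits],
            "loglik": [f.loglik for f in fits],
            "aicc": [f.aicc for f in fits],
        }
    )
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].min()
    return tab.sort_values("aicc").reset_index(drop=True)


def slope_difference_test(
    fit_a: SkewModelFit | tuple[float, float],
    fit_b: SkewModelFit | tuple[float, float],
    term: str = "topt",
) -> tuple[float, float]:
    """Two-sample Wald z for a slope difference between guild fits.

    z = (b_a - b_b) / sqrt(se_a^2 + se_b^2) with a two-sided normal p.
    Accepts fitted models or raw (coefficient, se) pairs.
    """
    b1, se1 = fit_a.slope(term) if isinstance(fit_a, SkewModelFit) else fit_a
    b2, se2 = fit_b.slope(term) if isinstance(fit_b, SkewModelFit) else fit_b
    denom = np.sqrt(se1**2 + se2**2)
    if denom == 0:
        if b1 == b2:
            return 0.0, 1.0
        raise ValueError("zero standard errors with unequal slopes")
    z = (b1 - b2) / denom
    return float(z), float(2 * norm.sf(abs(z)))
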