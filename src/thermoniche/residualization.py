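"""First stage of the two-stage residual analysis.

Per species: (1) a PCA of environmental covariates across the species'
frame, keeping axes that explain more than a retention fraction of the
variance; (2) a zero-inflated Poisson (ZIP) regression of abundance on the
retained axes plus depth, protection and sampling intensity — temperature
is deliberately excluded so the second stage can measure its effect on the
residuals; (3) response residuals y - E[y]; (4) a permutation Mantel test
for residual spatial autocorrelation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
import statsmodels.api as sm

logger = logging.getLogger(__name__)

FIXED_COVARIATES = ("depth", "protection", "sampling_intensity")


@dataclass
class PcaResult:
    loadings: np.ndarray          # covariates x axes
    scores: np.ndarray            # rows x axes
    variance_fraction: np.ndarray  # per-axis fraction, sums to 1
    retained_axes: np.ndarray     # indices of axes with fraction > retention
    columns: list[str] = field(default_factory=list)

    @property
    def retained_scores(self) -> np.ndarray:
        return self.scores[:, self.retained_axes]


def species_pca(covariate_matrix: pd.DataFrame, retention: float = 0.10) -> PcaResult:
    """Standardised PCA keeping axes that explain > ``retention`` variance.

    Constant covariates are dropped with a warning before decomposition;
    an all-constant matrix is an error.
    """
    X = pd.DataFrame(covariate_matrix)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 covariates")
    variances = X.var(axis=0, ddof=0)
    constant = variances[variances == 0.0].index.tolist()
    if constant:
        logger.warning("dropping constant covariates before PCA: %s", constant)
        X = X.drop(columns=constant)
    if X.shape[1] == 0:
        raise ValueError("all covariates are constant")
    Xs = StandardScaler().fit_transform(X.to_numpy(dtype=float))
    pca = PCA(n_components=min(Xs.shape)).fit(Xs)
    frac = pca.explained_variance_ratio_
    retained = np.nonzero(frac > retention)[0]
    return PcaResult(
        loadings=pca.components_.T,
        scores=pca.transform(Xs),
        variance_fraction=frac,
        retained_axes=retained,
        columns=list(X.columns),
    )


@dataclass
class ZipFit:
    """Fitted zero-inflated Poisson first-stage model.

    ``count_params`` are coefficients on the log scale of the Poisson mean
    (intercept first); ``infl_logit`` is the intercept-only logit of the
    structural-zero probability. ``fallback`` marks species where the ZIP
    optimiser failed and a plain Poisson GLM was used instead (pi = 0).
    """

    count_params: np.ndarray
    infl_logit: float
    loglik: float
    converged: bool
    fallback: bool
    design_columns: list[str]
    count_params_se: np.ndarray | None = None
    infl_logit_se: float | None = None

    @property
    def pi(self) -> float:
        return 0.0 if self.fallback else float(expit(self.infl_logit))

    def predict_mean(self, design: np.ndarray) -> np.ndarray:
        """E[y] = (1 - pi) * lambda on the count scale."""
        X = sm.add_constant(np.asarray(design, dtype=float), has_constant="add")
        lam = np.exp(X @ self.count_params)
        return (1.0 - self.pi) * lam


def build_design(frame: pd.DataFrame, pca: PcaResult | None) -> tuple[np.ndarray, list[str]]:
    """Assemble the first-stage design: retained PC scores + fixed covariates.

    Zero-variance columns (e.g. sampling_intensity, constant within a
    species frame) are dropped with a log entry to keep the design full
    rank; the intercept absorbs them.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    if pca is not None:
        for j, ax in enumerate(pca.retained_axes):
            cols.append(pca.scores[:, ax])
            names.append(f"PC{ax + 1}")
    for name in FIXED_COVARIATES:
        if name in frame.columns:
            cols.append(frame[name].to_numpy(dtype=float))
            names.append(name)
    X = np.column_stack(cols) if cols else np.empty((len(frame), 0))
    keep = [i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 0]
    if len(keep) < X.shape[1]:
        dropped = [names[i] for i in range(X.shape[1]) if i not in keep]
        logger.info("dropping zero-variance design columns: %s", dropped)
    return X[:, keep], [names[i] for i in keep]


def fit_zip(abundance: np.ndarray, design: np.ndarray,
            design_columns: list[str] | None = None) -> ZipFit:
    """Maximise the ZIP likelihood with log-link counts and an
    intercept-only logit inflation part; falls back to a Poisson GLM when
    the optimiser fails to converge."""
    y = np.asarray(abundance, dtype=float)
    X = sm.add_constant(np.asarray(design, dtype=float), has_constant="add")
    names = design_columns or [f"x{i}" for i in range(X.shape[1] - 1)]
    if not (y == 0).any() or not (y > 0).any():
        raise ValueError("response must contain both zero and positive counts")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.ZeroInflatedPoisson(y, X, exog_infl=np.ones((len(y), 1)),
                                           inflation="logit")
            res = model.fit(method="bfgs", maxiter=500, disp=0)
        converged = bool(res.mle_retvals.get("converged", False))
        if converged and np.all(np.isfinite(res.params)):
            return ZipFit(
                count_params=np.asarray(res.params[1:]),
                infl_logit=float(res.params[0]),
                loglik=float(res.llf),
                converged=True,
                fallback=False,
                design_columns=names,
                count_params_se=np.asarray(res.bse[1:]),
                infl_logit_se=float(res.bse[0]),
            )
    except Exception as exc:  # noqa: BLE001 - optimiser failures route to fallback
        logger.warning("ZIP fit raised %s; falling back to Poisson GLM", exc)
    logger.warning("ZIP fit did not converge; Poisson GLM fallback used")
    glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    return ZipFit(
        count_params=np.asarray(glm.params),
        infl_logit=-np.inf,
        loglik=float(glm.llf),
        converged=True,
        fallback=True,
        design_columns=names,
        count_params_se=np.asarray(glm.bse),
    )


def extract_residuals(fit: ZipFit, abundance: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Response residuals y - (1 - pi) * lambda on the count scale."""
    y = np.asarray(abundance, dtype=float)
    return y - fit.predict_mean(design)


def residualize_frame(frame: pd.DataFrame, covariate_cols: list[str],
                      retention: float = 0.10) -> tuple[np.ndarray, ZipFit, PcaResult | None]:
    """PCA + ZIP + residual extraction for one modelling frame."""
    pca = None
    usable = [c for c in covariate_cols
              if c in frame.columns and frame[c].var(ddof=0) > 0]
    if len(usable) >= 2:
        pca = species_pca(frame[usable], retention=retention)
    X, names = build_design(frame, pca)
    fit = fit_zip(frame["abundance"].to_numpy(), X, names)
    resid = extract_residuals(fit, frame["abundance"].to_numpy(), X)
    return resid, fit, pca


def mantel_test(
    geo_dist: np.ndarray,
    resid_dist: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation of two distance matrices with a permutation p.

    r is the Pearson correlation of the lower triangles; the one-sided
    p-value is (1 + #{permuted r >= observed}) / (n_perm + 1), permuting
    rows and columns of the second matrix jointly.
    """
    D1 = np.asarray(geo_dist, dtype=float)
    D2 = np.asarray(resid_dist, dtype=float)
    if D1.shape != D2.shape or D1.ndim != 2 or D1.shape[0] != D1.shape[1]:
        raise ValueError("matrices must be square and of matching dimension")
    n = D1.shape[0]
    if n < 3:
        raise ValueError("need dimension >= 3")
    if not (np.allclose(D1, D1.T) and np.allclose(D2, D2.T)):
        raise ValueError("matrices must be symmetric")
    il = np.tril_indices(n, k=-1)
    v1 = D1[il]

    def corr(mat: np.ndarray) -> float:
        v2 = mat[il]
        if v1.std() == 0 or v2.std() == 0:
            return 0.0
        return float(np.corrcoef(v1, v2)[0, 1])

    r_obs = corr(D2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if corr(D2[np.ix_(p, p)]) >= r_obs:
            count += 1
    p_val = (1 + count) / (n_perm + 1)
    return r_obs, p_val
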