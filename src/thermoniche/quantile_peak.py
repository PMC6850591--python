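"""Second stage: quantile-spline ceilings of residual abundance.

The 80th quantile of residual abundance is modelled as a smooth function
of temperature using a low-rank cubic regression spline (basis dimension
k = 4) fitted by minimising the pinball (check) loss with a
second-derivative roughness penalty; the smoothing parameter is chosen by
5-fold cross-validated pinball loss. The temperature of the curve's peak
is the realised thermal optimum T_opt. Because constructed absences are
subsampled, the fit is bootstrapped over 25 random absence subsets and
the replicate curves averaged pointwise before taking the argmax.

Shape classes follow the edge-drop rule: a thermal-abundance distribution
is 'abundant-centre' when the curve falls below 75% of its maximum at
both thermal edges, 'no-trend' when it does so at neither, and warm- or
cool-skewed when only the warm or only the cool edge stays high.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist

from . import config
from .survey_prep import balance_absences
from .residualization import residualize_frame

logger = logging.getLogger(__name__)

SHAPE_LABELS = ("no_trend", "abundant_centre", "warm_skewed", "cool_skewed")

DEFAULT_LAMBDA_GRID = np.logspace(-6, 3, 10)


# --------------------------------------------------------------------------
# spline machinery
# --------------------------------------------------------------------------

class NaturalSplineBasis:
    """Natural cubic regression spline with quantile-placed knots.

    ``basis_dim`` knots give a ``basis_dim``-dimensional space (intercept,
    linear term, and K-2 curvature terms); the fit is linear beyond the
    boundary knots, which keeps edge behaviour tame where data are sparse.
    Inputs are centred/scaled internally for conditioning.
    """

    def __init__(self, x: np.ndarray, basis_dim: int):
        x = np.asarray(x, dtype=float)
        self.center = float(x.mean())
        self.scale = float(x.std()) or 1.0
        z = (x - self.center) / self.scale
        knots = np.quantile(np.unique(z), np.linspace(0.0, 1.0, basis_dim))
        knots = np.unique(knots)
        if len(knots) < 3:
            raise ValueError("too few distinct temperatures for a spline basis")
        self.knots = knots
        self.dim = len(knots)

    def _d(self, z: np.ndarray, k: int) -> np.ndarray:
        kn = self.knots
        return (np.clip(z - kn[k], 0, None) ** 3
                - np.clip(z - kn[-1], 0, None) ** 3) / (kn[-1] - kn[k])

    def design(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.center) / self.scale
        cols = [np.ones_like(z), z]
        d_last = self._d(z, self.dim - 2)
        for k in range(self.dim - 2):
            cols.append(self._d(z, k) - d_last)
        return np.column_stack(cols)

    def _d2(self, z: np.ndarray, k: int) -> np.ndarray:
        kn = self.knots
        return 6.0 * (np.clip(z - kn[k], 0, None)
                      - np.clip(z - kn[-1], 0, None)) / (kn[-1] - kn[k])

    def penalty(self) -> np.ndarray:
        """Gram matrix of second derivatives; exact by Gauss-Legendre,
        since the integrand is piecewise quadratic."""
        gl_x, gl_w = np.polynomial.legendre.leggauss(3)
        P = np.zeros((self.dim, self.dim))
        for a, b in zip(self.knots[:-1], self.knots[1:]):
            mid, half = (a + b) / 2.0, (b - a) / 2.0
            pts = mid + half * gl_x
            d2_last = self._d2(pts, self.dim - 2)
            d2 = np.column_stack(
                [np.zeros_like(pts), np.zeros_like(pts)]
                + [self._d2(pts, k) - d2_last for k in range(self.dim - 2)]
            )
            P += half * (d2 * gl_w[:, None]).T @ d2
        return P


def pinball_loss(residual: np.ndarray, tau: float) -> np.ndarray:
    """Check loss rho_tau(r) = r * (tau - 1[r < 0])."""
    r = np.asarray(residual, dtype=float)
    return r * (tau - (r < 0.0))


def _fit_coefs(B: np.ndarray, y: np.ndarray, P: np.ndarray, lam: float,
               tau: float, eps: float) -> np.ndarray:
    """Minimise smoothed pinball + lam * c'Pc (convex; L-BFGS)."""

    c0 = np.linalg.lstsq(B.T @ B + 1e-8 * np.eye(B.shape[1]), B.T @ y, rcond=None)[0]

    def objective(c: np.ndarray) -> tuple[float, np.ndarray]:
        r = y - B @ c
        # smooth pinball: tau*r + eps*log(1 + exp(-r/eps)), -> rho_tau as eps->0
        z = -r / eps
        soft = eps * np.logaddexp(0.0, z)
        loss = float(np.sum(tau * r + soft)) / len(y)
        w = tau - expit(z)                           # d loss / d r
        grad = -(B.T @ w) / len(y) + 2.0 * lam * (P @ c)
        return loss + lam * float(c @ P @ c), grad

    res = minimize(objective, c0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10})
    return res.x


@dataclass
class QuantileCurve:
    """Fitted tau-quantile curve of residual abundance over temperature."""

    grid: np.ndarray
    fitted: np.ndarray
    basis_dim: int
    smoothing_parameter: float
    tau: float
    coefs: np.ndarray = field(default=None, repr=False)
    basis: NaturalSplineBasis = field(default=None, repr=False)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.basis.design(np.asarray(x, dtype=float)) @ self.coefs


def fit_quantile_spline(
    sst: np.ndarray,
    residuals: np.ndarray,
    tau: float = config.QUANTILE_TAU,
    basis_dim: int = config.SPLINE_BASIS_DIM,
    lambda_grid: np.ndarray | None = None,
    smoothing_parameter: float | None = None,
    grid: np.ndarray | None = None,
    n_grid: int = 200,
    cv_folds: int = 5,
    seed: int = 0,
    knot_x: np.ndarray | None = None,
) -> QuantileCurve:
    """Penalised pinball-loss spline fit of the tau-quantile vs temperature.

    If ``smoothing_parameter`` is given it is used directly; otherwise it
    is chosen from ``lambda_grid`` by k-fold cross-validated pinball loss
    (ties broken towards the smallest value, i.e. least smoothing).
    ``knot_x`` optionally supplies the values whose quantiles place the
    knots (e.g. presence temperatures only, concentrating flexibility
    where abundance information lives); the default is all of ``sst``.
    """
    x = np.asarray(sst, dtype=float)
    y = np.asarray(residuals, dtype=float)
    if len(x) < 2 * basis_dim:
        raise ValueError(f"need >= {2 * basis_dim} observations, got {len(x)}")
    lo, hi = float(x.min()), float(x.max())
    if not hi > lo:
        raise ValueError("temperature range must be > 0")
    basis = NaturalSplineBasis(x if knot_x is None else np.asarray(knot_x, float),
                               basis_dim)
    B = basis.design(x)
    P = basis.penalty()
    iqr = np.subtract(*np.percentile(y, [75, 25]))
    eps = max(1e-3 * (iqr if iqr > 0 else float(np.std(y)) or 1.0), 1e-9)

    if smoothing_parameter is None:
        lams = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid)
        if len(lams) == 1:
            smoothing_parameter = float(lams[0])
        else:
            rng = config.child_rng(seed, config.SEED_SPLINE_CV)
            folds = rng.permutation(len(x)) % cv_folds
            scores = np.zeros(len(lams))
            for k in range(cv_folds):
                tr, te = folds != k, folds == k
                if tr.sum() < basis_dim or te.sum() == 0:
                    continue
                for i, lam in enumerate(lams):
                    c = _fit_coefs(B[tr], y[tr], P, lam, tau, eps)
                    scores[i] += pinball_loss(y[te] - B[te] @ c, tau).sum()
            smoothing_parameter = float(lams[int(np.argmin(scores))])
    coefs = _fit_coefs(B, y, P, float(smoothing_parameter), tau, eps)
    if grid is None:
        grid = np.linspace(lo, hi, n_grid)
    curve = QuantileCurve(
        grid=np.asarray(grid, dtype=float),
        fitted=None,
        basis_dim=basis_dim,
        smoothing_parameter=float(smoothing_parameter),
        tau=tau,
        coefs=coefs,
        basis=basis,
    )
    curve.fitted = curve.predict(curve.grid)
    return curve


# --------------------------------------------------------------------------
# bootstrap over absence subsets
# --------------------------------------------------------------------------

@dataclass
class ToptEstimate:
    topt: float
    curve: QuantileCurve
    n_boot: int
    per_boot_topt: list[float]


def _argmax_lowest(grid: np.ndarray, values: np.ndarray) -> float:
    """Grid argmax; ties broken towards the lowest temperature."""
    best = np.max(values)
    return float(grid[np.nonzero(values >= best - 1e-12)[0][0]])


def bootstrap_topt(
    frame: pd.DataFrame,
    covariate_cols: list[str],
    n_boot: int = config.N_BOOTSTRAP,
    tau: float = config.QUANTILE_TAU,
    basis_dim: int = config.SPLINE_BASIS_DIM,
    retention: float = config.PCA_RETENTION,
    seed: int = 0,
    n_grid: int = 200,
) -> ToptEstimate:
    """Residualize + quantile fit over ``n_boot`` random absence subsets.

    Each replicate rebalances absences with a fresh child seed, refits the
    first-stage ZIP and the quantile spline, and predicts on a grid common
    to all replicates; the aggregated curve is the pointwise mean and
    T_opt its argmax. When absences do not outnumber presences there is no
    subsampling variability and a single fit is performed. The smoothing
    parameter is cross-validated on the first replicate and reused.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n_pres = int((~frame["is_absence"]).sum())
    n_abs = int(frame["is_absence"].sum())
    if n_abs <= n_pres:
        n_boot = 1
    # Predict (and locate the peak) on the occupied thermal range only:
    # beyond the warmest/coolest presence the spline is informed by sparse
    # constructed absences and its boundary behaviour is not meaningful.
    pres_sst = frame.loc[~frame["is_absence"], "sst"]
    grid = np.linspace(pres_sst.min(), pres_sst.max(), n_grid)
    curves = []
    per_boot = []
    lam = None
    failures = 0
    for b in range(n_boot):
        sub = balance_absences(frame, seed=seed, replicate=b)
        try:
            resid, _, _ = residualize_frame(sub, covariate_cols, retention=retention)
            c = fit_quantile_spline(
                sub["sst"].to_numpy(), resid, tau=tau, basis_dim=basis_dim,
                smoothing_parameter=lam, grid=grid, seed=seed,
                knot_x=sub.loc[~sub["is_absence"], "sst"].to_numpy(),
            )
        except Exception as exc:  # noqa: BLE001 - replicate failure tolerated
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            failures += 1
            continue
        lam = c.smoothing_parameter
        curves.append(c.fitted)
        per_boot.append(_argmax_lowest(grid, c.fitted))
    if not curves:
        raise RuntimeError("all bootstrap replicates failed for this species")
    mean_fit = np.mean(curves, axis=0)
    agg = QuantileCurve(grid=grid, fitted=mean_fit, basis_dim=basis_dim,
                        smoothing_parameter=lam, tau=tau)
    return ToptEstimate(
        topt=_argmax_lowest(grid, mean_fit),
        curve=agg,
        n_boot=len(curves),
        per_boot_topt=per_boot,
    )


# --------------------------------------------------------------------------
# temperature-effect permutation test
# --------------------------------------------------------------------------

def temperature_effect_test(
    sst: np.ndarray,
    residuals: np.ndarray,
    tau: float = config.QUANTILE_TAU,
    basis_dim: int = config.SPLINE_BASIS_DIM,
    smoothing_parameter: float = 0.0,
    n_perm: int = config.EFFECT_TEST_PERMUTATIONS,
    seed: int = 0,
) -> float:
    """Permutation p-value for a temperature effect on the quantile ceiling.

    Statistic: pinball-loss reduction of the smooth fit relative to the
    constant tau-quantile fit; the null is built by permuting temperature
    against residuals.
    """
    x = np.asarray(sst, dtype=float)
    y = np.asarray(residuals, dtype=float)
    const_loss = pinball_loss(y - np.quantile(y, tau), tau).sum()

    def stat(xp: np.ndarray) -> float:
        c = fit_quantile_spline(xp, y, tau=tau, basis_dim=basis_dim,
                                smoothing_parameter=smoothing_parameter, n_grid=2)
        # the spline family contains the constant fit, so the true loss
        # reduction is >= 0; clip away smoothed-optimisation artefacts
        return max(const_loss - pinball_loss(y - c.predict(xp), tau).sum(), 0.0)

    obs = stat(x)
    rng = config.child_rng(seed, config.SEED_PERMUTATION)
    exceed = 0
    for _ in range(n_perm):
        if stat(rng.permutation(x)) >= obs:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


# --------------------------------------------------------------------------
# shape classification
# --------------------------------------------------------------------------

@dataclass
class ShapeClass:
    label: str
    rel_abund_cool_edge: float
    rel_abund_warm_edge: float
    threshold: float


def classify_shape(
    curve: QuantileCurve,
    tmin: float,
    tmax: float,
    threshold: float = config.SHAPE_THRESHOLD,
) -> ShapeClass:
    """Classify the thermal-abundance distribution by edge drop.

    The curve is shifted so its minimum is zero (residual curves can be
    negative and '% of maximum abundance' presumes a non-negative scale),
    then evaluated at the cool and warm edges relative to its maximum.
    """
    if not tmin < tmax:
        raise ValueError("tmin must be < tmax")
    g, f = curve.grid, curve.fitted
    lo, hi = g[0], g[-1]
    if tmin < lo or tmax > hi:
        logger.info("edges clamped to curve grid span")
    shifted = f - f.min()
    M = shifted.max()
    if M == 0:
        logger.warning("flat zero curve; classified as no_trend")
        return ShapeClass("no_trend", 1.0, 1.0, threshold)
    r_cool = float(np.interp(np.clip(tmin, lo, hi), g, shifted) / M)
    r_warm = float(np.interp(np.clip(tmax, lo, hi), g, shifted) / M)
    if r_cool >= threshold and r_warm >= threshold:
        label = "no_trend"
    elif r_cool < threshold and r_warm < threshold:
        label = "abundant_centre"
    elif r_warm >= threshold:
        label = "warm_skewed"
    else:
        label = "cool_skewed"
    return ShapeClass(label, r_cool, r_warm, threshold)


# --------------------------------------------------------------------------
# category-proportion chi-square
# --------------------------------------------------------------------------

def shape_proportions_test(labels: list[str | ShapeClass]) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of shape-category counts vs uniform n/4."""
    if len(labels) == 0:
        raise ValueError("need at least one label")
    names = [l.label if isinstance(l, ShapeClass) else l for l in labels]
    counts = np.array([names.count(k) for k in SHAPE_LABELS], dtype=float)
    return _chi_square(counts, expected=counts.sum() / 4.0)


def chi_square_from_percentages(percentages: list[float], n: int) -> tuple[float, int, float]:
    """Goodness-of-fit statistic from printed category percentages.

    Observed counts are percentage/100 * n; the uniform expectation is
    n/4 per category (df = 3). Rounding of printed percentages means the
    observed counts need not sum exactly to n.
    """
    obs = np.asarray(percentages, dtype=float) / 100.0 * n
    return _chi_square(obs, expected=n / 4.0)


def _chi_square(observed: np.ndarray, expected: float) -> tuple[float, int, float]:
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    df = len(observed) - 1
    return chi2, df, float(chi2_dist.sf(chi2, df))
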