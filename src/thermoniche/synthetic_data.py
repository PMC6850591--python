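"""Synthetic reef-survey generator with known ground truth.

Emulates the structure of a global shallow-reef visual-census dataset:
sites spanning a 5-30 °C sea-surface-temperature gradient, environmental
covariates partially collinear with temperature, a coral-to-macroalgae
habitat transition near 23 °C, and species whose zero-inflated counts
follow a split-Gaussian thermal performance curve

    lambda(T) = peak_lambda * exp(-((T - T_opt) / sigma_side)^2),

with ``sigma_side = sigma_min`` below the optimum and ``sigma_max`` above.
Counts are zero with probability ``pi`` (structural zeros) and otherwise
Poisson. Every generated species carries its ground truth so downstream
estimators can be scored for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import config

SCENARIOS = ("symmetric", "warm_skew", "cool_skew", "mixed")

COVARIATE_PREFIX = "cov_"


@dataclass(frozen=True)
class SpeciesTruth:
    """Generator-side ground truth for one species."""

    species_id: str
    order: str
    family: str
    genus: str
    true_topt: float          # °C
    true_sigma_min: float     # °C, cool-side scale (> 0)
    true_sigma_max: float     # °C, warm-side scale (> 0)
    peak_lambda: float        # expected count at T_opt
    zero_inflation_pi: float  # structural-zero probability in [0, 1)
    habitat_pref: float       # signed coral (+) vs macroalgae (-) preference
    scenario: str = "symmetric"

    def __post_init__(self) -> None:
        if self.true_sigma_min <= 0 or self.true_sigma_max <= 0:
            raise ValueError("sigma parameters must be > 0")
        if not 0.0 <= self.zero_inflation_pi < 1.0:
            raise ValueError("zero_inflation_pi must be in [0, 1)")

    @property
    def true_tskew(self) -> float:
        """sigma_max - sigma_min; negative = warm-skewed."""
        return self.true_sigma_max - self.true_sigma_min


def truths_to_frame(species: Sequence[SpeciesTruth]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in species])


def generate_sites(
    n_sites: int,
    sst_range: tuple[float, float] = config.SST_RANGE,
    covariate_sst_correlation: float = 0.6,
    n_covariates: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a site table across a thermal gradient.

    Covariates are built through a Gaussian copula so each has the requested
    Spearman rank correlation with SST. Coral cover rises and macroalgae
    cover falls sigmoidally with SST, crossing near 23 °C, with their sum
    bounded by 100%. Latitude decreases with SST so that thermally similar
    sites are also spatially close (needed for buffer-based absences).
    """
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")
    lo, hi = float(sst_range[0]), float(sst_range[1])
    if not lo < hi:
        raise ValueError(f"sst_range must satisfy min < max, got {sst_range}")
    if not 0.0 <= covariate_sst_correlation <= 1.0:
        raise ValueError("covariate_sst_correlation must be in [0, 1]")

    rng = config.child_rng(seed, config.SEED_SITES)
    sst = rng.uniform(lo, hi, size=n_sites)

    # spatial layout: latitude tracks the thermal gradient with scatter
    latitude = 65.0 - 60.0 * (sst - lo) / (hi - lo) + rng.normal(0.0, 2.0, n_sites)
    longitude = rng.uniform(0.0, 40.0, size=n_sites)

    # Gaussian-copula covariates with target Spearman correlation to SST.
    # For a bivariate normal, rho_spearman = (6/pi) asin(r/2); invert it.
    rho_s = covariate_sst_correlation
    r = 2.0 * np.sin(np.pi * rho_s / 6.0)
    ranks = pd.Series(sst).rank(method="average").to_numpy()
    z_sst = _normal_scores(ranks, n_sites)
    covs = {}
    for j in range(n_covariates):
        noise = rng.normal(0.0, 1.0, n_sites)
        covs[f"{COVARIATE_PREFIX}{j + 1}"] = r * z_sst + np.sqrt(1.0 - r**2) * noise

    depth = np.clip(rng.lognormal(mean=2.2, sigma=0.5, size=n_sites), 2.0, 40.0)
    protection = rng.integers(0, 3, size=n_sites)

    total_cover = np.clip(rng.normal(80.0, 6.0, n_sites), 40.0, 100.0)
    frac_coral = expit((sst - config.HABITAT_TRANSITION_C) / 1.5
                       + rng.normal(0.0, 0.4, n_sites))
    coral_cover = total_cover * frac_coral
    macroalgae_cover = total_cover * (1.0 - frac_coral)

    table = pd.DataFrame(
        {
            "site_id": [f"S{i:05d}" for i in range(n_sites)],
            "latitude": latitude,
            "longitude": longitude,
            "sst": sst,
            "depth": depth,
            "protection": protection,
            "coral_cover": coral_cover,
            "macroalgae_cover": macroalgae_cover,
            **covs,
        }
    )
    return table


def _normal_scores(ranks: np.ndarray, n: int) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf(ranks / (n + 1.0))


def covariate_columns(sites: pd.DataFrame) -> list[str]:
    return [c for c in sites.columns if c.startswith(COVARIATE_PREFIX)]


def generate_species(
    n_species: int,
    guild_mix: float = 0.5,
    skew_scenario: str = "mixed",
    seed: int = 0,
    sst_range: tuple[float, float] = config.SST_RANGE,
) -> list[SpeciesTruth]:
    """Generate species ground truths under a skew scenario.

    ``guild_mix`` is the fraction of tropical species (true T_opt > 23 °C);
    exactly ``round(n_species * guild_mix)`` species are tropical. Scenarios
    control the sigma asymmetry: ``symmetric`` sets sigma_min = sigma_max,
    ``warm_skew`` sets sigma_min > sigma_max (T_skew < 0), ``cool_skew`` the
    reverse. In the ``mixed`` scenario skewed species are additionally placed
    near the truncating end of the gradient (tropical warm-skew near the warm
    end, temperate cool-skew near the cool end), the mechanism by which
    skewed realised shapes arise in nature when niche space runs out.
    """
    if n_species < 1:
        raise ValueError(f"n_species must be >= 1, got {n_species}")
    if not 0.0 <= guild_mix <= 1.0:
        raise ValueError("guild_mix must be in [0, 1]")
    if skew_scenario not in SCENARIOS:
        raise ValueError(f"unknown skew_scenario {skew_scenario!r}; choose from {SCENARIOS}")

    rng = config.child_rng(seed, config.SEED_SPECIES)
    lo, hi = sst_range
    n_tropical = int(round(n_species * guild_mix))
    is_tropical = np.array([i < n_tropical for i in range(n_species)])

    out: list[SpeciesTruth] = []
    for i in range(n_species):
        tropical = bool(is_tropical[i])
        if skew_scenario == "mixed":
            # two thirds of each guild get the guild-typical skew
            scen = ("warm_skew" if tropical else "cool_skew") if rng.random() < 2 / 3 else "symmetric"
        else:
            scen = skew_scenario

        if scen == "symmetric":
            s = rng.uniform(1.5, 3.0)
            sigma_min = sigma_max = s
            topt = rng.uniform(23.5, hi - 3.5) if tropical else rng.uniform(11.0, 21.0)
        elif scen == "warm_skew":
            sigma_min = rng.uniform(2.5, 4.0)
            sigma_max = sigma_min * rng.uniform(0.35, 0.65)
            # near the warm end of the guild's range so the warm edge truncates
            topt = rng.uniform(hi - 3.0, hi - 0.5) if tropical else rng.uniform(20.0, 22.5)
        elif scen == "cool_skew":
            sigma_max = rng.uniform(2.5, 4.0)
            sigma_min = sigma_max * rng.uniform(0.35, 0.65)
            topt = rng.uniform(23.5, 25.5) if tropical else rng.uniform(lo + 0.5, lo + 3.5)
        else:  # pragma: no cover
            raise AssertionError(scen)

        order_i = int(rng.integers(0, 4))
        family_i = order_i * 3 + int(rng.integers(0, 3))
        genus_i = family_i * 2 + int(rng.integers(0, 2))
        pref_mag = rng.uniform(0.2, 1.0)
        out.append(
            SpeciesTruth(
                species_id=f"sp{i:04d}",
                order=f"ORD{order_i}",
                family=f"FAM{family_i}",
                genus=f"GEN{genus_i}",
                true_topt=float(topt),
                true_sigma_min=float(sigma_min),
                true_sigma_max=float(sigma_max),
                peak_lambda=float(rng.lognormal(mean=np.log(12.0), sigma=0.4)),
                zero_inflation_pi=float(rng.uniform(0.10, 0.30)),
                habitat_pref=float(pref_mag if tropical else -pref_mag),
                scenario=scen,
            )
        )
    return out


def split_gaussian_intensity(
    sst: np.ndarray, topt: float, sigma_min: float, sigma_max: float
) -> np.ndarray:
    """exp(-((T - T_opt)/sigma_side)^2) with the side-dependent scale."""
    sst = np.asarray(sst, dtype=float)
    sigma = np.where(sst < topt, sigma_min, sigma_max)
    return np.exp(-(((sst - topt) / sigma) ** 2))


def habitat_multiplier(pref: float, coral: np.ndarray, macro: np.ndarray) -> np.ndarray:
    """Bounded monotone link of habitat preference to cover difference."""
    return np.exp(pref * (np.asarray(coral) - np.asarray(macro)) / 100.0)


def expected_count(truth: SpeciesTruth, sites: pd.DataFrame) -> np.ndarray:
    """Poisson mean per site for one species (before zero inflation)."""
    lam = truth.peak_lambda * split_gaussian_intensity(
        sites["sst"].to_numpy(), truth.true_topt, truth.true_sigma_min, truth.true_sigma_max
    )
    return lam * habitat_multiplier(
        truth.habitat_pref, sites["coral_cover"].to_numpy(), sites["macroalgae_cover"].to_numpy()
    )


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(q, cum, v))


def true_shape_class(
    truth: SpeciesTruth,
    sites: pd.DataFrame,
    threshold: float = 0.75,
    edge_quantiles: tuple[float, float] = (0.025, 0.975),
) -> str:
    """Ground-truth shape class implied by a species' truth and the gradient.

    Computes the expected presence probability per site,
    ``(1 - pi) * (1 - exp(-lambda))``, takes the presence-weighted edge
    quantiles of site temperature, and applies the edge-drop rule to the
    true intensity curve. This is the label an ideal estimator should
    recover; it can differ from the sigma-asymmetry scenario tag when the
    gradient does not truncate the niche.
    """
    sst = sites["sst"].to_numpy(dtype=float)
    lam = expected_count(truth, sites)
    pres_prob = (1.0 - truth.zero_inflation_pi) * (1.0 - np.exp(-lam))
    if pres_prob.sum() <= 0:
        raise ValueError("species has no expected presences on this gradient")
    tmin = _weighted_quantile(sst, pres_prob, edge_quantiles[0])
    tmax = _weighted_quantile(sst, pres_prob, edge_quantiles[1])

    def intensity(t: float) -> float:
        return float(split_gaussian_intensity(
            np.array([t]), truth.true_topt, truth.true_sigma_min, truth.true_sigma_max
        )[0])

    peak = intensity(min(max(truth.true_topt, tmin), tmax))
    r_cool = intensity(tmin) / peak
    r_warm = intensity(tmax) / peak
    if r_cool >= threshold and r_warm >= threshold:
        return "no_trend"
    if r_cool < threshold and r_warm < threshold:
        return "abundant_centre"
    return "warm_skewed" if r_warm >= threshold else "cool_skewed"


def simulate_surveys(
    sites: pd.DataFrame,
    species: Sequence[SpeciesTruth],
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate zero-inflated Poisson counts for every species x site.

    Returns one row per species x site with integer ``count`` and an
    ``is_absence`` flag (count == 0). Counts are treated as already
    site-averaged densities per 500 m².
    """
    if len(sites) == 0 or len(species) == 0:
        raise ValueError("sites and species must be non-empty")
    rng = config.child_rng(seed, config.SEED_SURVEYS)
    n = len(sites)
    frames = []
    for truth in species:
        lam = expected_count(truth, sites)
        structural_zero = rng.random(n) < truth.zero_inflation_pi
        counts = rng.poisson(lam)
        counts[structural_zero] = 0
        frames.append(
            pd.DataFrame(
                {
                    "site_id": sites["site_id"].to_numpy(),
                    "species_id": truth.species_id,
                    "count": counts,
                    "is_absence": counts == 0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_community(
    n_sites: int = 500,
    n_species: int = 50,
    guild_mix: float = 0.5,
    skew_scenario: str = "mixed",
    covariate_sst_correlation: float = 0.6,
    seed: int = 0,
    sst_range: tuple[float, float] = config.SST_RANGE,
) -> tuple[pd.DataFrame, list[SpeciesTruth], pd.DataFrame]:
    """Convenience wrapper: sites, species truths and survey records."""
    sites = generate_sites(
        n_sites, sst_range=sst_range,
        covariate_sst_correlation=covariate_sst_correlation, seed=seed,
    )
    species = generate_species(
        n_species, guild_mix=guild_mix, skew_scenario=skew_scenario,
        seed=seed, sst_range=sst_range,
    )
    records = simulate_surveys(sites, species, seed=seed)
    return sites, species, records
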