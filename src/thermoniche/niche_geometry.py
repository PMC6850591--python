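"""Realised thermal-niche geometry per species.

Thermal edges T_min/T_max are the 2.5th and 97.5th empirical quantiles
(linear interpolation between order statistics) of temperatures at
occupied sites. Treating the edges as the 95% limits of a normal
distribution centred on T_opt gives the split-Gaussian scales

    sigma_min = |T_opt - T_min| / 1.96,   sigma_max = |T_max - T_opt| / 1.96,

and the skew statistic T_skew = sigma_max - sigma_min: negative means the
optimum sits nearer the warm edge (warm-skewed), positive nearer the cool
edge. Species are split into thermal guilds at 23 °C.

Note the magnitudes: the literal edge-minus-optimum difference for the
cool side is negative whenever T_min < T_opt, while the skew semantics
(centred distribution => skew 0) require non-negative scales, so absolute
distances are used throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import config

logger = logging.getLogger(__name__)


@dataclass
class ThermalProfile:
    species_id: str
    tmin: float
    tmax: float
    topt: float
    sigma_min: float
    sigma_max: float
    tskew: float
    guild: str
    coral_assoc: float
    macroalgae_assoc: float
    shape: object = None          # ShapeClass at the primary threshold
    shape_alt: object = None      # ShapeClass at the robustness threshold


def thermal_edges(presence_temperatures: np.ndarray,
                  quantiles: tuple[float, float] = config.EDGE_QUANTILES,
                  ) -> tuple[float, float]:
    """2.5th/97.5th empirical quantiles of occupied-site temperatures."""
    t = np.asarray(presence_temperatures, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("need >= 2 distinct temperatures")
    lo, hi = np.quantile(t, quantiles, method="linear")
    return float(lo), float(hi)


def sigmas_from_edges(topt: float, tmin: float, tmax: float,
                      z: float = config.Z_SCORE) -> tuple[float, float]:
    """Split-Gaussian scales from the edges; absolute distances over z.

    If T_opt falls outside [T_min, T_max] it is clamped to the nearer edge
    and the corresponding sigma is 0 (logged, degenerate one-sided niche).
    """
    if not tmin <= tmax:
        raise ValueError("tmin must be <= tmax")
    if topt < tmin or topt > tmax:
        logger.info("topt %.3f outside [%.3f, %.3f]; clamped", topt, tmin, tmax)
        topt = min(max(topt, tmin), tmax)
    return abs(topt - tmin) / z, abs(tmax - topt) / z


def tskew(sigma_min: float, sigma_max: float) -> float:
    """sigma_max - sigma_min; negative = warm-skewed, positive = cool-skewed."""
    if sigma_min < 0 or sigma_max < 0:
        raise ValueError("sigmas must be >= 0")
    return sigma_max - sigma_min


def assign_guild(topt: float, cutoff: float = config.GUILD_CUTOFF_C) -> str:
    """'temperate' below the cutoff, 'tropical' at or above it."""
    if not np.isfinite(topt):
        raise ValueError("topt must be finite")
    return "temperate" if topt < cutoff else "tropical"


def habitat_association(frame: pd.DataFrame, cover_column: str) -> float:
    """Abundance-weighted mean cover at presences minus background mean.

    Positive values indicate the species concentrates its abundance in
    sites richer in that habitat than the average surveyed site of its
    frame. Missing cover data yields NaN.
    """
    if cover_column not in frame.columns or frame[cover_column].isna().all():
        logger.warning("no %s data; association recorded as missing", cover_column)
        return float("nan")
    pres = frame[~frame["is_absence"]]
    w = pres["abundance"].to_numpy(dtype=float)
    if w.sum() <= 0:
        return float("nan")
    weighted = float(np.average(pres[cover_column].to_numpy(dtype=float), weights=w))
    background = float(frame[cover_column].mean())
    return weighted - background


def build_profile(
    species_id: str,
    frame: pd.DataFrame,
    topt: float,
    shape=None,
    shape_alt=None,
    z: float = config.Z_SCORE,
    guild_cutoff: float = config.GUILD_CUTOFF_C,
) -> ThermalProfile:
    """Assemble the full niche geometry of one species from its frame."""
    pres_t = frame.loc[~frame["is_absence"], "sst"].to_numpy()
    tmin, tmax = thermal_edges(pres_t)
    s_min, s_max = sigmas_from_edges(topt, tmin, tmax, z=z)
    return ThermalProfile(
        species_id=species_id,
        tmin=tmin,
        tmax=tmax,
        topt=float(min(max(topt, tmin), tmax)),
        sigma_min=s_min,
        sigma_max=s_max,
        tskew=tskew(s_min, s_max),
        guild=assign_guild(topt, cutoff=guild_cutoff),
        coral_assoc=habitat_association(frame, "coral_cover"),
        macroalgae_assoc=habitat_association(frame, "macroalgae_cover"),
        shape=shape,
        shape_alt=shape_alt,
    )


def profiles_to_frame(profiles: list[ThermalProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "species_id": p.species_id,
                "tmin": p.tmin,
                "tmax": p.tmax,
                "topt": p.topt,
                "sigma_min": p.sigma_min,
                "sigma_max": p.sigma_max,
                "tskew": p.tskew,
                "guild": p.guild,
                "coral_assoc": p.coral_assoc,
                "macroalgae_assoc": p.macroalgae_assoc,
                "shape": getattr(p.shape, "label", None),
                "shape_alt": getattr(p.shape_alt, "label", None),
            }
        )
    return pd.DataFrame(rows)
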