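"""End-to-end orchestration: records -> profiles -> pooled/skew inputs.

Thin glue over the analysis modules, used by the CLI, the test-suite and
reproduction scripts. Each step is an ordinary function call on the
module APIs; nothing here adds statistical behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import config, survey_prep, quantile_peak, niche_geometry
from .synthetic_data import covariate_columns

logger = logging.getLogger(__name__)


@dataclass
class SpeciesResult:
    species_id: str
    estimate: quantile_peak.ToptEstimate
    profile: niche_geometry.ThermalProfile
    frame: pd.DataFrame = field(repr=False, default=None)


def prepare_frames(
    records: pd.DataFrame,
    sites: pd.DataFrame,
    buffer_radius_deg: float = 10.0,
    min_records: int = config.MIN_RECORDS,
    min_thermal_range_C: float = config.MIN_THERMAL_RANGE_C,
) -> dict[str, pd.DataFrame]:
    """Absence construction, frame assembly, eligibility filtering."""
    with_abs = survey_prep.derive_absences(records, sites, buffer_radius_deg)
    frames = survey_prep.make_frames(with_abs, sites)
    frames = survey_prep.filter_species(frames, min_records, min_thermal_range_C)
    for sp, frame in frames.items():
        frame["sampling_intensity"] = survey_prep.sampling_intensity(frame)
    return frames


def analyse_species(
    species_id: str,
    frame: pd.DataFrame,
    covariate_cols: list[str],
    n_boot: int = config.N_BOOTSTRAP,
    seed: int = 0,
) -> SpeciesResult:
    """Bootstrap T_opt, then the full niche geometry and shape classes."""
    est = quantile_peak.bootstrap_topt(frame, covariate_cols, n_boot=n_boot, seed=seed)
    pres_t = frame.loc[~frame["is_absence"], "sst"].to_numpy()
    tmin, tmax = niche_geometry.thermal_edges(pres_t)
    shape = quantile_peak.classify_shape(est.curve, tmin, tmax, config.SHAPE_THRESHOLD)
    shape_alt = quantile_peak.classify_shape(est.curve, tmin, tmax, config.SHAPE_THRESHOLD_ALT)
    profile = niche_geometry.build_profile(
        species_id, frame, est.topt, shape=shape, shape_alt=shape_alt
    )
    return SpeciesResult(species_id, est, profile, frame)


def run_community(
    records: pd.DataFrame,
    sites: pd.DataFrame,
    n_boot: int = config.N_BOOTSTRAP,
    seed: int = 0,
    buffer_radius_deg: float = 10.0,
) -> dict[str, SpeciesResult]:
    """Per-species analysis for every species passing the filters."""
    frames = prepare_frames(records, sites, buffer_radius_deg)
    cov_cols = covariate_columns(sites)
    results: dict[str, SpeciesResult] = {}
    for i, (sp, frame) in enumerate(frames.items()):
        try:
            results[sp] = analyse_species(sp, frame, cov_cols, n_boot=n_boot, seed=seed + i)
        except Exception as exc:  # noqa: BLE001 - skip pathological species
            logger.warning("species %s failed: %s", sp, exc)
    return results


def profiles_frame(results: dict[str, SpeciesResult]) -> pd.DataFrame:
    """One ThermalProfile row per analysed species, taxonomy-free."""
    return niche_geometry.profiles_to_frame([r.profile for r in results.values()])


def one_stage_topt(frame: pd.DataFrame, seed: int = 0,
                   n_grid: int = 200) -> float:
    """T_opt from a single-stage fit: raw abundance vs temperature.

    Skips residualization entirely (no covariate adjustment); used as a
    robustness comparison against the two-stage estimate.
    """
    import numpy as np

    sub = survey_prep.balance_absences(frame, seed=seed)
    curve = quantile_peak.fit_quantile_spline(
        sub["sst"].to_numpy(), sub["abundance"].to_numpy(dtype=float), seed=seed,
        knot_x=sub.loc[~sub["is_absence"], "sst"].to_numpy(),
    )
    pres = frame.loc[~frame["is_absence"], "sst"]
    grid = np.linspace(pres.min(), pres.max(), n_grid)
    return quantile_peak._argmax_lowest(grid, curve.predict(grid))


def pooled_inputs(results: dict[str, SpeciesResult], guild: str | None = None) -> pd.DataFrame:
    """Standardised + binned maxima across species, ready for the pooled fit."""
    from . import pooled_shape

    pts = []
    for r in results.values():
        if guild is not None and r.profile.guild != guild:
            continue
        if r.profile.sigma_min + r.profile.sigma_max <= 0:
            logger.warning("species %s has zero niche width; excluded", r.species_id)
            continue
        pts.append(pooled_shape.standardize(r.frame, r.profile))
    if not pts:
        raise ValueError("no species available for the pooled model")
    return pooled_shape.bin_q99(pd.concat(pts, ignore_index=True))
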