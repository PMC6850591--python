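"""Turn raw survey records into per-species modelling frames.

Absences are not recorded by visual-census surveys; they are constructed:
a species is assigned zero abundance at a surveyed site if it was not seen
there but was seen at another site within a 10-degree latitude/longitude
buffer. Species with too few records or too narrow an observed thermal
range are dropped, and absences are down-sampled to the number of
presences so they cannot overwhelm the abundance signal.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import config

logger = logging.getLogger(__name__)


def derive_absences(
    records: pd.DataFrame,
    sites: pd.DataFrame,
    buffer_radius_deg: float = 10.0,
) -> pd.DataFrame:
    """Add zero-count rows inside each species' spatial buffer.

    Only rows with ``count > 0`` in ``records`` are treated as observations;
    any existing zero rows are discarded and regenerated, which makes the
    operation idempotent. Distance is planar Euclidean in degrees, matching
    the degree-space buffer definition.
    """
    if buffer_radius_deg <= 0:
        raise ValueError("buffer_radius_deg must be > 0")
    presences = records[records["count"] > 0]
    coords = sites.set_index("site_id")[["latitude", "longitude"]]
    all_xy = coords.to_numpy()
    site_ids = coords.index.to_numpy()

    out = []
    for species_id, grp in presences.groupby("species_id", sort=True):
        present_ids = grp["site_id"].unique()
        if len(present_ids) == 0:  # pragma: no cover - groupby yields none
            continue
        pres_xy = coords.loc[present_ids].to_numpy()
        # site is a candidate absence if within radius of >= 1 presence site
        d2 = ((all_xy[:, None, :] - pres_xy[None, :, :]) ** 2).sum(axis=2)
        within = (d2 <= buffer_radius_deg**2).any(axis=1)
        absent_mask = within & ~np.isin(site_ids, present_ids)
        absence_ids = site_ids[absent_mask]
        out.append(grp.assign(is_absence=False))
        if len(absence_ids):
            out.append(
                pd.DataFrame(
                    {
                        "site_id": absence_ids,
                        "species_id": species_id,
                        "count": 0,
                        "is_absence": True,
                    }
                )
            )
    dropped = set(records["species_id"].unique()) - set(presences["species_id"].unique())
    for sp in sorted(dropped):
        logger.warning("species %s has no presences anywhere; excluded", sp)
    if not out:
        return records.iloc[0:0]
    return pd.concat(out, ignore_index=True)


def make_frames(records: pd.DataFrame, sites: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Join site predictors onto records, one modelling frame per species."""
    merged = records.merge(sites, on="site_id", how="left", validate="many_to_one")
    merged = merged.rename(columns={"count": "abundance"})
    return {sp: grp.reset_index(drop=True) for sp, grp in merged.groupby("species_id", sort=True)}


def filter_species(
    frames: dict[str, pd.DataFrame],
    min_records: int = config.MIN_RECORDS,
    min_thermal_range_C: float = config.MIN_THERMAL_RANGE_C,
) -> dict[str, pd.DataFrame]:
    """Keep species with enough presences over a wide enough thermal range.

    Inclusive at the thresholds: >= ``min_records`` presence rows and an
    observed presence SST range >= ``min_thermal_range_C``.
    """
    kept = {}
    for sp, frame in frames.items():
        pres = frame[~frame["is_absence"]]
        if len(pres) < min_records:
            continue
        sst = pres["sst"]
        if sst.max() - sst.min() < min_thermal_range_C:
            continue
        kept[sp] = frame
    return kept


def balance_absences(frame: pd.DataFrame, seed: int = 0, replicate: int = 0) -> pd.DataFrame:
    """Subsample absences (without replacement) down to the presence count.

    Presence rows are never altered. Deterministic for a given
    (seed, replicate) pair; ``replicate`` indexes bootstrap resamples.
    """
    pres = frame[~frame["is_absence"]]
    absn = frame[frame["is_absence"]]
    if len(absn) <= len(pres):
        return frame
    rng = config.child_rng(seed, config.SEED_BALANCE, replicate)
    keep = rng.choice(len(absn), size=len(pres), replace=False)
    return pd.concat([pres, absn.iloc[np.sort(keep)]], ignore_index=True)


def sampling_intensity(frame: pd.DataFrame) -> float:
    """Survey sites per degree of temperature across the species' range."""
    sst = frame["sst"]
    span = float(sst.max() - sst.min())
    if span <= 0:
        raise ValueError("zero thermal range; species should have been filtered")
    return frame["site_id"].nunique() / span
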