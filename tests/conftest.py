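import logging

import numpy as np
import pandas as pd
import pytest

import thermoniche as tn

logging.getLogger("thermoniche").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_community():
    """A modest synthetic community shared across read-only tests."""
    sites, species, records = tn.simulate_community(
        n_sites=400, n_species=12, guild_mix=0.5, skew_scenario="mixed", seed=7
    )
    return sites, species, records


@pytest.fixture(scope="session")
def prepared_frames(small_community):
    sites, species, records = small_community
    presences = records[records["count"] > 0]
    return tn.prepare_frames(presences, sites)


def make_frame(sst, abundance, is_absence=None, **extra):
    """Hand-build a minimal modelling frame for unit tests."""
    sst = np.asarray(sst, dtype=float)
    abundance = np.asarray(abundance, dtype=float)
    if is_absence is None:
        is_absence = abundance == 0
    n = len(sst)
    base = {
        "site_id": [f"S{i}" for i in range(n)],
        "sst": sst,
        "abundance": abundance,
        "is_absence": np.asarray(is_absence, dtype=bool),
    }
    base.update(extra)
    return pd.DataFrame(base)
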