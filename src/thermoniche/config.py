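"""Shared configuration: defaults and the random-number protocol.

All stochastic operations take a single integer seed. Internally a master
seed is expanded into independent child streams through
:func:`child_rng` using fixed, documented offsets, so that adding a new
consumer of randomness never perturbs existing streams.
"""

from __future__ import annotations

import numpy as np

# --- fixed child-stream offsets (never renumber) ---------------------------
SEED_SITES = 1
SEED_SPECIES = 2
SEED_SURVEYS = 3
SEED_BALANCE = 4          # absence balancing; per-bootstrap replicate adds its index
SEED_SPLINE_CV = 5
SEED_PERMUTATION = 6
SEED_MCMC = 7

# --- scientific defaults ----------------------------------------------------
SST_RANGE = (5.0, 30.0)            # °C, span of the simulated thermal gradient
GUILD_CUTOFF_C = 23.0              # °C, temperate/tropical split
HABITAT_TRANSITION_C = 23.0        # °C, coral -> macroalgae crossover
EDGE_QUANTILES = (0.025, 0.975)    # realised thermal edges
Z_SCORE = 1.96                     # edge-to-sigma conversion
QUANTILE_TAU = 0.8                 # quantile level of the abundance ceiling
SPLINE_BASIS_DIM = 4               # regression-spline degrees of freedom
N_BOOTSTRAP = 25                   # absence-subset replicates
MIN_RECORDS = 30                   # species eligibility: presence records
MIN_THERMAL_RANGE_C = 3.0          # species eligibility: observed range
SHAPE_THRESHOLD = 0.75             # edge drop threshold for shape classes
SHAPE_THRESHOLD_ALT = 0.50         # robustness threshold
PCA_RETENTION = 0.10               # keep axes explaining > this fraction
MANTEL_PERMUTATIONS = 999
EFFECT_TEST_PERMUTATIONS = 199
BIN_WIDTH = 0.1                    # standardised-temperature bin width
BIN_PCT = 0.99                     # within-bin abundance percentile
MCMC_CHAINS = 4
MCMC_ITERATIONS = 10_000
MCMC_BURN_IN = 2_500
MCMC_THIN = 5
RHAT_LIMIT = 1.01


def child_rng(seed: int, offset: int, index: int = 0) -> np.random.Generator:
    """Return an independent Generator for stream ``offset`` of ``seed``.

    ``index`` distinguishes repeated draws within one stream (e.g. bootstrap
    replicates). Streams are derived with ``SeedSequence`` spawn keys, so
    they are statistically independent and reproducible.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(offset), int(index)))
    return np.random.default_rng(ss)
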