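"""Shared fixtures: trained networks are expensive, so they are session-scoped.

Training seeds and evaluation seeds are fixed constants so the suite is
deterministic run to run.
"""

import pytest

from cxheading import TrainingConfig, build_columnar_mask, optimize, optimize_cl1a_tb1_map

TRAIN_SEED = 1


@pytest.fixture(scope="session")
def mask():
    return build_columnar_mask()


@pytest.fixture(scope="session")
def trained_weights(mask):
    """Joint-modulation network trained at package defaults."""
    weights, _ = optimize(mask, seed=TRAIN_SEED)
    return weights


@pytest.fixture(scope="session")
def trained_variants(mask, trained_weights):
    """Joint plus CL1a-only and CL2-only re-optimised networks."""
    out = {"both": trained_weights}
    for pop in ("cl1a", "cl2"):
        ws, _ = optimize(
            mask, seed=TRAIN_SEED, config=TrainingConfig(modulated_population=pop)
        )
        out[pop] = ws
    return out


@pytest.fixture(scope="session")
def steering_interface():
    return optimize_cl1a_tb1_map(seed=0)
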