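import numpy as np
import pandas as pd
import pytest

from crossformat import (
    BinnedRates,
    archetype_population,
    bin_rates,
    make_design,
    simulate_spikes,
)


@pytest.fixture(scope="session")
def main_session():
    """A small main-task session with a planted mixed population."""
    design, trials = make_design("main", reps_per_condition=6, seed=1)
    specs = archetype_population(
        {"shared_action3": 10, "shared_hand": 6, "single_intention": 4, "unselective": 4},
        seed=2,
        effect_size=25.0,
        observation_gain=1.0,
    )
    spikes, gt = simulate_spikes(design, trials, specs, seed=3)
    rates = bin_rates(spikes, design)
    return {"design": design, "trials": trials, "spikes": spikes, "rates": rates, "specs": specs, "gt": gt}


def rates_from_values(values: np.ndarray, bin_width: float = 0.1, t0: float = 0.0) -> BinnedRates:
    """Wrap a raw (units x trials x bins) array as BinnedRates for direct
    constructions of deterministic response patterns."""
    n_bins = values.shape[2]
    centers = t0 + bin_width * (np.arange(n_bins) + 0.5)
    return BinnedRates(
        values=np.asarray(values, dtype=float),
        bin_centers_s=centers,
        bin_width_s=bin_width,
        window_s=(t0, t0 + n_bins * bin_width),
        unit_ids=np.array([f"u{i:04d}" for i in range(values.shape[0])]),
    )
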