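import sys
from pathlib import Path

import matplotlib
import pytest

matplotlib.use("Agg")

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from wprdm import synthetic_data as sd  # noqa: E402
from wprdm.wpr_inference import MCMCConfig  # noqa: E402


@pytest.fixture(scope="session")
def small_scenario():
    """A compact population with the WPR-generating structure."""
    cfg = sd.scenario_config(
        "wpr_true",
        n_participants=60,
        trials_easy=60,
        trials_hard=60,
        trials_undoable=20,
        seed=101,
    )
    trials, wmc, truth = sd.generate_population(cfg)
    trials = sd.apply_contamination_and_censoring(trials, cfg)
    return cfg, trials, wmc, truth


@pytest.fixture
def fast_wpr_mcmc():
    """Shortened ensemble run for pipeline-level tests."""
    return MCMCConfig(steps=300, burn=300, rhat_threshold=1.1)
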