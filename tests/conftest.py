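"""Shared fixtures.

The scaled power-study experiment (20 forward replicates plus joint
segmented fits) is expensive, so the replicate histories are simulated
once per session and both observation designs are scored against the
same histories.
"""

import numpy as np
import pytest

from fluctsel import evaluation as ev
from fluctsel import simulate as sim


@pytest.fixture(scope="session")
def fig1_trajectories():
    """Twenty desk-scale replicate histories of the three-period design."""
    cfg = ev.desk_simulation_config()
    ss = np.random.SeedSequence(1)
    return [
        sim.simulate_replicate(cfg, np.random.default_rng(child), replicate_id=i)
        for i, child in enumerate(ss.spawn(20))
    ]


@pytest.fixture(scope="session")
def fig1_c200(fig1_trajectories):
    """Continuous-sampling scenario, h=0.5, n=200, k up to 4."""
    spec = ev.legend_scenarios(scale="desk", replicates=20)["c200"]
    return ev.run_scenario(spec, seed=1, trajectories=fig1_trajectories)


@pytest.fixture(scope="session")
def fig1_c70(fig1_trajectories):
    """The n=70 variant of the same histories, k up to 2 (enough to score success)."""
    spec = ev.legend_scenarios(scale="desk", replicates=20)["c70"]
    spec = ev.ScenarioSpec(**{**spec.__dict__, "k_max": 2})
    return ev.run_scenario(spec, seed=2, trajectories=fig1_trajectories)


def bic_choice_up_to(record, k_cap):
    """Breakpoint count chosen by BIC restricted to k <= k_cap."""
    scores = {k: v[1] for k, v in record["model_scores"].items() if k <= k_cap}
    return min(scores, key=scores.get)
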