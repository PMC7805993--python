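"""Shared fixtures: small hand-built summaries and the measurement ensemble."""

from __future__ import annotations

import numpy as np
import pytest

import swarmopinion as sw
from swarmopinion.pipeline import collect_ensemble


def make_summary(
    n_agents: int = 150,
    window: tuple[int, int] = (0, 1),
    delta_s_before=(),
    delta=(),
    local_s=(),
    local_frac=(),
    local_opinion=(),
    rev_s=(),
    rev_old=(),
    rev_new=(),
) -> sw.RunSummary:
    """A RunSummary built from explicit sample arrays (test scaffolding)."""
    return sw.RunSummary(
        window=window,
        n_agents=n_agents,
        delta_s_before=np.asarray(delta_s_before, float),
        delta=np.asarray(delta, float),
        local_s=np.asarray(local_s, float),
        local_frac=np.asarray(local_frac, float),
        local_opinion=np.asarray(local_opinion, np.int64),
        rev_s=np.asarray(rev_s, float),
        rev_old=np.asarray(rev_old, np.int64),
        rev_new=np.asarray(rev_new, np.int64),
    )


@pytest.fixture(scope="session")
def abm_ensemble():
    """Reduced-scale measurement ensemble of the mobile-agent scenario.

    Study design: N = 150, gamma = 0.2, 1000 iterations with the final
    100 as measurement window; 13 initial A-fractions spanning [0.02,
    0.98] at 20 runs each, plus 100 extra runs at each of four extreme
    initial fractions so the tail bins of the state axis carry enough
    samples to resolve systematic model error there.
    """
    window = (900, 1000)
    cfg = sw.SwarmConfig(n_iterations=1000, gamma=0.2, seed=0)
    summaries = collect_ensemble(
        cfg, 20, s0_values=np.linspace(0.02, 0.98, 13), window=window
    )
    summaries += collect_ensemble(
        cfg.replace(seed=1), 100, s0_values=[0.02, 0.05, 0.95, 0.98], window=window
    )
    bin_width = 1.0 / 50.0
    return {
        "window": window,
        "window_length": window[1] - window[0],
        "bin_width": bin_width,
        "gamma": cfg.gamma,
        "delta": sw.delta_profile(summaries, window, bin_width),
        "local": sw.local_state_profile(summaries, window, bin_width),
        "revisions": sw.revision_counts(summaries, window, bin_width),
    }
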