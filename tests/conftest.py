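"""Shared fixtures.

The heavier fixtures run full 16 s simulation batches once per session
and are shared between the unit suite and the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from callosim import (
    CouplingSpec,
    SimulationSpec,
    StimulusSpec,
    integrate_batch,
    k_sweep,
    run_trial_protocol,
)


def trial_seeds(master: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


@pytest.fixture(scope="session")
def single_column_trials():
    """Ten independently seeded 16 s uncoupled trials per band preset."""
    out = {}
    for i, band in enumerate(("LB", "MB", "HB")):
        out[band] = integrate_batch(
            band,
            CouplingSpec(K=0.0),
            StimulusSpec(),
            SimulationSpec(),
            seeds=trial_seeds(100 + i, 10),
        )
    return out


@pytest.fixture(scope="session")
def strong_coupling_trials():
    """Twenty 16 s two-column LB trials at K = 70 (winner-take-all)."""
    return integrate_batch(
        ("LB", "LB"),
        CouplingSpec(K=70.0),
        StimulusSpec(),
        SimulationSpec(),
        seeds=trial_seeds(200, 20),
    )


@pytest.fixture(scope="session")
def region_sweeps():
    """Reduced K sweeps (step 2, 5 trials per K), three independent
    master seeds per band.  Near the winner-take-all onset the escape
    within one 16 s trial is a first-passage event, so a single sweep's
    boundary estimate carries seed noise; the criterion uses the median
    across master seeds."""
    grids = {"HB": np.arange(0.0, 41.0, 2.0), "LB": np.arange(0.0, 61.0, 2.0)}
    return {
        band: [
            k_sweep(band, grid, SimulationSpec(master_seed=300 + 10 * i + j), 5)
            for j in range(3)
        ]
        for i, (band, grid) in enumerate(grids.items())
    }


@pytest.fixture(scope="session")
def imagery_protocols():
    """Trial-averaged ERD/ERS curves for LB at K_H, K_L and K = 0."""
    return {
        K: run_trial_protocol(
            "LB", K, n_trials=20, sim=SimulationSpec(master_seed=400), hop_s=0.05
        )
        for K in (10.0, 26.0, 0.0)
    }
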