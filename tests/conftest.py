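"""Shared fixtures: the full-length simulated measurements are expensive, so
they are produced once per session and reused across tests."""

import numpy as np
import pytest

import rafttrace as rt
from rafttrace.pipeline import stage_seed

N_FRAMES = 20_000
N_SEEDS = 5
BINNINGS = (1, 2, 3, 4, 5)


def run_measurement(mode: str, replicate: int):
    """Simulate one full measurement and fit its diffusion law."""
    seed = stage_seed(1, f"{mode}{replicate}")
    cfg = rt.SimulationConfig(mode=mode, n_steps=N_FRAMES, seed=seed)
    traj = rt.simulate_trajectories(cfg)
    stack = rt.render_stack(traj, rt.OpticsCameraConfig(n_frames=N_FRAMES,
                                                        seed=seed + 1))
    points = rt.build_diffusion_law(stack, BINNINGS)
    return stack, rt.DiffusionLaw(points).fit()


@pytest.fixture(scope="session")
def free_measurement():
    """One free-diffusion measurement at D = 1 μm²/s (stack + law fit)."""
    return run_measurement("free", 0)


@pytest.fixture(scope="session")
def mode_law_fits(free_measurement):
    """Diffusion-law fits for N_SEEDS replicates of each diffusion regime."""
    fits = {"free": [free_measurement[1]], "domain": [], "hop": []}
    for mode in ("free", "domain", "hop"):
        start = 1 if mode == "free" else 0
        for k in range(start, N_SEEDS):
            fits[mode].append(run_measurement(mode, k)[1])
    return fits
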