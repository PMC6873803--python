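"""2D membrane-diffusion simulations: free, domain-confined, and hop regimes.

The simulator produces particle trajectories in a periodic square box.
Three regimes are supported, mirroring the phenomenology that an FCS
diffusion-law experiment distinguishes:

``free``
    homogeneous Brownian motion with diffusivity ``D_out``;
``domain``
    quasi-static, non-overlapping circular domains (interior diffusivity
    ``D_in``) whose boundaries are permeable with probabilities ``P_enter``
    (outside→in) and ``P_exit`` (inside→out) — hindered, trap-like diffusion;
``hop``
    a square meshwork of side ``mesh_side`` whose compartment boundaries are
    crossed with probability ``P_hop`` — cytoskeleton-fence hop diffusion.

Rejected boundary crossings are reflected.  All randomness flows from the
config seed through one `numpy.random.Generator`, so identical configs give
bitwise-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernels

__all__ = ["SimulationConfig", "TrajectorySet", "simulate_trajectories", "time_averaged_msd"]


class ConfigurationError(ValueError):
    """A simulation or rendering parameter is non-physical."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a 2D membrane-diffusion simulation.

    Lengths in μm, times in s, diffusivities in μm²/s.
    """

    box_side: float = 11.52   # 3× the default 16-pixel ROI; see docs/methods.md
    n_particles: int = 1350   # ≈10.2 particles/μm²
    D_out: float = 1.0
    mode: str = "free"                   # free | domain | hop
    domain_radius: float = 0.1
    domain_area_fraction: float = 0.20
    D_in: float = 0.1
    P_enter: float = 0.1
    P_exit: float = 0.05
    mesh_side: float = 0.8
    P_hop: float = 0.025
    dt: float = 3e-3
    n_steps: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        positive = ["box_side", "n_particles", "dt", "n_steps"]
        if self.mode == "domain":
            positive += ["domain_radius"]
        if self.mode == "hop":
            positive += ["mesh_side"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("D_out", "D_in"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("P_enter", "P_exit", "P_hop", "domain_area_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.mode not in ("free", "domain", "hop"):
            raise ConfigurationError(f"mode must be free|domain|hop, got {self.mode!r}")
        if self.mode == "domain" and 2 * self.domain_radius >= self.box_side:
            raise ConfigurationError("domain_radius must be smaller than half the box")


@dataclass
class TrajectorySet:
    """Simulated particle paths.

    ``positions`` are wrapped into [0, box_side); ``unwrapped`` carries the
    continuous paths used for mean-square-displacement analysis.  Shapes are
    (n_steps + 1, n_particles, 2).
    """

    positions: np.ndarray
    unwrapped: np.ndarray
    dt: float
    box_side: float
    config: SimulationConfig
    domain_centers: Optional[np.ndarray] = None

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0] - 1


def _place_domains(rng: np.random.Generator, box: float, radius: float,
                   area_fraction: float) -> np.ndarray:
    """Rejection-sample non-overlapping circle centers (periodic metric)."""
    if area_fraction == 0:
        return np.empty((0, 2))
    n_target = int(round(area_fraction * box**2 / (np.pi * radius**2)))
    n_target = max(n_target, 1)
    centers: list[np.ndarray] = []
    attempts = 0
    max_attempts = 20_000 * n_target
    while len(centers) < n_target:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigurationError(
                f"domain_area_fraction {area_fraction} with domain_radius {radius} "
                f"could not be packed into the box (placed {len(centers)}/{n_target})")
        c = rng.uniform(0.0, box, size=2)
        ok = True
        for other in centers:
            d = (c - other + box / 2) % box - box / 2
            if d @ d < (2 * radius) ** 2:
                ok = False
                break
        if ok:
            centers.append(c)
    return np.asarray(centers)


def simulate_trajectories(config: SimulationConfig) -> TrajectorySet:
    """Run the Brownian-dynamics simulation described by ``config``."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n, p = config.n_steps, config.n_particles
    start = rng.uniform(0.0, config.box_side, size=(p, 2))

    centers = None
    if config.mode == "free":
        sigma = np.sqrt(2.0 * config.D_out * config.dt)
        steps = rng.standard_normal((n, p, 2)) * sigma
        unwrapped = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    elif config.mode == "domain":
        centers = _place_domains(rng, config.box_side, config.domain_radius,
                                 config.domain_area_fraction)
        normals = rng.standard_normal((n, p, 2))
        uniforms = rng.random((n, p))
        unwrapped = _kernels.domain_walk(
            start, normals, uniforms, config.box_side, centers,
            config.domain_radius, config.D_in, config.D_out,
            config.P_enter, config.P_exit, config.dt)
    else:  # hop
        normals = rng.standard_normal((n, p, 2))
        uniforms = rng.random((n, p))
        unwrapped = _kernels.hop_walk(
            start, normals, uniforms, config.box_side, config.mesh_side,
            config.D_out, config.P_hop, config.dt)

    positions = unwrapped % config.box_side
    return TrajectorySet(positions=positions, unwrapped=unwrapped, dt=config.dt,
                         box_side=config.box_side, config=replace(config),
                         domain_centers=centers)


def time_averaged_msd(traj: TrajectorySet, max_lag: Optional[int] = None) -> tuple[np.ndarray, np.ndarray]:
    """Time- and ensemble-averaged MSD(Δ) from the unwrapped paths.

    Returns (lag times s, MSD μm²) for integer lags 1..max_lag
    (default: 10% of the trace).
    """
    n = traj.n_steps
    if max_lag is None:
        max_lag = max(n // 10, 1)
    lags = np.arange(1, max_lag + 1)
    u = traj.unwrapped
    msd = np.empty(max_lag)
    for i, k in enumerate(lags):
        d = u[k:] - u[:-k]
        msd[i] = np.mean(np.sum(d * d, axis=-1))
    return lags * traj.dt, msd
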