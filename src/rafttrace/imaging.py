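"""Render trajectories into EMCCD-like image stacks and read/write TIFF.

The camera model is the standard EMCCD cascade: expected photons per pixel
(Gaussian-PSF integral per emitter plus uniform background) → Poisson shot
noise → gamma-distributed electron-multiplication gain (shape = photon
count, scale = em_gain) → additive Gaussian read noise.  With em_gain = 1
and read_noise_sd = 0 the stack is purely shot-noise limited, and with
Poisson sampling disabled entirely the expected image is returned — both
degenerate settings are exercised by the test suite.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from . import _kernels
from .simulate import ConfigurationError, TrajectorySet

__all__ = ["OpticsCameraConfig", "ImageStack", "render_stack", "expected_image",
           "write_stack", "read_stack"]


@dataclass(frozen=True)
class OpticsCameraConfig:
    """Microscope and camera parameters for stack rendering.

    ``omega0`` is the 1/e² radius of the Gaussian PSF and ``a`` the pixel
    side, both in the sample plane (μm).  The defaults mirror a 24 μm camera
    pixel behind a 100× objective with a PSF matched to the pixel size.
    """

    omega0: float = 0.24
    a: float = 0.24
    roi: tuple[int, int] = (16, 16)          # (rows, cols)
    exposure: float = 3e-3                   # s
    n_frames: int = 20_000
    counts_per_molecule_per_frame: float = 300.0
    background_per_pixel_per_frame: float = 20.0
    em_gain: float = 1.0
    read_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("omega0", "a", "exposure"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_frames < 2:
            raise ConfigurationError(f"n_frames must be >= 2, got {self.n_frames}")
        if min(self.roi) < 1:
            raise ConfigurationError(f"roi must be positive, got {self.roi}")
        if self.counts_per_molecule_per_frame < 0 or self.background_per_pixel_per_frame < 0:
            raise ConfigurationError("photon rates must be >= 0")
        if self.em_gain < 1 or self.read_noise_sd < 0:
            raise ConfigurationError("em_gain must be >= 1 and read_noise_sd >= 0")


@dataclass
class ImageStack:
    """frames × H × W photon-count array plus the optics metadata needed
    for correlation analysis (pixel size, PSF radius, frame time)."""

    frames: np.ndarray
    a: float
    omega0: float
    exposure: float
    optics: Optional[OpticsCameraConfig] = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def expected_image(traj: TrajectorySet, optics: OpticsCameraConfig) -> np.ndarray:
    """Noise-free expected counts per frame (PSF deposition + background)."""
    h, w = optics.roi
    if h * optics.a > traj.box_side + 1e-12 or w * optics.a > traj.box_side + 1e-12:
        raise ConfigurationError(
            f"ROI {optics.roi} at pixel size {optics.a} μm exceeds the "
            f"{traj.box_side} μm simulation box")
    substeps = int(round(optics.exposure / traj.dt))
    if substeps < 1 or abs(substeps * traj.dt - optics.exposure) > 1e-9 * optics.exposure:
        raise ConfigurationError(
            f"trajectory dt {traj.dt} must divide the exposure {optics.exposure}")
    n_box = int(round(traj.box_side / optics.a))
    if abs(n_box * optics.a - traj.box_side) > 1e-9 * traj.box_side:
        raise ConfigurationError(
            f"box_side {traj.box_side} must be an integer multiple of the "
            f"pixel size {optics.a}")
    n_samples = optics.n_frames * substeps
    if n_samples > traj.n_steps + 1:
        raise ConfigurationError(
            f"trajectory too short: need {n_samples} samples, have {traj.n_steps + 1}")
    expected = _kernels.deposit_psf(
        traj.positions[:n_samples], substeps, optics.a, optics.omega0,
        h, w, traj.box_side, optics.counts_per_molecule_per_frame)
    expected += optics.background_per_pixel_per_frame
    return expected


def render_stack(traj: TrajectorySet, optics: OpticsCameraConfig,
                 noise: bool = True) -> ImageStack:
    """Image a trajectory set through the PSF onto the (noisy) camera.

    With ``noise=False`` the expected image is returned (no Poisson, gain or
    read noise), which is the configuration the deterministic tests use.
    """
    expected = expected_image(traj, optics)
    if not noise:
        frames = expected
    else:
        rng = np.random.default_rng(np.random.SeedSequence(optics.seed))
        frames = rng.poisson(expected).astype(np.float64)
        if optics.em_gain > 1:
            nz = frames > 0
            amplified = np.zeros_like(frames)
            amplified[nz] = rng.gamma(shape=frames[nz], scale=optics.em_gain)
            frames = amplified
        if optics.read_noise_sd > 0:
            frames = frames + rng.normal(0.0, optics.read_noise_sd, size=frames.shape)
    return ImageStack(frames=frames, a=optics.a, omega0=optics.omega0,
                      exposure=optics.exposure, optics=replace(optics))


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a multi-page float32 TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    meta = {"a_um": stack.a, "omega0_um": stack.omega0, "exposure_s": stack.exposure}
    if stack.optics is not None:
        meta["optics"] = asdict(stack.optics)
        meta["seed"] = stack.optics.seed
        blob = json.dumps(meta["optics"], sort_keys=True, default=str)
        meta["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path, a: Optional[float] = None,
               omega0: Optional[float] = None,
               exposure: Optional[float] = None) -> ImageStack:
    """Read a TIFF stack; metadata from the sidecar unless given explicitly."""
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    a = a if a is not None else meta.get("a_um")
    omega0 = omega0 if omega0 is not None else meta.get("omega0_um")
    exposure = exposure if exposure is not None else meta.get("exposure_s")
    if a is None or omega0 is None or exposure is None:
        raise ValueError(
            f"no sidecar for {path}; supply pixel size, PSF radius and exposure")
    optics = None
    if "optics" in meta:
        o = dict(meta["optics"])
        o["roi"] = tuple(o["roi"])
        optics = OpticsCameraConfig(**o)
    return ImageStack(frames=frames, a=a, omega0=omega0, exposure=exposure,
                      optics=optics)
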