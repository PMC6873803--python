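"""Observation-area geometry for camera-based FCS.

In imaging FCS every (binned) camera pixel acts as its own detection
element.  The effective observation area of a square pixel of side ``a``
seen through a microscope with a Gaussian point spread function of 1/e²
radius ``ω₀`` is the pixel area convolved with the PSF,

    A_eff = a² / [ erf(p₀) + (exp(−p₀²) − 1) / (√π p₀) ]²,   p₀ = a/ω₀,

which interpolates between the PSF area π·ω₀² for tiny pixels and the
geometric pixel area a² for large ones.
"""

from __future__ import annotations

import math

__all__ = ["effective_area", "sample_plane_pixel_size", "roi_side_um"]


def _erf_factor(p0: float) -> float:
    """erf(p₀) + (exp(−p₀²) − 1)/(√π·p₀), the 1D pixel–PSF overlap factor."""
    return math.erf(p0) + (math.exp(-p0 * p0) - 1.0) / (math.sqrt(math.pi) * p0)


def effective_area(a_bin: float, omega0: float) -> float:
    """Effective observation area (μm²) of a square pixel through a Gaussian PSF.

    Parameters
    ----------
    a_bin : float
        Side of the (software-binned) pixel in the sample plane, μm.
    omega0 : float
        1/e² radius of the Gaussian PSF approximation, μm.
    """
    if a_bin <= 0:
        raise ValueError(f"a_bin must be > 0, got {a_bin}")
    if omega0 <= 0:
        raise ValueError(f"omega0 must be > 0, got {omega0}")
    p0 = a_bin / omega0
    return (a_bin / _erf_factor(p0)) ** 2


def sample_plane_pixel_size(camera_pixel_um: float, magnification: float) -> float:
    """Pixel side in the sample plane: camera pixel size divided by magnification.

    A 24 μm camera pixel behind a 100× objective images 0.24 μm of sample.
    """
    if camera_pixel_um <= 0 or magnification <= 0:
        raise ValueError("camera_pixel_um and magnification must be > 0")
    return camera_pixel_um / magnification


def roi_side_um(n_pixels: int, camera_pixel_um: float, magnification: float) -> float:
    """Side length (μm) of an n-pixel ROI in the sample plane."""
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    return n_pixels * sample_plane_pixel_size(camera_pixel_um, magnification)
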