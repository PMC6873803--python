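"""Software pixel binning: the knob that varies the observation area
post acquisition in imaging FCS."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import ImageStack

__all__ = ["BinnedSeries", "bin_pixels"]


@dataclass
class BinnedSeries:
    """Per-super-pixel intensity time series at one binning factor.

    ``traces`` has shape (n_frames, n_rows, n_cols) in super-pixel units;
    ``a_bin`` is the binned pixel side in the sample plane (μm).
    """

    traces: np.ndarray
    n_bin: int
    a_bin: float
    omega0: float
    frame_time: float

    @property
    def n_superpixels(self) -> int:
        return self.traces.shape[1] * self.traces.shape[2]

    def flat(self) -> np.ndarray:
        """(n_frames, n_superpixels) view of the traces."""
        return self.traces.reshape(self.traces.shape[0], -1)


def bin_pixels(stack: ImageStack, n_bin: int) -> BinnedSeries:
    """Sum non-overlapping n_bin × n_bin pixel blocks per frame.

    Trailing rows/columns that do not fill a block are dropped; the binned
    pixel side is n_bin times the native one.
    """
    h, w = stack.shape
    if n_bin < 1:
        raise ValueError(f"n_bin must be >= 1, got {n_bin}")
    if n_bin > min(h, w):
        raise ValueError(f"n_bin {n_bin} exceeds ROI {stack.shape}")
    rows, cols = h // n_bin, w // n_bin
    cropped = stack.frames[:, :rows * n_bin, :cols * n_bin]
    traces = cropped.reshape(-1, rows, n_bin, cols, n_bin).sum(axis=(2, 4))
    return BinnedSeries(traces=traces, n_bin=n_bin, a_bin=n_bin * stack.a,
                        omega0=stack.omega0, frame_time=stack.exposure)
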