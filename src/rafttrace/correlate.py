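"""Temporal autocorrelation of intensity traces.

The estimator is

    G(τ_k) = ⟨δF(t)·δF(t+τ_k)⟩ / ⟨F⟩²,   δF = F − ⟨F⟩,

with the average over all t available at lag k and ⟨F⟩ the full-trace mean.
Lags follow a multi-tau scheme — 16 linearly spaced lags in the first
block, then 8 lags per block with the spacing doubling each block — which
covers millisecond-to-tens-of-seconds lags with O(log T) points.  The
correlation value at every lag is computed exactly on the raw trace (no
coarse-graining of the signal), so the estimator is unbiased at all lags
and agrees with a direct double-sum evaluation to machine precision; the
multi-tau structure only selects which lags are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["ACFCurve", "multitau_lags", "compute_acf", "compute_acf_grid",
           "direct_acf", "detrend_traces"]


def detrend_traces(traces: np.ndarray, window: int) -> np.ndarray:
    """Moving-average bleach correction: subtract the boxcar trend and
    restore the overall mean.  Off by default in the pipeline — the
    synthetic camera does not photobleach — but useful on real stacks.
    """
    traces = np.asarray(traces, dtype=np.float64)
    if window < 2 or window > traces.shape[0]:
        raise ValueError(f"detrend window must be in [2, n_frames], got {window}")
    kernel = np.ones(window) / window
    flat = traces.reshape(traces.shape[0], -1)
    trend = np.apply_along_axis(
        lambda t: np.convolve(np.pad(t, (window // 2, window - window // 2 - 1),
                                     mode="edge"), kernel, mode="valid"),
        0, flat)
    return (flat - trend + trend.mean(axis=0)).reshape(traces.shape)


@dataclass
class ACFCurve:
    """One autocorrelation curve: lag times (s, lag 0 excluded), G values,
    per-lag variance estimates, and the trace statistics behind them."""

    lags: np.ndarray
    G: np.ndarray
    var_G: Optional[np.ndarray]
    n_frames: int
    trace_mean: float
    frame_time: float


def multitau_lags(n_frames: int, lags_per_block: int = 16,
                  max_lag: Optional[int] = None) -> np.ndarray:
    """Pseudo-logarithmic integer lags: ``lags_per_block`` unit-spaced lags,
    then half as many per block with the spacing doubling every block."""
    if max_lag is None:
        max_lag = n_frames // 4
    max_lag = min(max_lag, n_frames - 2)
    lags = list(range(1, min(lags_per_block, max_lag) + 1))
    spacing = 2
    while lags and lags[-1] + spacing <= max_lag:
        start = lags[-1]
        for _ in range(lags_per_block // 2):
            start += spacing
            if start > max_lag:
                break
            lags.append(start)
        spacing *= 2
    return np.asarray(lags, dtype=np.int64)


def _acf_at_lags(traces: np.ndarray, lags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact mean-subtracted correlation at integer lags.

    ``traces``: (n_frames, n_traces).  Returns (G, means): G is
    (n_lags, n_traces).
    """
    n = traces.shape[0]
    mu = traces.mean(axis=0)
    if np.any(mu == 0):
        raise ValueError("zero-mean trace: ACF normalization undefined")
    delta = traces - mu
    G = np.empty((len(lags), traces.shape[1]))
    for i, k in enumerate(lags):
        G[i] = np.einsum("ij,ij->j", delta[: n - k], delta[k:]) / (n - k)
    return G / mu**2, mu


def compute_acf_grid(traces: np.ndarray, frame_time: float,
                     lags: Optional[np.ndarray] = None,
                     n_segments: int = 8) -> list[ACFCurve]:
    """ACF curves for many traces at once (traces: n_frames × n_traces).

    Per-lag variances come from splitting each trace into ``n_segments``
    contiguous blocks, correlating each block independently, and taking the
    variance of the block estimates (divided by the number of blocks).
    Blocks only support lags up to a quarter of the block length; beyond
    that the variance of the longest supported lag is carried forward.
    """
    traces = np.asarray(traces, dtype=np.float64)
    n = traces.shape[0]
    if n < 16:
        raise ValueError(f"trace too short for correlation: {n} frames")
    if lags is None:
        lags = multitau_lags(n)
    G, mu = _acf_at_lags(traces, lags)

    var = None
    seg_len = n // n_segments
    if n_segments >= 2 and seg_len >= 16:
        supported = lags <= seg_len // 4
        if supported.sum() >= 2:
            seg_lags = lags[supported]
            seg_G = np.empty((n_segments, len(seg_lags), traces.shape[1]))
            for s in range(n_segments):
                block = traces[s * seg_len: (s + 1) * seg_len]
                seg_G[s], _ = _acf_at_lags(block, seg_lags)
            seg_var = seg_G.var(axis=0, ddof=1) / n_segments
            var = np.empty_like(G)
            var[supported] = seg_var
            var[~supported] = seg_var[-1]
            var = np.maximum(var, 1e-30)
    curves = []
    for j in range(traces.shape[1]):
        curves.append(ACFCurve(
            lags=lags * frame_time, G=G[:, j],
            var_G=None if var is None else var[:, j],
            n_frames=n, trace_mean=float(mu[j]), frame_time=frame_time))
    return curves


def compute_acf(trace: np.ndarray, frame_time: float,
                lags: Optional[np.ndarray] = None,
                n_segments: int = 8) -> ACFCurve:
    """ACF of a single intensity trace (multi-tau lag scheme by default)."""
    return compute_acf_grid(np.asarray(trace, dtype=float)[:, None], frame_time,
                            lags=lags, n_segments=n_segments)[0]


def direct_acf(trace: np.ndarray, frame_time: float, lags: Sequence[int]) -> ACFCurve:
    """Plain double-sum estimator at explicit integer lags (validation path)."""
    trace = np.asarray(trace, dtype=np.float64)
    n = len(trace)
    mu = trace.mean()
    if mu == 0:
        raise ValueError("zero-mean trace: ACF normalization undefined")
    G = np.empty(len(lags))
    for i, k in enumerate(lags):
        acc = 0.0
        for t in range(n - k):
            acc += (trace[t] - mu) * (trace[t + k] - mu)
        G[i] = acc / (n - k) / mu**2
    return ACFCurve(lags=np.asarray(lags) * frame_time, G=G, var_G=None,
                    n_frames=n, trace_mean=float(mu), frame_time=frame_time)
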