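"""Numba hot loops: per-step trajectory updates and PSF rendering.

All kernels are serial and consume pre-drawn random numbers so that results
are bitwise reproducible for a fixed NumPy seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _min_image(d: float, box: float) -> float:
    """Wrap a coordinate difference into [-box/2, box/2)."""
    d = d % box
    if d >= 0.5 * box:
        d -= box
    return d


@njit(cache=True)
def _domain_of(x: float, y: float, centers: np.ndarray, radius: float, box: float,
               cell_ids: np.ndarray, cell_counts: np.ndarray, cell_size: float) -> int:
    n_cells = cell_counts.shape[0]
    cx = int((x % box) / cell_size)
    cy = int((y % box) / cell_size)
    if cx >= n_cells:
        cx = n_cells - 1
    if cy >= n_cells:
        cy = n_cells - 1
    for k in range(cell_counts[cy, cx]):
        j = cell_ids[cy, cx, k]
        dx = _min_image(x - centers[j, 0], box)
        dy = _min_image(y - centers[j, 1], box)
        if dx * dx + dy * dy <= radius * radius:
            return j
    return -1


@njit(cache=True)
def build_domain_grid(centers: np.ndarray, radius: float, box: float,
                      cell_size: float) -> tuple:
    """Cell lists of the domains overlapping each grid cell (periodic)."""
    n_cells = max(int(box / cell_size), 1)
    cell_size = box / n_cells
    max_per_cell = 16
    cell_ids = np.zeros((n_cells, n_cells, max_per_cell), dtype=np.int64)
    cell_counts = np.zeros((n_cells, n_cells), dtype=np.int64)
    reach = radius + 1.5 * cell_size
    for j in range(centers.shape[0]):
        lo_x = int(math.floor((centers[j, 0] - reach) / cell_size))
        hi_x = int(math.floor((centers[j, 0] + reach) / cell_size))
        lo_y = int(math.floor((centers[j, 1] - reach) / cell_size))
        hi_y = int(math.floor((centers[j, 1] + reach) / cell_size))
        for gy in range(lo_y, hi_y + 1):
            for gx in range(lo_x, hi_x + 1):
                wy = gy % n_cells
                wx = gx % n_cells
                c = cell_counts[wy, wx]
                if c < max_per_cell:
                    dup = False
                    for k in range(c):
                        if cell_ids[wy, wx, k] == j:
                            dup = True
                            break
                    if not dup:
                        cell_ids[wy, wx, c] = j
                        cell_counts[wy, wx] = c + 1
    return cell_ids, cell_counts, cell_size


@njit(cache=True)
def domain_walk(
    start: np.ndarray,          # (P, 2) wrapped start positions
    normals: np.ndarray,        # (n_steps, P, 2) standard normals
    uniforms: np.ndarray,       # (n_steps, P) U(0,1) for crossing acceptance
    box: float,
    centers: np.ndarray,        # (n_domains, 2)
    radius: float,
    d_in: float,
    d_out: float,
    p_enter: float,
    p_exit: float,
    dt: float,
) -> np.ndarray:
    """Brownian walk among trapping circular domains; returns unwrapped paths.

    Boundary crossings are accepted with P_enter (outside→in) / P_exit
    (inside→out); rejected crossings are reflected radially about the circle.
    """
    n_steps, n_p = normals.shape[0], normals.shape[1]
    out = np.empty((n_steps + 1, n_p, 2))
    sig_in = math.sqrt(2.0 * d_in * dt)
    sig_out = math.sqrt(2.0 * d_out * dt)
    cell_ids, cell_counts, cell_size = build_domain_grid(
        centers, radius, box, max(2.0 * radius, box / 64.0))
    for p in range(n_p):
        out[0, p, 0] = start[p, 0]
        out[0, p, 1] = start[p, 1]
    for t in range(n_steps):
        for p in range(n_p):
            ox = out[t, p, 0]
            oy = out[t, p, 1]
            wx = ox % box
            wy = oy % box
            cur = _domain_of(wx, wy, centers, radius, box,
                             cell_ids, cell_counts, cell_size)
            sig = sig_in if cur >= 0 else sig_out
            px = ox + sig * normals[t, p, 0]
            py = oy + sig * normals[t, p, 1]
            new = _domain_of(px % box, py % box, centers, radius, box,
                             cell_ids, cell_counts, cell_size)
            if new != cur:
                prob = p_exit if cur >= 0 else p_enter
                if uniforms[t, p] >= prob:
                    # reflect radially about the circle whose boundary was hit
                    j = cur if cur >= 0 else new
                    # local (non-wrapped) center position nearest the particle
                    cx = ox + _min_image(centers[j, 0] - wx, box)
                    cy = oy + _min_image(centers[j, 1] - wy, box)
                    dx = px - cx
                    dy = py - cy
                    r = math.sqrt(dx * dx + dy * dy)
                    if r > 1e-12:
                        s = (2.0 * radius - r) / r
                        if s < 0.0:
                            s = 0.0
                        px = cx + s * dx
                        py = cy + s * dy
                    else:
                        px = ox
                        py = oy
            out[t + 1, p, 0] = px
            out[t + 1, p, 1] = py
    return out


@njit(cache=True)
def hop_walk(
    start: np.ndarray,
    normals: np.ndarray,
    uniforms: np.ndarray,
    box: float,
    mesh: float,
    d_out: float,
    p_hop: float,
    dt: float,
) -> np.ndarray:
    """Brownian walk on a square meshwork; compartment-boundary crossings are
    accepted with probability P_hop, otherwise mirrored back off the mesh line.
    """
    n_steps, n_p = normals.shape[0], normals.shape[1]
    out = np.empty((n_steps + 1, n_p, 2))
    sig = math.sqrt(2.0 * d_out * dt)
    for p in range(n_p):
        out[0, p, 0] = start[p, 0]
        out[0, p, 1] = start[p, 1]
    for t in range(n_steps):
        for p in range(n_p):
            ox = out[t, p, 0]
            oy = out[t, p, 1]
            px = ox + sig * normals[t, p, 0]
            py = oy + sig * normals[t, p, 1]
            cxo = math.floor(ox / mesh)
            cyo = math.floor(oy / mesh)
            cxn = math.floor(px / mesh)
            cyn = math.floor(py / mesh)
            if cxn != cxo or cyn != cyo:
                if uniforms[t, p] >= p_hop:
                    if cxn != cxo:
                        b = mesh * (cxn if cxn > cxo else cxo)
                        px = 2.0 * b - px
                    if cyn != cyo:
                        b = mesh * (cyn if cyn > cyo else cyo)
                        py = 2.0 * b - py
            out[t + 1, p, 0] = px
            out[t + 1, p, 1] = py
    return out


@njit(cache=True)
def deposit_psf(
    pos: np.ndarray,            # (n_samples, P, 2) wrapped positions, μm
    substeps: int,
    a: float,                   # native pixel side, μm
    omega0: float,
    n_rows: int,
    n_cols: int,
    box: float,
    counts_per_molecule: float,
) -> np.ndarray:
    """Expected photon counts per frame from Gaussian-PSF emitters.

    Each particle deposits counts_per_molecule × the normalized Gaussian
    (1/e² radius ω₀) integrated over each pixel, truncated at 4ω₀.  Pixels
    live on the periodic box grid; the returned stack is the n_rows × n_cols
    ROI cropped from its corner, so emitters outside the ROI (when the box
    is larger) contribute only through genuine PSF overlap.
    """
    n_frames = pos.shape[0] // substeps
    n_p = pos.shape[1]
    out = np.zeros((n_frames, n_rows, n_cols))
    hw = int(math.ceil(4.0 * omega0 / a))
    n_box = max(int(round(box / a)), 1)
    c = math.sqrt(2.0) / omega0
    wxs = np.empty(2 * hw + 1)
    wys = np.empty(2 * hw + 1)
    inv_s = 1.0 / substeps
    reach = 4.0 * omega0 + a
    x_max = n_cols * a
    y_max = n_rows * a
    for f in range(n_frames):
        for s in range(substeps):
            idx = f * substeps + s
            for p in range(n_p):
                x = pos[idx, p, 0]
                y = pos[idx, p, 1]
                if x > x_max + reach and x < box - reach:
                    continue
                if y > y_max + reach and y < box - reach:
                    continue
                jc = int(math.floor(x / a))
                ic = int(math.floor(y / a))
                prev = math.erf(c * ((jc - hw) * a - x))
                for k in range(2 * hw + 1):
                    cur = math.erf(c * ((jc - hw + k + 1) * a - x))
                    wxs[k] = 0.5 * (cur - prev)
                    prev = cur
                prev = math.erf(c * ((ic - hw) * a - y))
                for k in range(2 * hw + 1):
                    cur = math.erf(c * ((ic - hw + k + 1) * a - y))
                    wys[k] = 0.5 * (cur - prev)
                    prev = cur
                for ky in range(2 * hw + 1):
                    row = (ic - hw + ky) % n_box
                    if row >= n_rows:
                        continue
                    wy = wys[ky] * counts_per_molecule * inv_s
                    for kx in range(2 * hw + 1):
                        col = (jc - hw + kx) % n_box
                        if col >= n_cols:
                            continue
                        out[f, row, col] += wy * wxs[kx]
    return out
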