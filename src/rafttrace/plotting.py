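"""Diagnostic plots: ACF curves with fits, the diffusion-law line, and the
RMSD density histogram.  All functions take/return matplotlib Axes."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .acf import ACFFitResults
from .difflaw import DiffusionLawResults
from .ligands import RMSDDensity

__all__ = ["plot_acf_fit", "plot_diffusion_law", "plot_rmsd_density"]


def plot_acf_fit(fit: ACFFitResults, ax: Optional[plt.Axes] = None) -> plt.Axes:
    if ax is None:
        _, ax = plt.subplots()
    curve = fit.curve
    ax.semilogx(curve.lags, curve.G, "o", ms=3, alpha=0.6, label="data")
    tau = np.geomspace(curve.lags[0], curve.lags[-1], 200)
    ax.semilogx(tau, fit.predict(tau), "-",
                label=f"fit: D={fit.params['D']:.3g} um$^2$/s")
    ax.set_xlabel(r"lag $\tau$ (s)")
    ax.set_ylabel(r"$G(\tau)$")
    ax.legend()
    return ax


def plot_diffusion_law(result: DiffusionLawResults,
                       ax: Optional[plt.Axes] = None) -> plt.Axes:
    if ax is None:
        _, ax = plt.subplots()
    a_eff = np.array([p.A_eff for p in result.points])
    tau_d = np.array([p.tau_D for p in result.points])
    err = np.sqrt([max(p.tau_D_var, 0.0) for p in result.points])
    ax.errorbar(a_eff, tau_d, yerr=err, fmt="o", capsize=3, label="data")
    grid = np.linspace(0.0, a_eff.max() * 1.05, 50)
    ax.plot(grid, result.tau_0 + result.slope * grid, "-",
            label=rf"$\tau_0$={result.tau_0:.2g} s ({result.mode})")
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.set_xlabel(r"$A_{\mathrm{eff}}$ ($\mu$m$^2$)")
    ax.set_ylabel(r"$\tau_D$ (s)")
    ax.legend()
    return ax


def plot_rmsd_density(density: RMSDDensity, ax: Optional[plt.Axes] = None,
                      label: Optional[str] = None) -> plt.Axes:
    if ax is None:
        _, ax = plt.subplots()
    widths = np.diff(density.bin_edges)
    ax.bar(density.bin_edges[:-1], density.frequencies, width=widths,
           align="edge", alpha=0.6, label=label)
    ax.set_xlabel("RMSD to reference (Å)")
    ax.set_ylabel("normalized frequency")
    if label:
        ax.legend()
    return ax
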