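"""The FCS diffusion law: τ_D(A_eff) = τ₀ + A_eff/D_eff.

A single camera-based measurement yields many observation areas by
post-acquisition pixel binning; plotting the diffusion time τ_D against
the effective area A_eff and fitting a straight line gives the intercept
τ₀, whose sign diagnoses sub-resolution membrane organisation:

* |τ₀| ≤ 0.2 s  — free diffusion,
* τ₀ > +0.2 s   — domain-confined (hindered) diffusion,
* τ₀ < −0.2 s   — hop diffusion through a meshwork.

The inverse slope is the effective long-range diffusion coefficient D_eff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .acf import ACFModel
from .binning import bin_pixels
from .correlate import compute_acf_grid
from .imaging import ImageStack
from .optics import effective_area

__all__ = ["DiffusionLawPoint", "DiffusionLaw", "DiffusionLawResults",
           "ReplicateSummary", "build_diffusion_law", "classify_mode",
           "aggregate_replicates", "InsufficientPointsError"]

TAU0_THRESHOLD_S = 0.2   # free/hindered/hop decision boundary on τ₀


class InsufficientPointsError(ValueError):
    pass


@dataclass(frozen=True)
class DiffusionLawPoint:
    """One (A_eff, τ_D) point of the diffusion-law plot."""

    A_eff: float            # μm²
    tau_D: float            # s
    tau_D_var: float = 0.0  # s²
    n_bin: int = 0
    n_fits: int = 0         # converged super-pixel fits pooled into the point


def classify_mode(tau_0: float, threshold: float = TAU0_THRESHOLD_S) -> str:
    """Diffusion mode from the diffusion-law intercept.

    Near-zero intercepts (|τ₀| ≤ threshold) indicate free diffusion, positive
    intercepts domain-confined diffusion, negative intercepts hop diffusion.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if abs(tau_0) <= threshold:
        return "free"
    return "domain_confined" if tau_0 > 0 else "hop"


@dataclass
class DiffusionLawResults:
    """Fitted diffusion law: intercept, inverse slope, and the mode call."""

    tau_0: float                 # s
    D_eff: float                 # μm²/s (nan when the slope is non-positive)
    se_tau_0: float              # s
    se_slope: float
    r2: float
    mode: str
    threshold: float
    slope: float                 # s/μm²
    points: list[DiffusionLawPoint]
    flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "FCS diffusion law fit: tau_D = tau_0 + A_eff / D_eff",
            f"  points             : {len(self.points)}",
            f"  tau_0              : {self.tau_0:.4g} +/- {self.se_tau_0:.3g} s",
            f"  D_eff              : {self.D_eff:.4g} um^2/s",
            f"  R^2                : {self.r2:.4f}",
            f"  mode (|tau_0| <=> {self.threshold:g} s) : {self.mode}",
        ]
        if self.flags:
            lines.append(f"  flags              : {', '.join(self.flags)}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_bin": [p.n_bin for p in self.points],
             "A_eff_um2": [p.A_eff for p in self.points],
             "tau_D_s": [p.tau_D for p in self.points],
             "tau_D_var": [p.tau_D_var for p in self.points]})


class DiffusionLaw:
    """Weighted linear model of τ_D against A_eff.

    Weights are inverse τ_D variances when available (unit weights
    otherwise); the fit is ordinary/weighted least squares via statsmodels.
    """

    def __init__(self, points: Sequence[DiffusionLawPoint],
                 threshold: float = TAU0_THRESHOLD_S) -> None:
        points = sorted(points, key=lambda p: p.A_eff)
        if len(points) < 2:
            raise InsufficientPointsError(
                f"diffusion-law fit needs >= 2 points, got {len(points)}")
        if len(points) == 2:
            warnings.warn("diffusion law fitted through only 2 points",
                          stacklevel=2)
        self.points = list(points)
        self.threshold = threshold

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "DiffusionLaw":
        pts = [DiffusionLawPoint(A_eff=row["A_eff_um2"], tau_D=row["tau_D_s"],
                                 tau_D_var=row.get("tau_D_var", 0.0),
                                 n_bin=int(row.get("n_bin", 0)))
               for _, row in frame.iterrows()]
        return cls(pts, **kwargs)

    def fit(self) -> DiffusionLawResults:
        a_eff = np.array([p.A_eff for p in self.points])
        tau_d = np.array([p.tau_D for p in self.points])
        variances = np.array([p.tau_D_var for p in self.points])
        if np.all(variances > 0):
            w = 1.0 / variances
        else:
            w = np.ones_like(tau_d)
        exog = sm.add_constant(a_eff)
        res = sm.WLS(tau_d, exog, weights=w).fit()
        tau_0, slope = float(res.params[0]), float(res.params[1])
        se_tau_0, se_slope = float(res.bse[0]), float(res.bse[1])
        flags = []
        if slope > 0:
            d_eff = 1.0 / slope
        else:
            d_eff = float("nan")
            flags.append("non-positive slope: D_eff undefined")
        return DiffusionLawResults(
            tau_0=tau_0, D_eff=d_eff, se_tau_0=se_tau_0, se_slope=se_slope,
            r2=float(res.rsquared), mode=classify_mode(tau_0, self.threshold),
            threshold=self.threshold, slope=slope, points=self.points,
            flags=flags)


def build_diffusion_law(stack: ImageStack, binnings: Sequence[int] = (1, 2, 3, 4, 5),
                        triplet: bool = False, min_converged: int = 3,
                        ) -> list[DiffusionLawPoint]:
    """Bin → correlate → fit each binning; pool super-pixel fits per binning.

    For each binning factor every super-pixel trace is correlated and fitted
    with the ACF model; the binning's τ_D is the median over converged
    super-pixel fits (robust to edge pixels) with a variance estimated from
    the median absolute deviation, and A_eff comes from the binned pixel
    side and the PSF radius.
    """
    if len(binnings) < 3:
        raise InsufficientPointsError(
            f"diffusion law needs >= 3 binnings, got {len(binnings)}")
    points = []
    for n_bin in binnings:
        series = bin_pixels(stack, n_bin)
        curves = compute_acf_grid(series.flat(), series.frame_time)
        tau_ds = []
        for curve in curves:
            try:
                fit = ACFModel(curve, series.a_bin, series.omega0,
                               triplet=triplet).fit()
            except ValueError:
                continue
            if fit.converged:
                tau_ds.append(fit.tau_D)
        if not tau_ds:
            continue
        tau_ds = np.asarray(tau_ds)
        med = float(np.median(tau_ds))
        mad = float(np.median(np.abs(tau_ds - med)))
        var = (1.4826 * mad) ** 2 / len(tau_ds)
        points.append(DiffusionLawPoint(
            A_eff=effective_area(series.a_bin, series.omega0), tau_D=med,
            tau_D_var=var, n_bin=n_bin, n_fits=len(tau_ds)))
    if len(points) < 3:
        raise InsufficientPointsError(
            f"only {len(points)} binnings produced converged fits (need >= 3)")
    return points


@dataclass
class ReplicateSummary:
    """Mean ± sample SD of τ₀ over replicate measurements."""

    tau_0_mean: float
    tau_0_sd: float
    n: int
    condition_label: str
    single_replicate: bool = False

    def __str__(self) -> str:
        tag = " (single replicate)" if self.single_replicate else ""
        return (f"{self.condition_label}: tau_0 = {self.tau_0_mean:.3g} "
                f"+/- {self.tau_0_sd:.3g} s (n={self.n}){tag}")


def aggregate_replicates(fits: Sequence[DiffusionLawResults],
                         label: str = "") -> ReplicateSummary:
    """Arithmetic mean and sample SD (n−1) of τ₀ across replicates."""
    if len(fits) == 0:
        raise ValueError("need at least one replicate fit")
    values = np.array([f.tau_0 for f in fits])
    single = len(values) == 1
    sd = 0.0 if single else float(np.std(values, ddof=1))
    return ReplicateSummary(tau_0_mean=float(values.mean()), tau_0_sd=sd,
                            n=len(values), condition_label=label,
                            single_replicate=single)
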