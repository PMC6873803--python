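# Methods

This note documents the models implemented in `rafttrace`, the choices made
where the design was genuinely open, and what the synthetic data can and
cannot establish about real measurements.

## Imaging-FCS autocorrelation model

Camera-based (TIRF) FCS records an intensity trace per pixel. For a square
observation pixel of side `a` (sample-plane units) and a Gaussian PSF of
1/e² radius `ω₀`, the temporal autocorrelation of a single diffusing
species is

    G(τ) = (1/N) · [ g(p(τ)) / g(p(0)) ]² · T(τ) + G_∞
    g(p) = erf(p) + (exp(−p²) − 1) / (√π·p)
    p(τ) = a / sqrt(4Dτ + ω₀²)
    T(τ) = 1 + (F_t/(1−F_t))·exp(−τ/t_f)       (optional triplet term)

with fitted parameters `N` (mean particle number in the observation area),
`D` (μm²/s), optionally the triplet fraction `F_t` and residence time
`t_f`, and the long-lag offset `G_∞`. The amplitude at τ→0⁺ is
`(1/N)(1+F_t/(1−F_t)) + G_∞`, and `G` is strictly decreasing for
`F_t = 0`; both properties are asserted in tests. A multi-component variant
`acf_model_multi` (amplitudes `α_i = B_i²⟨N_i⟩/(ΣB_i⟨N_i⟩)²`) is provided;
the default analysis fits one component, which is the appropriate model for
the single-D-per-pixel maps the pipeline produces.

### Effective observation area

`A_eff = a²/g(a/ω₀)²` is the squared-norm ratio of the pixel–PSF
convolution (`(∫W)²/∫W²` with `W = square(a) ⊗ Gaussian(ω₀)`). It
interpolates between `π·ω₀²` (pixel ≪ PSF) and `a²` (pixel ≫ PSF) and is
strictly increasing in both arguments. The closed form is verified against
direct numerical convolution quadrature to well below 0.1%.

### Diffusion time

The ACF fit determines `D`; the diffusion time is **defined** here as
`τ_D := A_eff / D`. The proportionality constant between `τ_D` and
`A_eff/D` is a convention: any positive constant rescales the diffusion-law
intercept magnitude without changing its sign. This choice makes the
diffusion law exact with `τ₀ = 0` and `D_eff = D` for ideal free diffusion,
which is the cleanest calibration point. Intercept thresholds are
configurable for use with other conventions.

## ACF estimation

The estimator is `G(τ_k) = ⟨δF(t)δF(t+τ_k)⟩/⟨F⟩²` with `δF = F − ⟨F⟩` and
the full-trace mean. Lags follow a multi-tau scheme (16 unit-spaced lags,
then 8 lags per block with doubling spacing, up to a quarter of the trace).
Unlike a classical hardware multi-tau correlator, the correlation value at
each selected lag is computed exactly on the raw trace — the signal is
never coarse-grained — so the estimator is unbiased at every lag and
agrees with a direct double-sum evaluation to machine precision. The
multi-tau structure here is purely a lag-selection rule; with O(log T)
lags, exact evaluation costs O(T log T) per trace, which is negligible next
to rendering.

Per-lag variances (fit weights) come from splitting the trace into 8
contiguous blocks, correlating each block independently, and taking the
across-block variance of the mean. Blocks support lags up to a quarter of
the block length; beyond that the variance of the longest supported lag is
carried forward (a deliberate, slightly conservative extrapolation).
Short traces fall back to unweighted fits.

### Fitting

Weighted nonlinear least squares (Levenberg–Marquardt via lmfit), with
`N` initialized from `1/G(τ₁)`, `D` from the half-decay lag through
`A_eff/(4τ_half)`, bounds `D ∈ (10⁻⁶, 10³) μm²/s`, `F_t ∈ [0, 0.5]`,
`G_∞` free. After convergence the optimizer is restarted once from its own
optimum; this resets the trust region and polishes shallow-valley solutions
to machine precision on clean data at negligible cost. A fit is flagged
non-converged if the optimizer fails or `D` sticks to a bound.
Bleach-correction detrending is available but off by default — the
synthetic camera has no photobleaching.

## Diffusion law and mode classification

For binnings `n = 1…5`, super-pixel traces are summed (`n×n` blocks),
correlated and fitted; each binning contributes one point
`(A_eff(n·a, ω₀), τ_D)` with `τ_D` the **median** over converged
super-pixel fits (robust to edge super-pixels and occasional fit failures)
and a variance from the median absolute deviation. The line
`τ_D = τ₀ + A_eff/D_eff` is fitted by inverse-variance weighted least
squares (unit weights if variances are unavailable). A non-positive slope
leaves `D_eff` undefined but still reports `τ₀` and the mode, since noisy
confined data can produce it.

The intercept classifies the diffusion mode with the standard ±0.2 s
boundary: `|τ₀| ≤ 0.2 s` free, `τ₀ > 0.2 s` domain-confined,
`τ₀ < −0.2 s` hop diffusion. The threshold is configurable because the
`τ_D` convention above rescales intercepts. Replicate measurements are
aggregated as arithmetic mean ± sample SD (n−1); a single replicate is
flagged and reported with SD 0.

## Synthetic data

### Membrane-diffusion simulator

2D Brownian dynamics in a periodic square box, three regimes:

* **free** — homogeneous diffusivity `D_out`; Gaussian steps of per-axis
  variance `2·D_out·dt`.
* **domain** — static, non-overlapping circular nanodomains (rejection-
  sampled placement, periodic metric) with interior diffusivity `D_in`;
  boundary crossings accepted with `P_enter` (out→in) / `P_exit` (in→out),
  rejected crossings reflected radially about the circle.
* **hop** — square meshwork of side `mesh_side`; compartment-boundary
  crossings accepted with probability `P_hop`, otherwise mirrored off the
  mesh line.

Defaults (chosen once, on physical grounds, as the package's standard
study conditions):

| parameter | default | rationale |
|---|---|---|
| `box_side` | 11.52 μm (3× the 16-px ROI) | see finite-box note below |
| `n_particles` | 1350 (≈10 μm⁻²) | a few particles per observation area |
| `D_out` | 1.0 μm²/s | typical membrane-protein mobility |
| `dt` | 3 ms | one step per camera frame |
| domain `R` | 0.1 μm | sub-resolution ordered nanodomain |
| `domain_area_fraction` | 0.20 | minority ordered phase |
| `D_in` | 0.1 μm²/s | ~10× slower ordered-phase interior |
| `P_enter`/`P_exit` | 0.1 / 0.05 | partition barrier; ≈1 s trap residence |
| `mesh_side` | 0.8 μm | actin-fence compartment scale |
| `P_hop` | 0.025 | strong fences, ≈10⁻² pass probability |

With these settings the three regimes produce diffusion-law intercepts of
≈ 0 s, ≈ +1.3 s and ≈ −0.9 s respectively — well separated by the ±0.2 s
boundary — while keeping every `τ_D` (≤ ~11 s) measurable within the 60 s
trace. The domain-mode intercept magnitude is comparable to published
live-cell values for raft-partitioning probes. These parameters were fixed
by requiring (i) the qualitative regime each mode must realize and (ii)
correlation times that fit the acquisition length; they are not fitted to
any external dataset.

**Finite-box effects.** A periodic box truncates the diffusion-mode
spectrum at `q_min = 2π/L` and fixes total particle number, which
suppresses long-lag correlations and biases fitted `D` upward when the box
barely exceeds the field of view (≈ +24% at box = ROI, ≈ +7% at 3× ROI for
the default optics). The 3× default keeps this residual bias comfortably
inside the ±20% recovery tolerance; the remaining percent-level offset is a
known property of closed-box simulations, not of the estimator.

### Camera model

Each particle deposits `counts_per_molecule_per_frame` × the normalized
Gaussian-PSF integral over each pixel (1D erf differences, truncated at
4ω₀ where the neglected mass is < 10⁻¹⁵ of the total). Pixels live on the
periodic box grid and the ROI is cropped from its corner, so emitters
outside the ROI contribute only genuine PSF spillover, and a box-sized ROI
conserves photons exactly. Frames average `⌈exposure/dt⌉` sub-steps (the
default `dt = exposure` renders instantaneous positions; sub-stepping is
available when motion blur at high `D` matters). Noise follows the EMCCD
cascade: Poisson photons → gamma-distributed gain (shape = photon count,
scale = `em_gain`) → additive Gaussian read noise. `em_gain = 1` with zero
read noise is exactly shot-limited — the default for validation work,
since EM gain only adds the ×2 excess-noise factor without changing
correlation shapes.

Default optics: `ω₀ = 0.24 μm` and `a = 0.24 μm`, matching a 24 μm camera
pixel behind a 100× objective; the PSF radius is a package choice (typical
high-NA TIRF values are 0.2–0.3 μm), as is the 300 counts/molecule/frame
brightness. The default 16×16 ROI at 20,000 frames is a deliberately
scaled-down acquisition (live-cell practice uses e.g. 21×21 px and 50,000
frames); it keeps a full simulated measurement in the tens of seconds while
leaving all inferences comfortably converged.

### Synthetic acyl chains

Chains of `n` carbons (default 16, the palmitate length) are built from
internal coordinates by the natural-extension-reference-frame method with
exact bond length (1.53 Å) and C–C–C angle (111.5°). Dihedral models:
`all_trans` (planar zig-zag), `rotamer_sampled` (trans/gauche⁺/gauche⁻ at
180°/±65° with weights 0.6/0.2/0.2), `continuous` (uniform dihedrals).
`cis_bond_index = j` pins the dihedral about the C(j)–C(j+1) bond to 0°,
emulating the kink of a monounsaturated chain (16:1 cis-9 by default).
The ensembles span linear-to-strongly-kinked shapes, which is the property
the RMSD-density analysis needs; they do **not** model sterics or excluded
volume (a rotamer draw may self-intersect), bond-length/angle vibrations,
torsional minima shifts near the cis bond, or the carboxyl head group.
Conclusions from synthetic ensembles therefore concern the analysis chain
(superposition, binning, normalization), not fatty-acid conformational
thermodynamics.

## Conformer RMSD analysis

Ligand copies are extracted from PDB-format text per (model, chain,
residue number); alternate locations resolve to the highest-occupancy atom
(ties: lexicographically first altloc). Chain carbons are matched by
canonical names C1…Cn; conformers missing atoms are matched on the common
subset and flagged, and conformers with fewer than three matched carbons
are excluded and counted. Multiple copies of a ligand within one entry are
counted per copy.

Superposition is the least-squares optimal **proper** rotation plus
translation (no reflection — chirality is physical; no scaling), computed
via SVD-based alignment. The RMSD distribution over an ensemble is
histogrammed into 20 equal-width bins over `[0, max RMSD]` by default
(configurable to a fixed range for cross-dataset comparability) and counts
are divided by the dataset size, so frequencies sum to one. This matches
the "normalized occurrence" reading of a probability of being
conformationally close; it is **not** a per-Å density (dividing by bin
width would make it one), and axis labels say so. The closest conformer is
the RMSD argmin, ties broken by lexicographic source id.

## Problem sizes and runtime

The test suite and the acceptance script simulate 16×16-pixel, 20,000-frame
measurements (one per regime in the script; five per regime in the
mode-separation test). One full measurement — trajectories, rendering,
correlation at five binnings, ~370 ACF fits and the diffusion-law fit —
takes ~15–35 s on one CPU. These sizes are the package's standard
validation conditions; larger boxes, longer stacks and finer binning
ladders are plain configuration.

## Known limitations

* Single-component, 2D, free-model ACF fits: no anomalous-diffusion
  exponent, no axial PSF term, no spatial cross-correlation.
* The periodic closed box leaves a percent-level upward bias on fitted `D`
  (see above); increase `box_side` where that matters.
* The trap/fence simulators use per-step crossing probabilities; mapping
  `P_enter/P_exit/P_hop` to physical permeabilities depends on `dt` and is
  not calibrated to a specific lipid system.
* Synthetic conformers are geometric, not thermodynamic (no Boltzmann
  weighting beyond rotamer frequencies, no sterics).
* No photobleaching, blinking (beyond the optional triplet term in the
  *fit* model), or camera pixel cross-talk in the renderer.
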