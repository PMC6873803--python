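# rafttrace

Imaging-FCS diffusion-law analysis of membrane protein dynamics, plus
fatty-acid conformer RMSD densities — with a built-in synthetic-data
generator so the whole chain is verifiable end to end.

## The problem

Whether a membrane protein diffuses freely, is transiently trapped in
ordered lipid nanodomains ("rafts"), or hops between cytoskeleton-fenced
compartments is invisible to a single diffusion coefficient: all three
regimes can show the same apparent mobility at one length scale. Imaging
total-internal-reflection fluorescence correlation spectroscopy (ImFCS)
resolves this by measuring how the diffusion time scales with the
observation area. Every camera pixel yields an intensity trace; its
temporal autocorrelation

    G(τ) = (1/N) · [ g(p(τ)) / g(p(0)) ]² · [1 + (F_t/(1−F_t)) e^{−τ/t_f}] + G_∞,
    g(p) = erf(p) + (e^{−p²} − 1)/(√π p),   p(τ) = a / √(4Dτ + ω₀²),

is fitted for the particle number N, diffusion coefficient D, triplet
parameters F_t, t_f, and offset G_∞ (a = pixel side, ω₀ = PSF 1/e² radius).
Software-binning pixels post acquisition varies the effective observation
area A_eff = a²/g(a/ω₀)², and the **FCS diffusion law**

    τ_D(A_eff) = τ₀ + A_eff / D_eff,     τ_D := A_eff / D

diagnoses sub-resolution organization through its intercept: |τ₀| ≤ 0.2 s
indicates free diffusion, τ₀ > +0.2 s domain-confined diffusion, and
τ₀ < −0.2 s hop diffusion.

The package's second analysis addresses the acyl chain that anchors such
proteins (e.g. Wnt ligands) in the membrane: given many deposited
conformers of a fatty-acid ligand, superpose each on a reference conformer
over its chain carbons (optimal proper rotation + translation), histogram
the RMSDs into 20 bins, normalize by dataset size, and report the closest
conformer — the probability distribution of being conformationally close
to the reference.

Audience: membrane biophysicists running camera-based FCS, and anyone who
needs a tested, scriptable reference implementation of the diffusion-law
and conformer-density analyses with simulated ground truth.

## What's in the box

* `rafttrace.simulate` — 2D Brownian dynamics in free, trapping-nanodomain
  and meshwork-hop regimes (periodic box, bitwise-reproducible).
* `rafttrace.imaging` — Gaussian-PSF rendering onto an EMCCD-like camera
  (Poisson → gamma gain → read noise), TIFF + JSON-sidecar IO.
* `rafttrace.binning`, `rafttrace.correlate` — software binning and an
  exact multi-tau-scheme ACF estimator with block-wise error bars.
* `rafttrace.acf` — the ACF model and `ACFModel(...).fit()` →
  `ACFFitResults` (parameters, errors, χ², τ_D, A_eff, `summary()`).
* `rafttrace.difflaw` — `DiffusionLaw(points).fit()` →
  `DiffusionLawResults` (τ₀, D_eff, R², mode, `summary()`), replicate
  aggregation.
* `rafttrace.chains`, `rafttrace.ligands` — synthetic acyl-chain conformer
  ensembles (trans/gauche rotamers, optional cis kink), PDB parsing,
  Kabsch-type superposition, RMSD densities, closest-conformer reports.
* `rafttrace.cli` — `rafttrace {simulate|imfcs|difflaw|conformers|demo}`.

## Worked example

One command simulates a freely diffusing membrane protein (D = 1 μm²/s),
images it through a 0.24 μm PSF onto a 12×12-pixel camera for 10,000
frames at 3 ms, runs the full analysis and writes every table:

```bash
rafttrace demo --seed 42 --out demo_out
```

The report ends with the diffusion-law stage:

```
"difflaw": {
  "tau_0_s": 0.006946573983532767,
  "D_eff": 1.017992508077195,
  "r2": 0.9959341506369295,
  "mode": "free"
}
```

or, through the library:

```python
import rafttrace as rt

stack = rt.read_stack("demo_out/stack_free.tif")
points = rt.build_diffusion_law(stack, binnings=(1, 2, 3, 4))
print(rt.DiffusionLaw(points).fit().summary())
```

```
FCS diffusion law fit: tau_D = tau_0 + A_eff / D_eff
  points             : 4
  tau_0              : 0.006947 +/- 0.0127 s
  D_eff              : 1.018 um^2/s
  R^2                : 0.9959
  mode (|tau_0| <=> 0.2 s) : free
```

The intercept is statistically zero and the inverse slope recovers the
simulated D within 2%, so the measurement is classified as free diffusion.
Re-running with `mode="domain"` (trapping nanodomains) or `mode="hop"`
(meshwork fences) in the simulation config moves τ₀ to ≈ +1.3 s or
≈ −0.9 s while the ±0.2 s rule classifies each correctly — the same
analysis a cholesterol-extraction experiment is read with, where
dissolving ordered domains collapses a positive intercept toward zero.

For the conformer analysis:

```bash
rafttrace conformers --ligand PLM --reference ref.pdb:PLM \
    --pdb conformers.pdb --bins 20 --out conf_out
```

writes the per-conformer RMSD table, the 20-bin normalized density and
`closest.json` with the closest conformer and its RMSD.

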