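# pbodytools

Analysis tools for the physical state of biomolecular condensates —
ribonucleoprotein granules such as the P bodies that store maternal mRNAs in
*Drosophila* oocytes. The package is aimed at researchers who want to go
from raw observations (bleach-recovery traces, time-lapse images, particle
detections, proteome disorder annotations) to the quantitative readouts that
characterize whether a condensate behaves like a liquid, a viscous fluid, or
an arrested solid, plus a coarse-grained simulation to reason about why.

Four analysis stages, one simulation engine, and seeded synthetic-data
generators that let everything build and test without downloads:

* **`lattice_mc`** — lattice Monte Carlo simulation of protein-RNA
  condensation. Proteins are five-bead chains (a central ordered-domain bead
  flanked by disordered-region beads), RNA a 20-bead homopolymer, on a
  periodic cubic lattice with contact energies in kT and Metropolis dynamics.
  Sweeping the protein:protein interaction scale shows condensate integrity
  rising and dilute-phase RNA falling — condensate integrity as a proxy for
  RNA storage.
* **`frap`** — FRAP normalization and kinetics. Fits the single-exponential
  recovery I(t) = P(1 − e^(−t/τ)) + y₀, and derives half-time t½ = τ·ln 2,
  mobile fraction, apparent diffusion D ≈ 0.224 ω²/t½, and Stokes-Einstein
  apparent viscosity η = k_B T/(6π R_h D).
* **`morphology`** — segmentation and shape descriptors (aspect ratio,
  circularity 4π·A/P², areas), shape-relaxation fitting, a simple linear
  particle tracker with Wilcoxon displacement comparisons, and scaled fusion
  times (τ_fusion / radius).
* **`disorder`** — intrinsically disordered region (IDR) calling from
  consensus predictor counts (runs of ≥ 25 residues with ≥ 3 predictors
  agreeing) and a resampling test for whether a protein set is more
  disordered than size-matched random sets from the proteome.
* **`synthetic`** — seeded generators for all of the above, with ground truth.
* **`pbody` CLI** — `simulate`, `sweep`, `frap-fit`, `morphology`, `track`,
  `fusion`, `disorder`, `synth`; every run writes a reproducibility manifest.

See `docs/methods.md` for model definitions, estimator calibration, and
limitations.

## Worked example

Fit a synthetic "embryo-like" recovery curve and derive transport estimates:

```python
import numpy as np
from pbodytools import frap
from pbodytools.synthetic import gen_frap_curves

curves, truth = gen_frap_curves("embryo", n_curves=1, seed=7)
fit = frap.fit_recovery(curves[0])
print(f"P = {fit.P:.3f}, tau = {fit.tau:.1f} s, y0 = {fit.y0:.3f}")
print(f"t_half = {fit.t_half:.1f} s, mobile fraction = {fit.mobile_fraction:.2f}")

t_half = frap.half_time_from_tau(62.79 / np.log(2))   # oocyte internal recovery
D = frap.apparent_diffusion(omega_um=0.446, t_half_s=t_half)
eta = frap.apparent_viscosity(D, rh_m=4.34e-10, temperature_k=294.15)
print(f"t_half = {t_half:.2f} s, D = {D:.2e} um^2/s, eta = {eta:.0f} Pa.s")
```

prints

```
P = 0.451, tau = 30.6 s, y0 = 0.201
t_half = 21.2 s, mobile fraction = 0.56
t_half = 62.79 s, D = 7.10e-04 um^2/s, eta = 700 Pa.s
```

The first two lines recover the generator's ground truth (P = 0.456,
τ = 30 s, mobile fraction 0.57 — an early-embryo-like, dynamic condensate).
The last line is the transport chain for a slow internal recovery
(half-time 62.79 s): an apparent diffusion near 7×10⁻⁴ μm²/s and an
apparent viscosity near 700 Pa·s, i.e. orders of magnitude more viscous
than liquid-like condensates (treat the η as qualitative — it hinges on the
assumed hydrodynamic radius).

And a desk-scale condensation sweep from the shell:

```bash
pbody sweep --seed 1 --out results/sweep
column -t results/sweep/sweep.tsv
```

which reports, per protein:protein interaction scale, the replicate mean ±
SEM of condensate integrity (fraction of protein chains in the largest
cluster) and of the dilute-phase RNA fraction: integrity climbs from ~0.19
to ~0.95 while dilute RNA falls from ~0.71 to ~0.08 as the scale goes from
0 to 1.5 — weakening protein-protein interactions releases RNA.

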