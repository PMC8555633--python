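# Methods

This note documents the models, estimators, numerical choices, and the scope
of what the synthetic-data tests do and do not demonstrate.

## Coarse-grained lattice model of protein-RNA condensation

**Representation.** A DEAD-box-helicase-like protein is a five-bead chain on
a periodic cubic lattice: one central ordered-domain (OD) bead flanked by two
intrinsically disordered (IDR) beads on each side, i.e. `[IDR, IDR, OD, IDR,
IDR]`. RNA is a 20-bead homopolymer of RNA beads. Bead typing is
configurable through `PolymerSpec`. Each lattice site holds at most one bead
(excluded volume) and consecutive beads of a chain occupy face-adjacent
sites.

**Energetics.** The energy is a sum of symmetric pairwise contact energies
(kT units, k = 1) over face-adjacent (6-neighbourhood) non-bonded bead
pairs; bonded pairs (consecutive in a chain) contribute nothing. Default
contact energies:

| pair | kT |
|---|---|
| OD-OD | -3.0 |
| OD-IDR | -1.0 |
| IDR-IDR | -0.2 |
| OD-RNA | -1.5 |
| IDR-RNA | -0.75 |
| RNA-RNA | +1.0 |

The ordering encodes the biology: adhesive contacts between folded domains
dominate, IDRs moderate, and RNA self-interaction is repulsive. The
magnitudes are model parameters, not measurements; they were chosen under
two constraints. First, the qualitative ordering above. Second, a structural
constraint implied by the system being modelled: protein-RNA attraction must
be weak enough that protein-RNA bridging *alone* cannot sustain a
condensate. With much stronger protein-RNA coupling, proteins act as
multivalent RNA crosslinkers and a condensate persists even with
protein-protein interactions switched off — in that regime condensate
integrity would no longer report on protein-protein interaction strength,
and the model's central prediction (weakening protein-protein interactions
releases RNA to the dilute phase) cannot be expressed. All entries are
config-exposed; `protein_scale` multiplies only the three protein-protein
entries, with protein-RNA and RNA-RNA held fixed across a sweep.

**Moves and acceptance.** Four move kinds with default mixture 0.3/0.2/0.4/0.1:

* *translate* — rigid chain translation by one lattice unit along a random axis;
* *rotate* — rigid rotation of the whole chain about a randomly chosen bead
  by one of the 24 proper cubic rotations;
* *local pivot* — rotation of the shorter sub-chain about a random internal bead;
* *global pivot* — rotation of the sub-chain from a random bead to a randomly
  chosen chain end, about that bead.

All moves preserve connectivity by construction (cubic rotations map
face-adjacent sites to face-adjacent sites); any overlap with an unmoved
bead is a structural rejection. Accepted otherwise by the Metropolis
criterion at kT = 1, with the move's ΔE computed locally; the incrementally
tracked total energy is tested to agree with a from-scratch recomputation to
1e-9 kT. Chains store unwrapped integer coordinates (occupancy is on wrapped
sites), which makes pivot arithmetic exact; this requires the lattice side
to exceed the longest chain, which configuration validation enforces.

**Cluster analysis.** Two chains are connected iff any inter-chain bead pair
is face-adjacent; condensates are the connected components. Reported per
frame: total energy, largest-cluster chain count, fraction of protein chains
in the largest cluster ("integrity"), and the fraction of RNA chains outside
the largest protein-containing cluster (the dilute-phase RNA fraction, the
model's readout for RNA release). Analysis uses the terminal 20% of frames
(burn-in fraction 0.8) and, for sweeps, the replicate mean ± SEM over three
independent replicas seeded `seed + replica`.

**Problem sizes.** The production preset is the full-scale system: a 60³
lattice with 800 protein and 50 RNA molecules. The desk-scale default used
by the tests and the acceptance script is a 24³ lattice with 60 protein and
10 RNA chains run for 3×10⁷ moves (frames every 5×10⁵ moves). This is the
smallest system we found that both condenses and equilibrates its cluster
structure: cluster coarsening proceeds only by single-chain exchange, so
larger or more dilute systems nucleate several condensates that do not merge
on accessible runs — at strong coupling that kinetic arrest is physically
meaningful, but it masks the equilibrium trend the sweep is meant to expose.
The sweep uses protein scales {0.0, 0.5, 1.0, 1.5}, spanning fully weakened
to stronger-than-default coupling.

**What the desk-scale sweep shows.** With the defaults above, integrity
increases and the dilute RNA fraction decreases strictly and monotonically in
the protein-protein scale (replicated across seed bases). It is a
demonstration of the model's qualitative prediction at small size, not an
estimate of any in vivo quantity.

## FRAP recovery kinetics

Normalization is a pointwise ratio: bleached condensate over unbleached
cytoplasm (whole-condensate bleach) or bleached sub-region over the whole
condensate (internal bleach). The recovery model is

    I(t) = P (1 - e^(-t/tau)) + y0,

fitted by bounded nonlinear least squares (scipy `curve_fit`,
initialization y0 = first intensity, P = last - first, tau = span/2, bounds
tau in [dt/10, 100·span], P, y0 >= 0). Note y0 is the intensity immediately
*after* the bleach (the model value at t = 0); the plateau is P + y0.
Derived quantities: half-time t_half = tau·ln 2; mobile fraction
(plateau - y0)/(pre_bleach - y0) = P/(pre_bleach - y0), clipped to [0, 1],
with pre_bleach defaulting to 1 for ratio-normalized curves. Fits with tau
pinned at a bound, or tau exceeding half the observation span (plateau not
reached), are flagged rather than rejected.

Transport estimates are exact closed forms: apparent diffusion
D ≈ 0.224 ω²/t_half with ω the bleach-region radius in μm, and apparent
viscosity from Stokes-Einstein, η = kB·T/(6π·Rh·D), with D converted to
m²/s internally. At the documented operating point (t_half = 62.79 s,
ω = 0.446 μm, T = 294.15 K, Rh = 4.34×10⁻¹⁰ m) the chain yields
D ≈ 7.1×10⁻⁴ μm²/s and η ≈ 700 Pa·s. The viscosity is qualitative: it
treats recovery as pure diffusion of a tracer of hydrodynamic radius Rh, and
that Rh (obtained by inverting the relation at the quoted D and η) is far
below a plausible value for a folded helicase — the module reports η for
any user-supplied Rh and does not resolve that tension.

**Estimator precision.** Under the fit-validation conditions (P = 0.5,
tau = 60 s, y0 = 0.1, 60 points over 600 s, Gaussian noise sd 0.02 — the
"reference" preset) the median relative error of P and tau is ~2% and ~4%,
and ±3-sd intervals cover the truth for ~99% of fits. Under the
low-amplitude "oocyte" preset (P = 0.12) the same noise yields ~7%/~15%
median error: that is an information limit of the data, not a fitter defect,
which is why precision claims are keyed to the reference conditions while
the oocyte/embryo presets are judged on recovered mobile fraction (within
±0.03 of 0.15 and 0.57).

## Condensate morphology, tracking, and fusion

Segmentation: optional rolling-ball background subtraction, global Otsu
threshold (manual override available), 8-connected components, minimum-area
filter in μm². Aspect ratio is the major/minor axis ratio of the
moment-equivalent ellipse; an independent test recomputes it from the
eigenvalues of the pixel-coordinate covariance. Circularity is
4π·area/perimeter² with a Crofton multi-direction perimeter estimator;
naive boundary counting overestimates circular perimeters by 5-10%, while
the Crofton estimate puts a rasterized disk of radius >= 20 px within 5% of
circularity 1 (the calibrated tolerance used in tests). Shape relaxation is
fitted as AR(t) = 1 + (AR0 - 1)·e^(-t/τs); a flat series at AR ≈ 1 is
flagged unidentifiable instead of fitted.

Tracking is a simple linear tracker: greedy nearest-neighbour frame-to-frame
linking in order of increasing distance, links longer than `max_disp`
forbidden, unmatched detections opening new tracks; no gap closing and no
merge/split handling. On constructions with initial spacing > 2·max_disp
and steps < max_disp/2 this linking provably equals the ground-truth
correspondence, which the tests exploit. Per-track *total displacement*
(path length) is compared between conditions with a Wilcoxon signed-rank
test (paired; zero differences dropped, all-zero case returns p = 1; the
reported statistic is the signed rank sum so swapping labels flips its sign)
or a Mann-Whitney U test (unpaired). Whether real comparisons are paired per
particle is an acquisition decision; both variants are provided.

Fusion traces are deformation signals normalized to 1 at contact and
decaying to 0 on completed fusion. The relaxation time constant τf is fitted
from signal(t) = e^(-t/τf); the scaled fusion time is τf divided by
condensate radius (s/μm), a size-independent viscosity proxy. Non-decaying
signals (aggregates) raise a fit error — fusion is not quantifiable — rather
than returning a number.

## Disorder enrichment

IDRs are maximal runs of residues where >= 3 consensus predictors call
disorder, kept only if >= 25 residues long; intervals are 1-based closed,
disjoint, and reconstruct exactly the residue set counted by the disorder
fraction (a property test). Enrichment of a protein set is its percentile
among `n_draws` random sets of the same cardinality drawn uniformly without
replacement from the whole proteome, with the strictly-below convention
(ties reported separately; a set equal to the whole proteome therefore
scores percentile 0). "Size-matched" means set-cardinality matching; an
optional length-stratified mode (quartile bins of protein length) is
available but off by default. Null draws may include members of the observed
set. Two statistics: protein-averaged (mean of per-protein fractions) and
residue-weighted (pooled IDR residues over pooled residues); the percentile
is invariant under any strictly monotone transform of the fractions. All
set statistics are computed in canonical (sorted-index) order so identical
sets give bit-identical values and tie handling is exact; a small-proteome
exhaustive enumeration provides the oracle (8 proteins, choose 3:
percentile 100·55/56 = 98.21).

## Synthetic data

Generators are seeded (`numpy` Generator; bit-reproducible given preset and
seed), emit ground truth beside the data, and use independent Gaussian noise
throughout. They emulate the statistical *structure* each stage assumes —
exponential recoveries, an ellipse relaxing to a circle at constant area, a
Beta-distributed proteome with a shifted subset, per-frame random-walk
detections, exponential fusion decays — not microscope optics, bleaching of
the unbleached pool, cytoplasmic background, or real proteome length/
disorder correlations. Passing round-trip tests therefore shows the
estimators are correct and well-calibrated under their own model
assumptions; it does not validate them against instrument noise or
real-data artifacts.

Preset catalogue (emulation parameters unless noted): FRAP "oocyte"
(mobile fraction 0.15, tau = 62.79/ln 2 s — both measured values),
"embryo" (mobile fraction 0.57, measured; tau 30 s), "1,6-HD" (recovery to
~60%), "reference" (fit-validation conditions); stacks "relaxation"
(AR 3 → 1, τs = 10 min); proteome "enriched" (17 of 2000 proteins, subset
mean fraction 0.5 vs background 0.25) and "null"; tracks "control" vs
"cytochalasin-D" (3× step scale) and "separated" (guaranteed-separation
construction); fusion "wildtype" (scaled time 1 s/μm over radii 0.5-2 μm)
and "aggregate" (non-decaying).

## Reproducibility and the CLI

Every stochastic stage requires an explicit seed (replica seeds are
`seed + replica`); the `pbody` CLI writes a manifest JSON (stage, parameters,
seed, inputs, package version, wall clock) beside each stage's outputs, so
a run is reproducible from its manifest alone. Tables are TSV with header
rows; trajectories are an extended-XYZ text dialect (comment line carries
step and energy); image stacks are multi-frame TIFF.

## Known limitations

* The lattice model has no RNA secondary structure, no sequence specificity,
  and no cluster-level moves; at strong coupling desk-scale systems can
  kinetically arrest, which is why the desk preset was sized as described.
* The FRAP model is a single exponential with no reaction-diffusion
  component or bleach-profile correction; the viscosity estimate inherits
  the Rh caveat above.
* Segmentation thresholds, the linking distance, and pairing of displacement
  comparisons are acquisition-dependent defaults, documented but not
  inferred from data.
* The enrichment module consumes precomputed consensus counts or intervals;
  it does not run disorder predictors.
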