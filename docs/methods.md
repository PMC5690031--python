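# Methods

This note records the physical model, the estimators, the numerical
choices, and what the synthetic data generator does and does not emulate.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Photon interaction data

The packaged element tables (`src/kvdose/data/elements/`, 13 elements
H–Ca plus Ar, 5–150 keV at 1 keV spacing) are produced once by
`scripts/generate_xs_table.py` from a self-contained semi-empirical model:

* **incoherent**: free-electron Klein–Nishina cross section times Z.
  Binding (incoherent-scattering-function) corrections are neglected; for
  low-Z elements they matter mostly below ~30 keV at small momentum
  transfer, where the photoelectric effect dominates the attenuation.
* **coherent**: Thomson cross section modulated by a hydrogen-like atomic
  form factor `F(x, Z) = Z (1 + (x / bZ^{1/3})²)^{-2}` with a single
  fitted Thomas–Fermi-scaled screening constant, integrated over angle.
* **photoelectric**: a smooth log-log surface in (Z, E) — there are no
  absorption edges above 5 keV for this element set.
* **energy absorption**: photoelectric (minus a small K-fluorescence
  escape estimate) plus Klein–Nishina mean-energy-transfer-weighted
  incoherent; coherent events transfer no energy.

The screening constant and photoelectric coefficients are fitted jointly
to standard reference total-attenuation values for H, C, N, O and Al and
to reference mass energy-absorption values for water and air (the latter
pin down the photoelectric/coherent split that totals alone cannot
resolve). Fitted mixtures reproduce the reference data to better than 2%
over 30–150 keV; elements above Z = 13 are Z-extrapolations of the
surface and run roughly 5% high. Mixtures follow mass-fraction
additivity; queries interpolate log-log. Collision kerma per unit fluence
is `E · μ_en/ρ(E)`, treating radiative losses and electron transport as
negligible (kV secondary electrons have micrometer ranges and are locally
absorbed).

Material presets: water, dry air (N/O/Ar, used for all kerma
normalizations), acrylic (C₅O₂H₈ at the machined density 1.16 g/cm³),
aluminum, epoxy-based soft-tissue and foamed lung substitutes of the kind
used in anthropomorphic phantoms (published mass fractions, antimony
trace dropped), and ICRU-46 adult bones (cortical, femur, marrow).

## HU segmentation

Site schemes (pelvis, thorax, head) are ordered lists of half-open HU
ranges with first-match precedence. Two published-table quirks forced
explicit policies:

* the thorax lung range (−750…−30) entirely covers the tissue range
  (−300…−50); the shipped preset lists the tissue rule first so both
  materials are reachable (lung keeps −750…−300 and −50…−30);
* HU values covered by no rule (e.g. pelvis −50…5) map to the material of
  the nearest rule boundary. The mapping is total over [−1024, 10000] and
  anything outside raises rather than silently defaulting.

An idealized "acrylic" scheme (air below −850 HU, acrylic above) serves
the homogeneous-cylinder images, whose acrylic voxels are written at
+120 HU.

## Source model and characterization

The beam is a point source at SAD = 100 cm (gantry angle 0° = source
posterior, +y beam direction, couch axis z). Its state is defined
entirely on the isocenter plane: blade-collimated field `[−x1,x2] ×
[−y1,y2]`, relative planar fluence normalized to 1 on the axis, and a
spectrum per transverse offset. Photon sampling is importance sampling on
that plane — uniform gantry angle in the arc, target point proportional
to the fluence, energy from the local spectrum — which is exact for a
model defined by its isocenter-plane fluence. The absolute fluence scale
comes from the output factor (cGy/mAs of in-air kerma at the isocenter on
the axis). The measured fluence is interpreted as fluence perpendicular
to the ray; the transport kernels carry the plane-crossing cosine
(≤ 2.7% at the widest field edge) so primary and scatter normalizations
agree exactly.

Characterization solves one inverse problem per transverse offset: a
Kramers-shaped bremsstrahlung base spectrum (number weights ∝ (kVp−E)/E,
1 keV bins, 5 keV cutoff, no characteristic lines) is hardened by the
aluminum-equivalent thickness whose computed HVL matches the measured
HVL, via bracketed root finding (HVL itself is a bracketed root of the
air-kerma-weighted transmission). The planar fluence is the kerma profile
divided by the local spectrum's air-kerma-per-fluence — the physically
correct normalization when the spectrum varies across the field — and is
treated as a separable transverse × radial product, the only
decomposition the two measured axes support. Profile interpolation is
shape-preserving piecewise cubic (PCHIP) with constant extrapolation:
unconstrained splines ripple at bowtie inflection points, and the 2 cm
sampling cannot support more structure.

## Synthetic measurement generator

`make_ground_truth_source` builds known bowtie-filtered sources for the
four protocol presets (100 kVp head and 125 kVp pelvis-spotlight at 200°
posterior-centered arcs with symmetric 13.6/9.2 cm blades; 110 kVp thorax
and 125 kVp pelvis at 360° with asymmetric 6.8/23.5 cm blades). The
on-axis aluminum-equivalent filtration is 6.5 mm (tube inherent plus
bowtie center), giving on-axis HVLs of 4.9–6.0 mm Al across 100–125 kVp —
the range published for clinical CBCT units; full bowties add up to
15 mm Al-equivalent quadratically toward the field edge, half bowties
ramp smoothly (softplus) toward the wide side only. The radial fluence
carries the point-source obliquity falloff. `simulate_measurements`
samples HVL and kerma profiles at 2 cm spacing (field edges included) —
exactly the tables the in-air protocol produces.

What the generator does **not** emulate: measurement noise, chamber
volume averaging, positioning error, characteristic anode lines, heel
effect, and off-axis spectral softening other than bowtie hardening.
Passing round-trip tests therefore demonstrates that the inversion is
self-consistent to ≲2% for smooth bowtie-shaped beams, not that it is
robust to noisy clinic data.

## Transport estimators

Ray tracing is exact Amanatides–Woo voxel traversal; optical lengths are
per-material chord lengths times interpolated linear coefficients.

* **Primary**: deterministic arc quadrature at 1° steps (midpoint rule).
  The step was chosen so the discretization error of smooth profiles is
  far below the Monte Carlo noise of the scatter components.
* **Scatter**: forced first interaction along each sampled ray
  (weight `1 − e^{−τ_exit}`, truncated-exponential site), survival
  biasing at every collision (weight × scatter probability, so
  photoabsorption never kills a history outright), next-event estimation
  to every POI at every collision, analog continuation flights, Russian
  roulette below weight 10⁻³ with survival probability 0.1, energy cutoff
  5 keV (locally absorbed). Incoherent scattering samples Klein–Nishina
  exactly (Kahn's method); coherent scattering keeps the photon energy
  and uses the Thomson angular shape — form factors enter only through
  the coherent total cross section, a deliberate simplification that
  overweights wide-angle coherent deflections slightly.
* **Near-field regularization**: next-event contributions closer than
  `d_min = max(half voxel diagonal, 2.5 mm)` to the POI use the ball
  average of the 1/d² kernel, `3/d_min²`, instead of a hard cap. The ball
  average is unbiased for a locally uniform collision density, whereas
  capping at `1/d_min²` under-scores the exclusion ball (a ~10% total
  deficit on a coarse-voxel benchmark); the 2.5 mm floor — the physical
  radius of the detectors the engine is meant to mimic — tames the
  heavy 1/d² variance tail. Agreement with the independent analog
  estimator (below) is the guard on this choice.
* **Uncertainty**: 1σ from 25 equal history batches. Histories are seeded
  individually (a splitmix-style hash of the run seed and the history
  index), which makes runs bit-reproducible and keeps paired runs with a
  perturbed geometry correlated history-by-history — the property that
  makes single-voxel substitution ratios (lung-to-tissue factors) nearly
  noise-free.

A plain analog Monte Carlo (`analog_reference_dose`: physical free
flights, outright photoelectric absorption, track-length fluence tally in
a sphere, no biasing and no next-event estimation) is bundled as an
independent cross-check of the biased engine; the test suite compares the
two on a homogeneous cube and checks the first-scatter component against
a closed-form single-voxel Klein–Nishina quadrature.

## Analysis components

TLD calibration is a least-squares line D = mQ + b with standard errors
from the fit covariance; the dose uncertainty uses a linear (worst-case)
combination ΔD = QΔm + mΔQ + Δb, not quadrature — the convention under
which such TLD uncertainties are usually reported. CTDIw uses
the standard 1/3 center + 2/3 periphery weights. Comparison statistics
use the measured dose as denominator (sign convention: positive means
computation above measurement is *positive* percent difference) and a
1σ error-bar-overlap pass criterion, both configurable. DTA finds the
nearest position where a piecewise-linear profile attains a point's dose,
by dense bracketing plus linear refinement. The lung-to-tissue factor
substitutes one voxel's material and recomputes with identical seeding,
so the ratio isolates the flux-to-kerma difference at the local hardened,
multidirectional spectrum.

## Problem sizes

The idealized cylinder is computed at its native 512×512×91 /
0.81×0.81×3 mm geometry. The synthetic thorax fixture used for
conversion factors runs at the same in-plane resolution (512×512×31).
The acceptance script uses 6×10⁵ histories for the scatter fraction,
1.5×10⁶ for the uncertainty figure, 1.5×10⁵ per profile point for the
partial-arc profile, and 4×10⁵ per evaluation for conversion factors;
unit tests use smaller counts with tolerances set from the estimators'
own reported uncertainties.

## Known limitations

* Coherent scattering without form-factor angular weighting and
  incoherent scattering without binding functions each overweight
  wide-angle scatter by a few percent of the scatter component near
  surfaces.
* Cross sections for Z > 13 (P, S, Cl, Ar, K, Ca) are extrapolated and
  run ~5% high, so bone doses are the least accurate.
* The spectrum model has no characteristic lines; at 100–125 kVp with a
  tungsten anode these carry a few percent of fluence.
* Fluence separability (transverse × radial) is an approximation forced
  by the two measured axes; true bowtie fluences are not exactly
  separable off-axis.
* The engine computes collision kerma at POIs, not full 3-D dose grids,
  and no electron transport — appropriate for kV energies only.
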