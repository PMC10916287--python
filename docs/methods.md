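# Methods

`dropxtal` models and measures the quantitative core of droplet-microfluidic
microcrystal preparation: how droplet volume sets crystal size and number,
and how fast the contents of a transported droplet homogenize. This note
records the models, their assumptions, the defaults and the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

Units are fixed package-wide: volumes in picolitres, lengths/diameters in
micrometres, number densities per nanolitre, concentrations in mg ml⁻¹,
velocities in mm s⁻¹, diffusivities in µm² s⁻¹, times in milliseconds,
frequencies in kHz. All converters live in `dropxtal.units`.

## Encapsulation statistics

Random loading of crystals or seeds into droplets is modelled as Poisson:
a suspension at density ρ_n (nl⁻¹) filling droplets of volume V (pl) gives a
mean occupancy λ = ρ_n·V/1000 and P(K=k) = e^(−λ)λ^k/k!. The Poisson choice
is an assumption — dilute, independent, well-stirred objects — and is the
standard model for stochastic encapsulation; it is consistent with the
observed occupancies at both ends of the volume range (λ ≈ 15.5 at
80 nl⁻¹ × 194 pl; λ ≈ 0.006 at 7 nl⁻¹ × 0.89 pl). The fraction of occupied
droplets holding exactly one object, P(K=1|K≥1) = λe^(−λ)/(1−e^(−λ)),
decreases strictly with λ and approaches 1 as λ→0: dilution buys uniformity
at the price of empty droplets.

Droplets are treated as spheres: d = (6V/π)^(1/3) and SA:V = 6/d. Channel-
confined droplets can be plugs, but reported droplet sizes in this field
use the sphere-equivalent convention, and all volume↔diameter bookkeeping
here follows it. Generation frequency is conservation of the dispersed
phase: f = Q_aqueous/V.

`fit_lambda` estimates λ by the sample mean (the Poisson MLE) with an exact
Garwood χ² interval by default; a percentile bootstrap is available. The
exact interval was chosen because the workflow lives at λ ≤ 0.1 where
normal approximations are poor. Note the sampling reality: with n = 500
droplets at λ = 0.1 the estimator's relative standard error is ~14 %, so a
±15 % point-recovery criterion cannot hold at the usual 18/20-seed rate;
the tests therefore assert interval *coverage* at λ = 0.1 and point
recovery only in the count-rich regime (λ = 1.5).

`fit_density_loss` fits a descriptive line of crystal density against SA:V.
The correlation between density loss and interfacial area is reported as a
fit only; no mechanistic claim is made.

## Mass-balance crystal sizing

A droplet of volume V with post-mix protein concentration c₀ above residual
solubility c_s can deposit protein mass V(c₀−c_s). With k crystals sharing
the droplet and packing density ρ (protein mass per crystal volume), each
crystal reaches volume V(c₀−c_s)/(ρk), and for a square prism of aspect a
(length:width), length = (volume·a²)^(1/3). Consequences the tests pin
down: length ∝ V^(1/3) at fixed k, and exact mass conservation
k·w²·L·ρ = V(c₀−c_s).

Defaults and why they are explicit parameters:

* ρ = 800 mg ml⁻¹ — typical of tetragonal lysozyme; never printed in
  crystallization protocols, so it must be configurable and visible.
* a = 2.7 — between the elongated 7×2 µm batch habit and near-equant
  micro-habits; predictions depend on a only as a^(2/3).
* c_s = 0 — high-salt lysozyme conditions drive near-complete depletion;
  set c_s > 0 for proteins with appreciable residual solubility.

Seed dilution follows the same balance: x-fold fewer seeds sharing the same
protein gives L = L₀·x^(1/3). This is deliberately an **upper bound**: the
cube-root law predicts 23.7 µm and 51.1 µm for 10× and 100× dilution of an
11 µm baseline, while observed crystals reach only ~18 and ~30 µm.
Incomplete depletion at low seed counts and non-linear seed-count scaling
both push below the bound; the model is documented as such and is not
tuned to match.

Elongated habits are capped at the droplet diameter
(`axial_ratio_cap`): needles cannot elongate past the compartment, so the
realized axial ratio L/w falls as droplets shrink — monotone non-decreasing
in droplet diameter by construction.

Into-crystal substrate transport is modelled as a slab of half-thickness
equal to the travel distance, faces held at the bath concentration,
initially substrate-free; the centre reaches a fraction of the bath value
at the time given by the textbook Fourier series, solved by bracketed
root-finding on the scaled time. Slab (not spherical) geometry matches the
"travel distance into the crystal" framing; the default centre fraction is
0.5. The inverse (`diffusivity_from_time`) converts an observed arrival
time to an effective diffusivity: 0.4 ms over 1 µm at fraction 0.5 implies
D_eff ≈ 950 µm² s⁻¹, the small-gas scale. No nucleation kinetics, growth
rates or lattice-specific corrections are modelled.

## Synthetic data

The generator emulates the statistical structure the measurements assume,
with a single `numpy.random.Generator` stream per image so identical seeds
are bit-identical:

* droplet diameters ~ Normal(d̄, CV·d̄) truncated at 0.2·d̄, placed by
  rejection sampling without overlap (bounded retries, then an error);
* per-droplet crystal counts ~ Poisson(λ);
* crystals as oriented rectangles (square-prism silhouettes), lengths
  Normal(L̄, CV·L̄) floored at 0.5 µm, orientation uniform on [0°, 180°),
  length capped at the droplet diameter, with bounded-retry non-overlap
  placement inside each droplet;
* rendering: bright interior, dark rim annulus, darker rods, ~1 px
  anti-aliased edges, 16-bit grayscale, optional Gaussian noise.

Mixing sequences map concentration affinely to intensity with the dye
darkening the image. A consequence worth stating: the CV of raw intensity
equals the CV of concentration only when the mean concentration is half
the dye stock (volume fraction 0.5); at other fractions the analyzer's
absorbance inversion (CV of I₀ − I, with I₀ the dye-free level) recovers
the concentration CV exactly, and the dual-path agreement test uses it.

What passing these tests shows: the measurement code recovers known truth
under the stated statistical structure. What it does not show: robustness
to optical artefacts. There is no PSF, depth of field, illumination
gradient or polydispersity failure mode in the generator, and the
measured micrographs of the real study are not reproduced.

## Droplet and crystal measurement

Detection is deliberately unsupervised and parameter-driven: global Otsu
threshold → hole filling (crystals are darker than the interior) →
distance-transform watershed to split touching droplets → circularity
filter (4πA/P², Crofton perimeter, default ≥ 0.8). Diameters are
area-equivalent circle diameters in µm. Edge-touching droplets are excluded
from summaries by default because their diameters would be truncated; the
original study's handling of partially imaged droplets is not documented,
so this is a stated default, not a reconstruction.

Crystals are segmented inside each (slightly eroded) droplet mask as
pixels darker than the interior median by max(25 % of the median, 4 robust
SDs), with a 4 px² minimum area to suppress speckle. Each connected region
is measured along its principal axes; with anti-aliased edges a
mid-contrast threshold lands on the physical boundary, so pixel-centre
spans are reported directly (no +1 px correction). Exactly axis-aligned
rods are measured ~1 px short by this convention; orientations drawn from
a continuous distribution make this a measure-zero case.

Population summaries report droplet diameter mean/CV, occupancy histogram,
λ̂ with its Garwood interval (delegating to `fit_lambda`), and crystal
length mean/CV. A single measured crystal reports CV as explicitly
undefined (`None`), never 0.

End-to-end recovery is tested at 500 droplets, λ = 0.1, 3 µm ± 15 % rods,
12 µm droplets at 3 % size CV, imaged at 0.25 µm/px (oil-immersion-scale
sampling), seeds 1–3: λ̂ within 20 % and length CV within 5 points of
truth. These sizes keep the suite fast while leaving the λ̂ sampling error
(~14 % relative SD) visible — the 20 % band is a statistical statement, not
a precision claim about the detector.

## Mixing simulation

The droplet is a 2-D disk in its co-moving frame. The recirculation driven
by transport past the walls is prescribed analytically as two
counter-rotating lobes from the stream function ψ = A·y·(1 − r²/R²), which
vanishes on the rim (the boundary is a streamline) and is incompressible
by construction; A is scaled so the peak speed is α·U with α = 0.5 by
default. The study gives images of the internal circulation but no flow
field, so α is a free calibration constant: **absolute mixing times are
calibration-dependent and only orderings and directions are claimed**.

Transport of the dye is a conservative finite-volume scheme: face-normal
velocities are differences of corner ψ values (hence exactly
divergence-free, with zero flux through every blocked face), advective
face states use MUSCL reconstruction with a minmod limiter, and diffusion
is an operator-split explicit conservative update. Total dye mass is
conserved to round-off; the suite asserts ≤ 0.1 % drift on every shipped
configuration. Stability (combined advective CFL 0.4 and diffusive number
0.24) is checked before the run; an explicit `dt` violating the bound is
rejected up front. The grid must resolve the droplet with at least 64
cells across; shipped configurations use 64.

Initial conditions:

* **generation** mode — N alternating dye/solvent lamellae (default
  N = 4) with widths in ratio φ:(1−φ), a surrogate for stream thinning at
  the droplet generator. Bands are stacked along the flow axis on the
  area-quantile coordinate, so the dye area fraction is exactly φ and each
  lobe receives exactly a φ share (bands stacked across the flow axis
  instead would partition unequal dye shares into the two lobes and leave
  a spurious diffusion-limited cross-lobe tail).
* **fusion** mode — two regions split by a single chord at area fraction
  φ: a fused droplet pair has one droplet-scale interface and no thinning.

Simulation time zero is the lamellar/fused initial condition — a stated
convention; the experimental "stream combination" landmark has no exact
simulation analogue.

The mixing measure is the CV of the scalar over the fluid mask, with the
mixing time defined as the first linearly interpolated crossing of the 5 %
threshold (0 if the trace starts below it; NaN — an explicit sentinel — if
it never crosses). `extract_kymograph` applies the same statistic to
rendered frame stacks, one CV per frame; `mixing_time_stats` aggregates
per-droplet crossings as mean ± sample SD, counting never-crossing traces
separately.

Behaviour the suite pins down, and its limits:

* the volume-fraction ordering t(φ=0.5) < t(0.3) < t(0.1) at 300 mm s⁻¹ in
  39 pl droplets — reinforced by the initial CV itself, √((1−φ)/φ);
* velocity monotonicity over 60/150/300 mm s⁻¹ paired with the shrinking
  droplet volumes higher shear produces (126/93/39 pl; the middle volume
  is a linear interpolation between the observed endpoints);
* fusion slower than generation at matched volume, velocity and φ
  (126 pl, 100 mm s⁻¹ — the velocity at which droplet fusion operates,
  where the striation-width mechanism is resolved). At the highest
  velocity the steady 2-D surrogate's threshold crossing becomes dominated
  by an initial-condition-independent tail (slow corner/core structures of
  the steady flow), and the generation/fusion distinction degenerates —
  a known limitation of a steady two-lobe surrogate for a 3-D,
  time-dependent droplet flow;
* a diffusion-only run (U = 0) agrees with an independently coded
  finite-difference oracle at a 4× finer step within 5 %;
* a small interior no-flux obstacle (1 % of the droplet area, the crystal)
  changes the mixing time by well under 10 % — crystals ride passively.
  The obstacle is implemented by pinning ψ to zero on adjacent corners, so
  conservation and discrete incompressibility survive exactly.

The dye diffusivity default is 400 µm² s⁻¹, the scale of a small organic
dye (~570 Da) in water; it is a parameter, not a fit. Absolute simulated
times at the shipped calibration land at the right order of magnitude
(single-digit milliseconds for tens-of-picolitre droplets at hundreds of
mm s⁻¹) but are not, and are not claimed to be, the experimental values.

## Serial-crystallography accounting

`ssx_rates` computes hit rate = 100·hits/images and indexing rate =
100·indexed/hits, with the indexing rate explicitly undefined (not zero)
when there are no hits. Values are kept unrounded; display rounds to one
decimal. Published tables occasionally round such cells inconsistently
with their own count ratios; this package always reports the computed
ratio.

## Reproducibility

Every stochastic component takes one integer seed driving one generator
stream; pipeline reruns with the same config are bit-identical, and the
effective config (with the package version) is written alongside every
run's outputs. The simulation and measurement paths are fully
deterministic given their inputs.
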