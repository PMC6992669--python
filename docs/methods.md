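# Methods

## Scope and model chain

The package estimates the exposure of the human tympanic membrane to pulsed
plane waves at 30, 60 and 90 GHz.  The chain is: tissue dielectric model →
voxel phantom → pulsed FDTD solution → sensor records → power density (PD)
and SAR → lumped bioheat temperature rise → uncertainty budget.  Each stage
is usable on its own and is cross-checked against an independent closed form
where one exists (transfer matrices for layered reflectance, exponential
decay for penetration, analytic Gaussian integrals for the pulse, an
exponential solution for perfusion decay).

## Dielectrics

Tissue permittivities are tabulated at 37 °C for six tissues
(bone/cartilage, dermis, epidermis, stratum corneum, the fibrous lamina of
the membrane, mucous membrane) at the three band frequencies, shipped as a
checksummed CSV.  The sign convention is ε = ε′ − iε″ with ε″ ≥ 0 under
e^{+iωt}; optics-style internals (complex index N = n + iκ, characteristic
matrices) use the conjugate e^{−iωt} form, and only convention-independent
real quantities cross module boundaries.  Derived quantities:

* σ = ε₀ ε″ 2πf (S/m) — the equivalent conductivity the solver and SAR use;
* n = √((|ε|+ε′)/2), κ = √((|ε|−ε′)/2) — principal square root of ε;
* δ = c/(ωκ) — the **field** 1/e penetration depth.  Power decays as
  e^{−2z/δ}, which is exactly the exponent the PD-based heating-rate formula
  uses, so that formula consumes this δ.  (The power 1/e depth would be
  δ/2; the choice is stated here once and used consistently.)
* α = 2ωκ/c = 2/δ — power absorption coefficient.

Between the three tabulated frequencies ε′ and ε″ are interpolated linearly
in log f; outside 30–90 GHz the table refuses.  Only anchor frequencies are
used by the solver runs in this package.

The temperature adjustment of literature permittivities measured at room
temperature multiplies ε′ and ε″ by the ratio of a water model evaluated at
target and measurement temperature — soft tissues are ~70–75 % water, which
dominates mm-wave dispersion.  The water model is a single Debye term with
static permittivity from the Malmberg–Maryott (1956) polynomial and
high-frequency limit and relaxation time from Kaatze (1989); coefficients
live in a pinned CSV so the adjustment is bit-for-bit reproducible.  Any
standard parameterisation would do: the adjustment is a ratio, exactly
invertible, and the identity at equal temperatures.  The model reproduces
liquid-water absorption of ≈3.6×10³ m⁻¹ at 30 GHz / 25 °C.

A documented inconsistency: the stratum-corneum refractive index at 30 GHz
is often quoted as 3.60, but the closed form applied to the tabulated
ε = 10 − 6i gives 3.29.  The 60 and 90 GHz values (2.39, 1.99) reproduce
exactly.  The package does not attempt to reverse-engineer the discrepancy;
the table is authoritative.

### Reflectance oracles

`fresnel_normal_incidence` and `transfer_matrix_stack` exist to validate the
solver, and to answer layered-membrane questions cheaply.  The transfer
matrix uses the standard characteristic-matrix product with complex indices;
with N = n + iκ under e^{−iωt} the off-diagonal entries carry −i·sinφ (the
+i variant belongs to the opposite time convention and produces R > 1 for
lossy stacks — the pulsed-solver cross-check catches exactly this class of
error, which is why both routes are kept).  R + T + A = 1 holds to 1e−10;
an optional exit half-space makes the zero-layer stack degenerate to the
bare Fresnel interface.  Oblique incidence is out of scope: the solver's
oracle need is normal incidence.

## Phantom

Uniform cubic voxels, labels on cell centres, canal axis +x, anterior +y,
superior +z; voxel (i,j,k) spans the half-open cube at origin + i·Δ.  The
canal is an elliptical cylinder (horizontal semi-axis 3.5 mm, vertical
4.5 mm, 25 mm deep) carved through bone/cartilage, with a 10 % inferior
widening ramped over the last quarter of its depth.  The wall lining is
stratum corneum facing the lumen (deep-canal thickness 0.1 mm) over
epidermis (0.02 mm), built by morphological dilation so it follows the
widened cross-section.  The membrane is a planar four-layer slab tilted 25°
from its superior margin (layer thicknesses measured along the slab
normal); behind it lie a small air-filled middle-ear cavity and a
bone/cartilage baffle that absorbs whatever is transmitted.  Layers thinner
than one voxel are inflated to one voxel with a warning, and the effective
layer extents are recorded in the phantom metadata — sensor placement reads
those, not the nominal thicknesses.

The pinna is modelled as three rounded bone/cartilage blocks (tragus,
antitragus, antihelix) at a configurable scale (default 10 mm).  No
anatomical source constrains their dimensions, so any full-scale result
that depends on them inherits that arbitrariness; the reduced-scale test
scenario therefore runs without them by default (see below).

## FDTD solver

Standard Yee staggering, explicit leapfrog, timestep dt = fraction /
(c·√Σ1/Δᵢ²) with fraction 0.95 by default.  Materials are narrowband: each
run evaluates every tissue's (ε′, σ) at the run's carrier and uses the
ordinary lossy-dielectric update — separate runs per frequency, no
dispersive update equations.  Boundaries are 8-cell convolutional PML
(cubic-graded σ, σ_max = 0.8(m+1)/(η₀Δ), κ = 1, α = 0) backed by PEC; a
first-order Mur boundary serves the 1-D solver.

The excitation is a soft electric-field source on a full transverse plane
just inside the −x PML: a cosine carrier under a Gaussian envelope whose
total window (default 100 ps) has 1 % edge amplitude, i.e. envelope σ =
window/6.07.  Windows shorter than 1.5 carrier cycles are rejected (a 20 ps
window is valid only at 90 GHz).  Oblique incidence applies a per-cell
arrival-time gradient (k̂·r)/c across the plane — the wave-vector is
rotated, never the phantom, so sensor coordinates are angle-invariant.
Polarisation is ẑ except for the superior tilt (k in the x–z plane), which
uses ŷ.  The radiated amplitude of a soft plane source is frequency- and
timestep-dependent, so quantitative scenarios always pair the exposure run
with a free-space reference on the identical grid and normalise by the
measured incident field; this also makes cross-frequency comparisons fair.

The solver is deterministic — no randomness anywhere — and aborts with the
step index if fields go non-finite.  In 1-D, reflected waves are separated
from incident ones by linearity (subtracting an empty-grid run with the
same source) rather than by total-field/scattered-field bookkeeping, and
carrier-frequency reflectance/transmittance come from single-frequency DFTs
of those records.  Layer thicknesses are voxelised to whole cells and the
transfer-matrix comparison is evaluated for the voxelised thicknesses, so
the two routes describe the same physical stack.

Verification anchors (all in the test suite): free-space pulse speed within
1 % of c; plane-source aperture uniformity within 2 %; reflectance and
transmittance of random ≤5-layer tissue stacks within 1 % absolute of the
transfer matrix (measured ~1e−4); field decay in a lossy half-space within
3 % of e^{−z/δ} (measured ~0.3 %); lossless-cavity energy constant to
machine precision using the mixed discrete energy εE²ⁿ + μH^{n+1/2}H^{n−1/2}
(the exact invariant of the Yee scheme); near-membrane peak |E| changing
0.6 % when the grid is refined from 0.2 to 0.1 mm on a fixed, fully
resolvable geometry.

## Sensors

Point sensors record per-step |E|, |H| and components at a voxel; planar
sensors record a peak-over-time |E| map plus the instantaneous series at the
plane centre (both views, since either may be wanted from a figure).  The
default full-ear inventory is 18 objects: canal-entrance and 20 mm points,
four planes (transverse at 20 mm, longitudinal bisection, membrane surface,
0.03 mm inside the membrane), a six-point array at the epidermis/fibrous
junction 0.03 mm inside the membrane and a matching array 0.02 mm beyond it
in the middle ear.  Array layout: two central sensors and a four-point
peripheral ring at 0.65 of the membrane semi-axes.  Thin-membrane sensors
snap along x into the named tissue of the *built* phantom, so they stay
valid at any resolution.

## Dosimetry

PD at a tissue sensor is the product of that sensor's separately taken peak
|E| and peak |H| (paired peaks, matching how tabulated per-sensor E and H
values are combined); the peak of the instantaneous E·H product is available
by flag.  In air PD = E²/377.  SAR = σE²/(2ρ) with E the peak sensor
magnitude ("peak" convention); the "rms" convention drops the /2.  Records
are normalised to an incident level by scaling E and H with
incident_E/source_amplitude (PD and SAR then scale by the square — valid by
linearity, since nonlinear tissue response is excluded); double
normalisation raises.  Array statistics use the sample SD (n−1).  The
reference levels are 10 W/m² ↔ 61.4 V/m and 50 W/m² ↔ 137 V/m; occupational
results are exactly 5× public ones (the incident-PD ratio).

## Thermal model

The membrane is a single lumped node: the conduction term of the Pennes
balance is not spatially resolved (for sub-degree rises over seconds it is
negligible; an explicit lumped loss coefficient exists as a sensitivity
hook, default 0).  Perfusion removes ρ_b c_b BP ρ_t (T − T_b) per unit
volume — BP is stored in SI m³ kg⁻¹ s⁻¹ and multiplied by ρ_t for
consistent units (fibrous tissue 6.3e−8, i.e. 3.8 ml kg⁻¹ min⁻¹).
Integration is explicit Euler at dt = 0.1 s over 5 s; with the fibrous
parameters the perfusion time constant is c_t/(ρ_b c_b BP) ≈ 1.25e4 s, so
stability is trivial, Euler agrees with the exponential solution to <0.5 %,
and the perfusion correction to a 5 s rise is ~0.02 % — the quantitative
content behind "blood flow is negligible for short exposures".  The
headline case integrates the occupational 90 GHz orthogonal rate
6.45e−3 °C/s to 0.032 °C.

Two initial-rate routes are reported side by side: SAR/c_t (method 1) and
PD·e^{−2z/δ}/(δρc) (method 2); on consistent fields they agree within a
factor ~2, and the report asserts a factor-2.5 consistency band.  A
convention ambiguity is exposed rather than hidden: published tabulations
of this chain are internally consistent with the *rms* SAR convention
(rates equal to 2·SAR_peak/c_t) feeding the temperature step, so the
report's default convention is "rms" and the flag used is recorded in the
table metadata; "peak" is available.

## Uncertainty budget

Symmetric fractional SDs (literature permittivity 8 %, temperature
adjustment 2 %, thermal properties 5 %, meshing 3 %) combine by
root-sum-square (≈10.1 %).  The permittivity-perturbation harness reruns a
scenario with ε′ and ε″ scaled ±10 % and reports the fractional change of
the membrane field; because SAR and temperature go with the field squared,
those bounds are mapped through (1+g)²−1 before entering the budget.  The
asymmetric bounds are then **added linearly per side** to the symmetric
RSS.  Design note: quadrature addition was considered and rejected — the
perturbation bounds are worst-case excursions, not independent SDs, and
quadrature visibly understates the negative side (−41 % instead of ≈−50 %
for field bounds of (+5.5 %, −22.1 %)); linear addition is the conservative
choice and matches how such budgets are typically quoted.  The desk-scale
harness scenario is the 1-D membrane stack (its perturbation response
matches the transfer matrix within 1 %); the 3-D mini ear can be
substituted at higher cost.

## Reduced-scale scenario and what passing tests show

The full-size model (≈5×10⁸ cells at the published resolutions) is
cluster-scale; the solver accepts such configurations but the tested path
is the "mini ear": full canal cross-section and complete membrane layering,
canal shortened to 8 mm, 0.15 mm voxels (~8×10⁵ cells), ~15 s per
frequency on one CPU.  8 mm is long enough for one membrane-reflection
round trip inside a 100 ps window at 90 GHz.  At this spacing the membrane
layers inflate to one voxel each, and the pinna blocks are disabled by
default: their unconstrained geometry adds edge diffraction that, at
reduced scale, can mask the canal/membrane frequency trend the scenario
isolates (with them enabled, an interference minimum appeared at 60 GHz).
What the reduced-scale tests show is therefore the *qualitative* physics:
membrane peak PD (normalised to the measured incident PD) strictly
increasing 30 → 60 → 90 GHz at orthogonal incidence, and central membrane
sensors reading more than the peripheral mean.  They deliberately do not
assert full-scale magnitudes (penetration fractions, exact central
enhancement ratios, absolute table values), which depend on the full canal
length, graded meshing and pinna details.

Synthetic fixtures likewise emulate only what their consumers need:
plane-wave records have exact analytic E/H ratios and optional seeded
multiplicative noise, but no multipath, no angular spectrum and no sensor
noise floor — passing dosimetry tests on them validates arithmetic and
conventions, not field prediction.

## Numerical choices and limitations

* 1-D oracle runs: spacing min(λ₀/(120·n_max), thinnest layer/4), Courant
  0.999, 8-cycle pulses; single-frequency DFT over fully decayed records.
* 3-D: Courant fraction 0.95, CPML 8 cells, NaN check every 100 steps,
  auto run length = pulse window + 3 axial transits.
* Materials are sampled at cell centres (no sub-cell averaging at
  interfaces); the refinement test bounds the consequence.
* Tie-breaks: layer bins are half-open in the slab-normal coordinate;
  voxel lookup floors to the containing cell.
* Not modelled: dispersive (multi-pole) tissue response within a run,
  oblique-incidence transfer matrices, 1 g/10 g volume-averaged SAR,
  convective/radiative heat exchange at the membrane surfaces, metabolic
  heating, anatomical realism beyond the simplified geometry.
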