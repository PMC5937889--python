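# Methods

## The model

A brown adipocyte (BA) is treated as a grand-canonical thermodynamic system
exchanging heat and particles with its surroundings. For sustained
thermogenesis the change in internal energy is negligible (dU ≈ 0): the
free-proton inventory of a whole cell is ~10⁵ protons, about six orders of
magnitude less than one second of full-capacity consumption, so any sustained
heat release must be continuously paid for by chemical resupply (glucose
oxidation, NADH/FADH₂ turnover) rather than drawn from a store. Volume change
and motility of mitochondria in the crowded cytosol are taken as zero, and
transient Ca²⁺ fluxes are ignored for *sustained* heating (they matter for
the initial transient but are not modelled here). What remains of the work
terms is the electrochemical one: the heat released equals pmf · dH⁺.

Combining this with Fourier's law over the surface of a spherical organelle
of radius r gives the surface gradient magnitude

    |∇T| = pmf · I_H⁺ / (4π κ r²),

and substituting the source into the thermal diffusion equation
∂T/∂t = D∇²T + H/C gives the central result: because pmf and I_H⁺ are
uniform across a single organelle, the heating term is spatially uniform,
the temperature field stays harmonic (∇²T = 0), and

    ∂T/∂t = η · pmf · I_H⁺ / (V C).

η is the thermogenic efficiency: 1 for NE+ATP co-stimulated BA (all
electrochemical power degraded to heat through UCP1), ≈ 0.6 for typical
cells (≈ 40% of glucose free energy is conserved as ATP), 0 for
erythrocytes. The resting state is I_H⁺ = 0 and ∂T/∂t = 0; any nonzero
UCP1 current defines the thermogenic state.

### Two regimes, deliberately both implemented

The harmonic (uniform-heating) solution neglects conductive loss; the
conduction-limited steady state neglects the time dependence. The package
implements both and does not adjudicate between them, because their
juxtaposition *is* the point: for the canonical 20 pW source the conduction
steady state yields a surface excess of ~4×10⁻⁶ K while the uniform-heating
model heats at ~4.8 K/s — applying the steady-state estimate to a
thermogenic cell is what produces the notorious ~10⁻⁵ discrepancy with
measured intracellular temperature changes. Physically, the uniform-heating
law describes the initial/insulated limit and the conduction solution the
long-time limit of the same diffusion equation; real organelles sit between
them.

## Parameters and defaults

| Parameter | Default | Units | Why |
| --- | --- | --- | --- |
| Δψ | 200 | mV | typical mitochondrial pmf magnitude; the default config puts the whole pmf in the electrical term (see below) |
| ΔpH | 0 | — | decomposition of the 200 mV into Δψ and ΔpH is left to the user |
| T | 310 | K | body temperature |
| capacitance | 1.0 | pF | within the measured 0.5–1.2 pF mitoplast range; 1.0 pF × 100 pA/pF reproduces the 100 pA working current |
| current density | 100 | pA/pF | within the measured 60–110 pA/pF UCP1 range |
| V | 1 | µm³ | canonical mitochondrial volume; as a sphere, r = 0.6204 µm |
| C | 4.18×10⁶ | J K⁻¹ m⁻³ | water at 37 °C — cytosol is conventionally water-like; not printed in the source material, chosen once |
| κ | 0.6 | W m⁻¹ K⁻¹ | water at 37 °C, same reasoning |
| cell | 20 µm, pH 7.4 | — | canonical BA for the proton-pool numbers |
| glucose uptake | 0.18 | pmol/h·cell | basal uptake; stimulated uptake is tens to hundreds of times higher |
| protons/glucose | 24 | — | glucose + 6 H₂O in the TCA cycle |
| mitochondria/cell | 1000 | — | canonical BA count |
| Ea | 6.55 | kcal/mol | measured dye activation energy |
| Tref | none | K | the reference temperature of a dye calibration is experiment-specific; deliberately has no default and must be supplied |

Sign conventions: Δψ is stored as a nonnegative magnitude (the membrane
potential is physically negative inside); ΔpH = pH_in − pH_out so an
alkaline matrix adds ~61.5 mV per pH unit at 310 K; the inward thermogenic
current is positive; the negative radial gradient at the surface is reported
as a magnitude plus a direction string. This keeps every worked number
positive and avoids double-negation bugs. The factor "2.3" in the
chemiosmotic relation is evaluated as ln 10 = 2.302585…; a `legacy_2_3`
flag reproduces the rounded literal.

## Numerical choices

* **Drive integration** (`integrate_temperature`) is exact: for a
  piecewise-constant schedule the temperature is piecewise linear in time
  and is accumulated in closed form, so synthetic fixtures carry no solver
  error.
* **Diffusion solver**: finite-volume discretization on a uniform radial
  grid (conservative — the discrete boundary outflow balances the source
  power to round-off at steady state), backward-Euler time stepping
  (unconditionally stable; the bath relaxation time R²/D ≈ 17 ms for the
  default 50 µm bath is resolved with dt = 1–2 ms). The source indicator is
  applied per cell by exact volume fraction, which removes staircase error
  where the organelle surface falls between grid points. Symmetry at r = 0
  (zero flux through the centre), Dirichlet bath temperature at R_outer.
  R_outer defaults to 50 µm ≫ the organelle to approximate an unbounded
  sink. Verified against the closed-form conduction steady state (parabolic
  inside the source, a + b/r outside, value- and flux-continuous at the
  surface): the volume-weighted relative L2 error is ≈ 0.1% at N = 256 and
  decreases monotonically with refinement.
* **Laplacian residual checker**: conservative second-order central
  differences; at r = 0 the symmetric limit 3·∂²T/∂r² is used. A uniform
  field gives an exactly zero residual — the testable content of the
  harmonic-solution claim — and 1/r residuals vanish at second order.
* **State classification tolerance**: currents below 10⁻⁶ pA count as
  steady, a documented threshold for floating-point drives.
* **Thermometry guards**: the inversion denominator must stay positive
  (otherwise a calibration-range error); temperatures outside [250, 350] K
  warn. The calibration uses the molar gas constant with the molar Ea —
  mixing per-particle k_B with a molar Ea would be wrong by N_A. As written,
  the relation implies nr < 1 ⇒ T < Tref; since the dye pair's direction is
  not fixed by the relation itself, `sensitivity_sign = −1` flips it.
* **Rate estimation**: sliding-window least-squares slopes (default window
  5 samples) rather than pointwise differences; the "max rate" of a noisy
  trace is the max windowed slope and the "mean rate" is the global OLS
  slope, labelled as a time average. Exact on noiseless linear traces.
* **Drive recovery**: I = slope·V·C/(η·pmf) with the OLS slope; the
  confidence interval propagates the slope's standard error through the
  linear rescaling (t distribution). The standard error is computed directly
  from the residuals so an exactly flat trace yields a zero-width interval
  at zero rather than NaN.
* **Noise on ratio traces** that would produce nr ≤ 0 is
  rejection-resampled, not clipped; clipping would bias the inversion.

## What the synthetic data does and does not emulate

`mitotherm.synthetic` generates traces from the forward model itself
(piecewise-constant drives, additive Gaussian noise on T or on nr,
seed-reproducible). It emulates the *structure* of stimulation experiments —
rest / NE / NE+ATP / CCCP segment labels, 1 Hz sampling, minute-scale
recordings — but not imaging physics: no shot noise, photobleaching, focus
drift, segmentation error, or cell-to-cell variability. NE-only stimulation
in real BA can produce heating, constant temperature, or occasional cooling;
cooling lies outside the η ∈ [0, 1] model and is representable here only as
a zero-drive label. Passing the recovery tests therefore shows the inference
machinery is correct under the stated noise model, not that real imaging
data would be equally well-behaved. The published experimental summary
statistics (max rate ~0.06 K/s, sustained average <~0.005 K/s) are used as
fixed inputs to ratio computations, not re-derived — the underlying raw
imaging data are not public.

## Known limitations and open points

* **Heat loss is not subtracted from the heating law**: the ~4.8 K/s is a
  capacity, an upper bound valid while conduction is negligible, not a
  prediction of observed cellular heating (observed rates are ~100–1000×
  smaller).
* **Proton buffering is out of scope.** The "free pool" is the
  instantaneous V·10^(−pH)·N_A count; cellular buffering capacity (which
  dwarfs the free pool) is deliberately excluded because the headline ~10⁵
  figure is defined on the free pool.
* The oft-quoted ~6.3×10² free protons *per mitochondrion* is not
  reproducible from pH 7.4 and a 1 µm³ volume (which give ~24); it would
  require a ~26 µm³ compartment or a pH near 6. The package reports the
  formula's output for whatever parameters are supplied and leaves the
  discrepancy documented rather than patched.
* The "<1% of thermogenic capacity" figure refers to the sustained average
  (0.005/4.78 ≈ 0.10%); the transient experimental maximum gives
  0.06/4.78 ≈ 1.25%. Both ratios are computed; transient Ca²⁺ contributions
  relevant to the maximum are outside the model.
* Geometry is 1-D radial: no aspherical organelles, no interaction between
  neighbouring mitochondria, no advection, and κ and C are
  temperature-independent.
* Whether the published sustained-average rate averages over time, over
  cells, or both is not stated; the package's summary reports a time
  average and labels it as such.

## Problem sizes

Defaults used by the tests and examples: diffusion grids of 64–512 points
over a 50 µm bath integrated to 0.4 s (≈ 23 bath relaxation times) at
dt = 2 ms; synthetic traces of 600 samples at 1 Hz; recovery coverage
estimated over 100 seeds. All are the package's own choices of desk-scale
problem sizes for a closed-form-verifiable model.
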