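# mitotherm

Thermal-physical modelling of mitochondrial thermogenesis in brown
adipocytes (BA).

Whether a single cell can measurably heat itself has been a long-running
dispute: conduction-based estimates put the steady-state temperature rise of
a micron-scale heat source at a few microkelvin, five orders of magnitude
below the ~0.1–1 K changes reported by fluorescent thermometry. `mitotherm`
implements the model that resolves the tension: a thermogenic mitochondrion
is not at steady state. During sustained thermogenesis the internal-energy
change is negligible (dU ≈ 0), the heat released equals the electrochemical
work of the proton flow, and — because the proton-motive force and current do
not vary with radius inside one organelle — the temperature field is
spatially harmonic (∇²T = 0) and rises linearly in time:

```
∂T/∂t = η · pmf · I_H⁺ / (V C),      pmf = Δψ − (2.3 R T / F) · ΔpH
```

where `I_H⁺` is the inward proton current (the UCP1 current in stimulated
BA), `V` the mitochondrial volume, `C` the volumetric heat capacity of the
surroundings, and `η` the thermogenic efficiency (1 for NE+ATP-stimulated
BA, ≈0.6 for typical cells, 0 for erythrocytes). The package is aimed at
cell biophysicists and bioenergeticists who want the model's worked numbers,
the conduction-limit comparison, proton-pool budgets, and dye-ratio
thermometry conversions as tested, composable functions.

## What's inside

| Module | Contents |
| --- | --- |
| `mitotherm.units` | physical constants, SI conversions, Nernst slope 2.303·RT/F |
| `mitotherm.bioenergetics` | pmf from Δψ and ΔpH, UCP1 current from mitoplast capacitance × density, power P = pmf·I, proton flux |
| `mitotherm.thermal` | heating rate, surface temperature gradient, steady vs thermogenic state, exact piecewise drive integration, capacity utilization |
| `mitotherm.diffusion` | implicit radial diffusion solver, analytic conduction steady state, spherical Laplacian residual checker |
| `mitotherm.budget` | free-proton pools, consumption vs glucose supply, depletion times, sustainability report |
| `mitotherm.thermometry` | dye-ratio ↔ temperature conversion (Arrhenius calibration, Ea ≈ 6.55 kcal/mol), sliding-window rate estimation |
| `mitotherm.synthetic` | reproducible synthetic temperature / dye-ratio traces, proton-current recovery with confidence intervals |
| `mitotherm.cli`, `mitotherm.io` | `mitotherm` command-line tool, YAML/JSON config, CSV trace I/O |

## Worked example

The canonical working point is a 1 µm³ spherical mitochondrion with
pmf = 200 mV and a UCP1 current of 100 pA (a 1.0 pF mitoplast at
100 pA/pF) in water-like cytosol (C = 4.18×10⁶ J K⁻¹ m⁻³,
κ = 0.6 W m⁻¹ K⁻¹):

```console
$ mitotherm report
pmf_mV:
  value: 200.0
  from: chemiosmotic relation
proton_current_pA:
  value: 100.0
  from: capacitance x density
power_W:
  value: 2.0000000000000002e-11
  from: P = pmf * I
heating_rate_K_per_s:
  value: 4.784688995215311
  from: dT/dt = eta*pmf*I/(V*C)
surface_gradient_K_per_m:
  value: 6.892783232215557
  direction: inward-directed heat flux => negative radial gradient
  from: Fourier's law over the sphere
proton_flux_per_s:
  value: 624150907.4460763
  from: I / e
capacity_utilization_pct:
  value: 0.1045
  observed_rate_K_per_s: 0.005
budget:
  pool_protons: 100424.46151585349
  theoretical_demand_pmol_per_s: 1.0364269656262173
  observed_demand_pmol_per_s: 0.001
  supply_pmol_per_s: 0.0012000000000000001
  depletion_time_s: 1.6089772572273266e-07
  supply_demand_ratio: 1.2000000000000002
  sustainable: True
  notes: demand basis: observed sustained consumption
```

Reading the numbers: the 20 pW organelle could heat itself at ~4.8 K/s —
its full thermogenic capacity — yet the observed sustained heating of
~0.005 K/s uses ~0.1% of it. The whole cell's free proton pool (~10⁵
protons at pH 7.4 in a 20 µm cell) would be drained in ~0.16 µs at full
capacity, so thermogenesis is limited by proton resupply; basal glucose
uptake (0.18 pmol/h, 24 H⁺ per glucose) supplies 1.2×10⁻³ pmol/s, just
covering the observed sustained demand of ~10⁻³ pmol/s.

Other one-liners:

```console
$ mitotherm rate
heating_rate_K_per_s: 4.78469
$ mitotherm pmf --delta-psi-mv 140 --delta-ph 1
pmf_mV: 201.511
$ mitotherm diffusion --out profile.csv    # conduction-limited steady state
steady_excess_K: 6.33789e-06
```

The last line is the conduction-limit comparison: were the same 20 pW source
held at a *steady* state in an infinite bath, its temperature excess would be
microkelvin-scale — the familiar ~10⁻⁵ discrepancy that arises from applying
steady-state reasoning to a thermogenic (time-dependent) state.

Thermometry converts dye-ratio traces (`time_s,nr` CSV) with
`mitotherm thermometry convert --tref-k 310 --in nr.csv --out T.csv` and
estimates heating rates with `mitotherm thermometry rate --in T.csv`;
`mitotherm simulate` writes synthetic traces with a ground-truth sidecar.

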