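# h2o2perm

Tools for quantifying how hydrogen peroxide crosses lipid membranes and the
human red blood cell (RBC) membrane. The package is aimed at membrane
biophysicists and redox biologists who need to turn raw partition and kinetic
measurements — or simulated versions of them — into permeability
coefficients, partition thermodynamics, and whole-blood clearance
predictions.

## What it computes

**Partition thermodynamics.** The partition constant of H2O2 between an
organic solvent and water is measured by a *double-partition* protocol in
which only the two aqueous phases are assayed. Closed mass balance over the
second equilibration gives

    K_D = C_w2 V_w2 / ((C_w1 − C_w2) V_os2)

and from K_D(T): ΔG° = −RT ln K_D, with ΔH°/ΔS° from a van't Hoff line
(`ln K_D` vs `1/T`).

**Solubility–diffusion model.** For a membrane decomposed into slabs of
width w_i, local partition constant K_i and diffusion coefficient D_i, the
permeability coefficient is the inverse of the summed resistances,
P_m = [Σ w_i/(K_i D_i)]⁻¹. The default profile models the bilayer core as a
1.6-nm hexadecane-like centre flanked by two 0.7-nm octanol-like regions.

**Enzyme latency.** An enzyme enclosed by a semi-permeable membrane shows
reduced apparent activity; at steady state the intact/disrupted activity
ratio R equals the inverse transmembrane substrate gradient, and

    P_m = k_catalase · R / [(A/V)(1 − R)]

with A/V the surface-to-volume ratio (≈ 3/r for spherical vesicles). The
pipeline goes: time courses → Beer–Lambert conversion → initial rates →
secondary-plot slopes → R → P_m, plus Arrhenius fits of P_m(T) and
single/double-exponential fits of stopped-flow transport traces.

**RBC clearance kinetics.** A two-compartment ODE model couples
extracellular H2O2 to the cell interior through P_m, with intracellular
consumption by catalase (pseudo-first-order) and peroxiredoxin 2
(second-order, 400 µM pool at 1×10⁸ M⁻¹s⁻¹). It yields transmembrane
gradients, the extracellular half-life at physiological hematocrit, pathway
shares, and forward-simulated latency experiments that close the loop on the
latency estimator.

Every experimental design has a seeded synthetic generator
(`h2o2perm.synthetic`) with a machine-readable ground-truth sidecar, so the
whole pipeline can be exercised and validated without wet-lab data.

## Worked example

```python
import h2o2perm as hp
from h2o2perm.synthetic import gen_timecourse_series

# simulate an RBC latency experiment (absorbance at 240 nm, 1% noise)
sample = gen_timecourse_series(design="rbc", P_m=1.6e-3, k_catalase=82.1,
                               noise_sd=0.01, seed=42)
model = hp.LatencyExperiment(sample.intact, sample.disrupted,
                             sample.geometry, k_catalase=82.1)
print(model.fit().summary())
```

```
Enzyme-latency permeability estimate
========================================
  k_intact    = 9.201 +- 0.33 s^-1/amount
  k_disrupted = 36.78 +- 2.2 s^-1/amount
  R           = 0.2502 +- 0.018
  gradient    = 3.997-fold
  k_catalase  = 82.1 s^-1
  A/V         = 1.556e+04 cm^-1 (explicit)
  P_m         = 0.001761 +- 0.00017 cm s^-1
```

The fitted intact and disrupted secondary-plot slopes (per molar HbO2) give
a latency ratio R ≈ 0.25 — a fourfold activity gap — and the recovered
P_m ≈ 1.8×10⁻³ cm s⁻¹ agrees with the simulation's true 1.6×10⁻³ within the
propagated standard error.

```python
res = hp.RBCKineticsModel(hp.physiological_scenario()).simulate()
print(res.summary())
```

```
Two-compartment H2O2 clearance simulation
============================================
  P_m        = 0.0016 cm/s   hematocrit = 0.45
  k_cat      = 82.1 s^-1  k_prx*Prx = 4e+04 s^-1
  Prx2 mode  = constant_pool
  C0_out     = 1e-06 M over t in [0, 0.341] s
  gradient (C_out/C_in, quasi-steady) = 1611
  mass conservation error (max rel.)  = 2.50e-15
  extracellular half-life = 34.1 ms
  pathway shares: catalase 0.002, Prx2 0.998
```

At 45% hematocrit with an active Prx2 pool, extracellular H2O2 is ~1600-fold
more concentrated than cytosolic H2O2 and is cleared with a half-life of
~34 ms — blood acts as a fast, strongly compartmentalised H2O2 sink.

A CLI mirrors the library (`h2o2perm partition|profile|latency|kinetics|
synth|report`); see `h2o2perm --help`.

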