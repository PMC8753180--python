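# Methods

## Double-partition estimation of K_D

Both equilibration steps are treated as closed mass balances: no interfacial
loss, evaporation, or H2O2 decomposition during equilibration (the solvents
are mutually pre-saturated in the protocol this emulates, so no volume
transfer occurs either). Under those assumptions the estimator
`K_D = C_w2 V_w2 / ((C_w1 − C_w2) V_os2)` is exact, and the synthetic
generator's forward model (`forward_double_partition`) solves the same two
equilibria in closed form. The test suite checks the estimator against an
*independent* root-finding equilibrium solver rather than against the
generator, so the two implementations cannot share a bug silently.

Units: volumes are carried in a single consistent unit (mL in the examples;
K_D is a concentration ratio so the unit cancels), concentrations in molar,
temperatures converted to kelvin at the interface (`as_kelvin` accepts °C or
K; 25 °C ≡ 298.15 K, 37 °C ≡ 310.15 K).

Thermodynamics: ΔG° = −RT ln K_D (R = 8.314 J mol⁻¹ K⁻¹). The van't Hoff
fit is ordinary least squares of ln K_D on 1/T with slope −ΔH°/R and
intercept ΔS°/R; with exactly two temperatures it is exact, which matters
because the classic protocol uses only 25 and 37 °C. Report-level rounding
(one decimal in kJ mol⁻¹) happens only in `thermo_report_table`, never in
the stored results.

Degenerate inputs: C_w1 ≤ C_w2 is rejected as an inconsistent measurement
(it would imply a negative or infinite K_D); C_w2 = 0 returns K_D = 0.

## Slab solubility–diffusion model

`P_m = [Σ w_i/(K_i D_i)]⁻¹` over ordered slabs; resistances add, so the
result is invariant to reordering and to subdividing slabs. The default
H2O2 profile uses the two measured solvent partition constants (octanol
6.6×10⁻², hexadecane 8.2×10⁻⁶) for flank and core, a uniform diffusion
coefficient equal to the aqueous value (1.4×10⁻⁵ cm² s⁻¹) — per-slab
overrides are allowed — and no slabs for the headgroup/structured-water
regions, for which no partition estimate exists. The water-layer barrier
comparison (`barrier_factor`) fixes the membrane thickness at 3.0 nm, the
sum of the three slab widths; this is the only thickness the slab model
defines and is an explicit convention of this package.

## Enzyme-latency pipeline

*Initial rates.* The default regression window is the earliest of {first
10% of substrate consumed, first 60 s}, extended forward if needed to keep
at least 4 points. An OLS slope over a window in which a fraction c of an
exponential decay is consumed underestimates the t = 0 rate by ≈ c/2; at
the 10% default this is a ≤5% bias per trace, and because intact and
disrupted traces are cut at the same consumed fraction the bias cancels in
the slope *ratio* R, which is the estimand.

*Secondary plots.* OLS with a free intercept (robust to small baselines);
the slope per unit amount is the pseudo-first-order constant. The slope is
invariant to point reordering and rescales inversely with the amount unit.

*Latency ratio and P_m.* R = k_intact/k_disrupted must lie in (0, 1);
R ≥ 1 (no barrier) is flagged with a warning in batch mode and raises only
when a P_m is actually requested. `pm_from_latency` and `r_from_pm` are
exact inverses. Liposome A/V uses 3/r on the nominal hydrodynamic radius
with no hydration correction (< 4% effect for the vesicle sizes modelled).
For cells, `k_catalase` is obtained by extrapolating the lysed-arm slope
(per molar HbO2) to the intracellular HbO2 concentration of 20 mM; for
liposomes it comes from the catalase work-solution calibration supplied in
configuration. The default intracellular catalase constant for the RBC,
82.1 s⁻¹, is frozen from inverting the latency relation at
P_m = 1.6×10⁻³ cm s⁻¹ and R = 1/4.3 (provenance noted in `constants.py`).

*Arrhenius.* OLS of ln P_m on 1/T; E_a = −slope·R. No correction is applied
for the enzyme's own activation energy (catalase's is ~2.5 kJ mol⁻¹, small
against the 32–130 kJ mol⁻¹ permeation barriers).

*Stopped-flow fits.* Single exponential `a e^{−kt} + c` for osmotic water
efflux; double exponential `a₁e^{−k₁t} − a₂e^{−k₂t} + c` for glycerol
shrink-reswell, where the slow constant (decaying phase) is the glycerol
transport constant. Rate guesses come from the half-decay / peak time and
the tail log-slope; a bounded 5-restart multi-start avoids the k₁↔k₂ label
swap and constants are reported sorted. Non-convergence after the restarts
raises a fit error with the model named.

## Two-compartment clearance model

State: extracellular and intracellular H2O2, the reduced Prx2 pool, and two
cumulative decomposition integrals (catalase, Prx2) used for pathway
fractions and the mass-balance audit. Extracellular coupling scales the
per-cell flux by Hct/(1−Hct); cells are identical and well mixed, and no
unstirred-layer term is included (the USL permeability is ~36-fold above
the membrane's, making its resistance negligible). The network deliberately
contains only permeation, catalase, and Prx2 — no glutathione peroxidase,
NADPH/thioredoxin recycling, or catalase intermediates; `prx_mode` selects
between a constant pool (physiological), a finite pool without recycling
(bolus experiments that exhaust NADPH), and a finite pool with first-order
re-reduction. The 400 µM Prx2 pool is counted on a monomer-equivalent
1:1 H2O2 stoichiometry.

Integration uses LSODA with rtol 1e-8 and atol 1e-14 M; results are
tolerance-invariant to at least four significant figures (asserted in the
tests). Total H2O2 — free in both compartments plus decomposed,
volume-weighted — must be conserved to 1e-6 relative or the run aborts.

Closed forms used for cross-checks: the quasi-steady gradient
`C_out/C_in = 1 + k_intra/(P_m A/V)` (exact for the linearised system), and
the extracellular decay constant taken as the exact slow eigenvalue of the
linear two-compartment system, `[(a+b+k) − sqrt((a+b+k)² − 4bk)]/2` with
`a = P_m A/V`, `b = a·Hct/(1−Hct)`, `k = k_intra`. This reduces to the
permeation-limited form `b(1 − 1/gradient)` at low hematocrit and to
`k·Hct` in the fast-permeation (well-mixed) limit. The half-life is read on
the extracellular species — what a plasma measurement would see — by
monotone (PCHIP) interpolation of the simulated trace; the default horizon
is ten closed-form half-lives, extended once before erroring.

`forward_latency` integrates each simulated trace to ~12% substrate
consumption (rather than a fixed 60 s) so that every trace is cut at the
same consumed fraction by the initial-rate window rule; the early-window
regression bias then cancels exactly in the intact/lysed ratio, which is
what lets the round trip (simulate → rates → slopes → R → P_m) recover the
input permeability to better than 2% across the 10⁻⁴–10⁻² cm s⁻¹ range.
The lysed arm treats the enzyme as redistributed over the whole volume
(first-order decay at k_cat × cell-volume-fraction), at a tenfold lower
cell density than the intact arm, mirroring the experimental design.

The reaction network can be exported as a flat parameter table
(`RBCKineticsModel.reaction_table`) for cross-validation in external
simulators.

## Synthetic data: what it emulates, and what it does not

Generators are seeded (`numpy.random.default_rng`), byte-deterministic, and
ship JSON truth sidecars. The noise model everywhere is multiplicative
Gaussian on the measured signal, clipped at zero. Defaults encode the
experimental designs being emulated:

- partition: V_os1 = V_w1 = 5 mL, V_os2 = 2 mL, V_w2 = 5 mL; 5 mM H2O2 load
  for the octanol-like case, 2 M for the hexadecane-like case (chosen so
  the second aqueous phase stays in the peroxidase assay's linear range);
- latency series: liposome volumes 5–25 µL (stock vesicle volume fraction
  0.04, 1 mL reaction volume) or RBC suspensions at 0.9–3.5 µM HbO2 intact
  and a tenfold dilution lysed; 10 mM H2O2 read as absorbance at 240 nm
  (ε = 39.4 M⁻¹cm⁻¹, 1 cm path);
- vesicle radii: 100 nm for low-permeability (saturated-lipid-like)
  membranes and 500 nm for high-permeability (unsaturated-lipid-like)
  membranes, mirroring the use of 200 nm and 1000 nm extrusion pores; the
  larger radius keeps the latency ratio well away from 1 where the
  estimator's variance blows up as 1/(1−R);
- liposome catalase work solution: k_catalase = 80 s⁻¹ (≈8 µM catalase
  tetramer at ~10⁷ M⁻¹s⁻¹);
- cuvette sampling: 61 points over min(60 s, time to 15% consumption) —
  the standard 1 Hz/60 s read for slow traces, shortened for fast
  disrupted-arm traces so the initial-rate window keeps enough points;
- stopped flow: 2 s at 1 kHz (water), 40 s at 25 Hz (glycerol);
- Arrhenius: 20–40 °C in 5 °C steps (the 10–40 °C grid is available by
  passing `temperatures`).

The generators do **not** model instrument noise spectra, baseline drift,
photobleaching, hemolysis, H2O2 instability during equilibration, or
vesicle polydispersity. Passing recovery tests therefore demonstrates that
the estimators are correct and well-conditioned under idealised Gaussian
noise at realistic magnitudes — not that they are robust to every artefact
of real traces.

## Known limitations

- The slab model ignores lipid packing, composition, and position-dependent
  diffusion; it is a first-order estimate, not a replacement for measured
  permeabilities.
- The latency estimator's variance grows as 1/(1−R); experiments on highly
  permeable membranes need larger vesicles or slower enzyme loads.
- The clearance model omits H2O2 sources (e.g. hemoglobin autoxidation),
  Prx2 hyperoxidation, and any spatial structure; fractions and gradients
  are for the minimal three-reaction network only.
- Pathway fractions under a finite Prx2 pool depend on the assumed 1:1
  monomer stoichiometry of the 400 µM pool.
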