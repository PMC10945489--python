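# Methods

This note records the models, conventions and design choices behind
`aquaphase`, in the order the pipeline runs them.

## Electrostatic moments of three-point models

A rigid three-point model places −2q_H on the oxygen and +q_H on each
hydrogen at distance d_OH, half-angle θ = ϕ_HOH/2. The dipole moment and
the tetrahedral quadrupole moment follow in closed form,

    μ   = 2 q_H d_OH cos θ            [e·Å]
    Q_T = (3/2) q_H d_OH² sin² θ      [e·Å²]

reported in D and D·Å with 1 e·Å = 4.80320 D (CODATA-derived; the unit
convention is this package's, asserted against widely tabulated SPC/E
values μ = 2.35 D, Q_T = 2.04 D·Å rather than any single source).
`point_charge_moments` rebuilds both from the explicit charge
coordinates — μ as |Σqᵢrᵢ|, Q_T as ½(Θ_xx − Θ_yy) of the traceless tensor
Θ_αβ = ½Σq(3r_αr_β − r²δ_αβ) with the molecule in the xz-plane, dipole
along z, origin at the oxygen — and serves as the independent oracle in
the tests. Q_T is reported as the single scalar (the full tensor is
available from the oracle utility); sTIP3P's extra hydrogen repulsion
site is a boolean flag only and does not enter the formulas.

## Slab profiles and interface fits

Configurations are wrapped into [0, L) per axis on ingestion; the
molecule reference position is the oxygen site (at the default 0.5 Å bin
width the O-vs-center-of-mass difference is sub-bin). The slab is
re-centered along z by a *circular* mean: z maps to the angle 2πz/Lz, the
mass-weighted resultant is averaged on the unit circle and mapped back.
This is exact under periodic translations, which is the hard case — a
slab that has diffused across the boundary. When the resultant length
falls below 0.05 the z-distribution is treated as uniform (single phase)
and left untouched.

Profiles are per-bin mass densities in g/L, averaged over frames, with
the bin width adjusted to the nearest divisor of Lz (default 0.5 Å;
configurable). Total mass is conserved by construction and asserted to
1e−9 relative in the tests.

The double-tanh profile

    ρ(z) = ρ_v + (ρ_l − ρ_v)/2 [tanh((z − z_lo)/w) − tanh((z − z_hi)/w)]

is fitted by bounded least squares with a *shared* width w for both
interfaces — per-interface widths add a parameter that mostly absorbs
near-critical noise. Non-convergence returns a flagged result with
diagnostics rather than raising. Near-critical guard: when the fitted gap
ρ_l − ρ_v is below 3× its propagated standard error the fit is flagged
`indistinct_phases`; flagged points are excluded from critical-point
fitting by default (overridable), since coexistence densities close to
T_C are the least reliable part of the curve.

## Critical-point estimation

The scaling law ρ_l − ρ_v = A(1 − T/T_C)^β and the rectilinear diameter
(ρ_l + ρ_v)/2 = ρ_C + B(T_C − T) are fitted *jointly* with shared T_C
(β = 0.326 fixed, 3D-Ising; a free-β mode exists but is off by default
because the linear T_C–ρ_C coupling across models is partly an artifact
of the fitting procedure itself). The joint fit makes the branch
intersection at (T_C, ρ_C) exact by construction and is statistically
tighter than fitting the two laws sequentially. Weights are 1/sd per
residual when every point carries uncertainties, else unweighted.

Initial guesses are deterministic: T_C⁰ = 1.05·max T; ρ_C⁰ and B⁰ from a
straight-line fit of the diameter; A⁰ from the lowest-T gap. Preconditions:
≥4 unflagged points spanning ≥50 K. Domain guard: the optimizer constrains
T_C > max T; a solution within 0.1% of that bound means some input sits at
or above the critical temperature the data imply, and a `DomainError` is
raised (at τ = 10⁻³ the gap is still ≈10% of A, so no credible fit lands
there). Note the *vapor* branch of the fitted laws rises with T only in
the scaling regime near T_C; far below, the linear diameter term dominates
and the extrapolated branch turns over — the laws are asymptotic forms,
not global equations of state.

Uncertainties use trajectory splitting: per-block refits on a common
temperature grid, central value from the pooled fit, sd = spread of block
estimates (≥2 blocks required).

## Evaporation thermodynamics

ΔU = u_v − u_l per molecule (internal energies ingested in kJ/mol, a
kcal/mol converter is provided); molar volumes v = M/ρ with
M = 18.0153 g/mol; pΔV = p_sat(v_v − v_l) with 1 L·bar = 0.1 kJ; and
ΔH = ΔU + pΔV as an exact identity of the returned fields (the liquid
molar volume is kept, not approximated away). p_sat is the vapor
simulation's reported mean pressure when present — it reflects the actual
interactions — with the ideal-gas estimate p = (ρ_v/M)RT
(R = 0.0831446 L·bar·mol⁻¹·K⁻¹) as fallback. In the subcritical regime
(liquid ≈ 900–1000 g/L, vapor ≤ 50 g/L, T ≤ 550 K) the volume work is a
minor contribution, below ~20% of ΔH and typically ~10%; the tests assert
this as a sanity property of the pipeline.

## NPT analysis

**Spontaneous evaporation.** There is no sharp microscopic criterion for
"the box explosively expanded", so the detector uses a hysteresis rule
with configurable factors: a trace counts as evaporated when the mean
density over its final 20% is below 0.5× the liquid reference; the onset
is the first sample below 0.5× that never again recovers above 0.8×.
The verdict is monotone in the collapse threshold by construction.
T_evap is the lowest evaporated step of a heating ladder (default 1 K per
5 ns step = 0.2 K/ns); a liquid step above an evaporated one yields a
`consistent=False` warning rather than silence. A ladder with no
evaporated step returns "not reached", not an error. Barostat and
pre-equilibration are carried as metadata labels only — reported offsets
in the literature (Berendsen ≈ +20 K vs stochastic cell rescaling,
Parrinello–Rahman ≈ −10 K, no pre-equilibration ≈ −5…−10 K) are not
applied automatically.

**Maximum density.** ρ(T) is interpolated with a weighted quartic
polynomial (centered in T for conditioning) and T_MD taken from the
analytic stationary point with negative curvature inside the sampled
range; the quartic is a swappable stand-in for empirical liquid-density
forms and nests the parabolic shape of ρ(T) near the maximum exactly.
Strictly monotone data raise "no maximum in range". Block uncertainties
follow the 6×5 ns split convention with the first block discarded.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline reads, with ground truth
in sidecar records, deterministic under a seed:

* **Slab frames** — molecule z-positions are iid inverse-CDF samples from
  the double-tanh profile (exact step-mixture sampling in the w → 0
  limit), x–y uniform, whole-slab drift per frame to exercise wrapping.
  Default conditions mirror a coexistence box: 20×20×100 Å, ρ_l = 1000,
  ρ_v = 10 g/L, interfaces at 30/70 Å, w = 2 Å, 200 frames — ≈543
  molecules by mass consistency (the scenario of ~512 molecules, half at
  liquid density). Because the count must be an integer, the sidecar
  records the *effective* densities (×n/n_expected); a requested count
  >10% off the implied mass is rejected as infeasible. Molecules are
  independent — no excluded volume, no structure, no interfacial
  capillary waves — sufficient for density-profile statistics, and
  nothing more: passing tests validate the centering/histogram/fit
  chain, not water physics.
* **Coexistence tables** — closed-form inversion of the two laws
  (defaults T_C = 640 K, ρ_C = 300 g/L, A = 750, B = 0.85, β = 0.326 —
  magnitudes typical of three-point models) times (1 + ε),
  ε ~ N(0, noise_frac).
* **NPT ladders** — discrete Ornstein–Uhlenbeck density fluctuations
  (relaxation 0.1 ns, stationary sd 15 g/L ≈ 2%) around a linearly
  declining ρ_eq(T), sampled at 0.01 ns over 5 ns steps of 1 K from 580
  to 620 K; above the true T_evap = 600 K a step collapses to 5 g/L
  after an exponential waiting time (mean 1 ns) over a 0.3 ns ramp. The
  collapse model is phenomenological — exponential waiting plus linear
  ramp — chosen because only the detector's contract matters, not
  nucleation kinetics. With 5 ns steps the first step above the true
  transition evaporates with probability ≈0.99, so estimates
  concentrate at truth + dT.

## Cross-model statistics

Full linear fits report R² as the squared Pearson correlation; the
offset-only fit y = x + c uses c = mean(y − x) and
R² = 1 − SS_res/SS_tot about mean(y) (clipped at zero), which the OLS fit
can never undercut since it nests the offset model. Constant-y data score
R² = 0 by convention; constant-x raises. The published per-model
uncertainties are carried but not used as fit weights by default (plain
fits are what the bundled table supports; weighted variants sit behind a
flag). The experimental row of the characteristic-point table is excluded
from all cross-model fits and used only for reference deltas such as the
experimental T_C − T_MD gap. On the bundled table the offset fit of
T_evap on T_C gives c ≈ −26.4 K with R² ≈ 0.955, and the quadrupole
moment Q_T correlates more strongly with T_evap than the dipole moment μ
does — these numbers are computed at run time by the tests and the
acceptance script, never hard-coded.

## Problem sizes and numerical choices

The validation studies run at desk scale: 20 seeds × 12-point coexistence
tables, one 200-frame slab (~543 molecules), 10 seeded 41-step ladders at
500 samples/step — the full suite finishes in a few seconds. Optimizer
tolerances are 1e−14 (xtol/ftol/gtol) for the joint critical fit;
curve_fit defaults for the interface fit; the quartic fit uses
numpy.polyfit with 1/sd weights. Ties and degenerate inputs (flat
profiles, uniform gas, single-phase boxes, zero-variance predictors) are
flagged or rejected explicitly, as described above.

## Known limitations

* All statistical guarantees are for the synthetic generators'
  idealizations; real MD output adds correlated frames, capillary-wave
  broadening, finite-size effects and barostat-dependent offsets that
  the generators deliberately omit.
* The rectilinear-diameter form is linear by choice; curved-diameter
  scaling corrections are out of scope, as is surface tension,
  per-atom profiles, non-orthorhombic boxes, and boiling-point
  estimation (T_evap is a superheating limit, not T_B).
* Binary trajectory formats (XTC/TRR/DCD) are not read; the pipeline
  consumes text GRO/XYZ/CSV.
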