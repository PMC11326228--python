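# Methods

This note records the model, its assumptions, the numerical choices, and
what the synthetic data do and do not establish. Units are SI internally
(m, s, Pa); interfaces report mm, μm, min, kHz where those are customary.

## Model overview

The cochlea is unrolled into two stacked 2-D rectangular fluid layers of
length L = 12 mm (gerbil): the Corti fluid (height 60 μm) above the scala
tympani (height 500 μm), separated by the basilar membrane. Three one-way
coupled stages: (1) a kinematic traveling wave prescribes the motion of the
Corti-fluid top wall; (2) the incompressible Navier–Stokes equations with
the advective term retained are integrated to a time-periodic state and
averaged over one period to give the drift (steady-streaming) field; (3)
that drift field, held constant (quasi-steady: acoustic period ~1 ms versus
delivery horizon ~hours), advects a diffusing solute released at the round
window, yielding effect-time maps.

## Traveling-wave surrogate

The wave is kinematic: displacement `u_m(x,t) = A(x) cos(2πft + φ(x))`,
with

- **Envelope** `A(x)`: exponential basal tail growing at 3 dB/mm toward the
  CF place of the stimulus frequency, peak value `a_peak`, cos² taper to
  zero over a 0.5-mm stall margin apical of the peak. Traveling waves stall
  shortly after their CF place; the taper avoids a velocity-boundary
  discontinuity.
- **Phase** `φ(x) = −∫₀ˣ k(s) ds`, `k = 2πf/c(x)`, with phase velocity
  decaying linearly from 40 m/s at the base to 3 m/s at the peak (and held
  there through the taper). Values bracket reported cochlear-wave speeds;
  both are configuration.
- **Place–frequency map**: Greenwood form
  `CF(kHz) = 0.398 (10^{2.2(1−x/L)} − 0.631)`, a published gerbil fit;
  parameters exposed.
- **Amplitude**: `a_peak` is the *cross-section (area-change)* motion of
  the Corti channel, the quantity that pumps. Outer-hair-cell somatic
  strain is a few percent of a 20–50 μm cell, so the default is 2 μm at
  80 dB SPL with `active_gain = 1` — a few percent of the 60-μm channel
  height, and deliberately conservative: the reference fluid–structure
  simulations report streaming three orders faster than this surrogate
  produces. A separate helper maps SPL to basilar-membrane-referred
  displacement (80 dB → 25 nm) for users calibrating against BM
  measurements; the two scales are distinct on purpose.
- **Salicylate** is represented purely as `active_gain < 1` multiplying the
  envelope (gain 0 = motility fully blocked). No pharmacokinetics.

## Flow stage

Incompressible Navier–Stokes with ν = 7×10⁻⁵ m²/s (100× water — the
effective viscosity of the narrow interconnected Corti spaces; applied to
both layers, per-layer override possible) and ρ = 1000 kg/m³.

- **Discretization**: staggered (MAC) finite volumes, uniform x, nonuniform
  y; Crank–Nicolson viscous terms (prefactorized sparse LU Helmholtz
  solves), Adams–Bashforth-2 centered advection, non-incremental pressure
  projection (prefactorized Poisson). The projection pseudo-pressure stands
  in for p in the membrane law — a first-order-in-time pressure splitting,
  adequate because the drift diagnostics converge with the cycle average.
- **Membrane**: internal interface with Darcy normal flux `u_p = −K Δp`
  (K = 1 m/(s·Pa)) plus the membrane's own structural velocity, and zero
  tangential slip on both sides. In the pressure Poisson system the
  membrane face carries transmissibility K, so the projected field
  satisfies continuity and the Darcy law exactly in the discrete sense. At
  the default K the membrane is effectively transparent to normal flow
  (transmembrane pressures ≪ 1 Pa); drift changes by <0.1% over
  K ∈ [0.3, 3]. A consequence verified numerically: purely structural
  membrane motion produces no drift at this K, so the solver's default
  drives the top wall with the full area-change wave (`bm_fraction = 0`);
  the antiphase split option matters only for small K.
- **Boundaries**: rigid no-slip side and bottom walls; prescribed normal
  velocity on the deforming top wall. A closed rigid box cannot absorb a
  nonzero instantaneous wall flux, so the spatial mean of the prescribed
  wall velocity (zero time-mean) is subtracted — a uniform "piston"
  correction. Periodic-in-x channels, tangential wall motion and body
  forces are supported for the analytic oracles (Poiseuille,
  oscillating-plate boundary layer).
- **Time stepping**: ≥100 steps per period (10 μs at 1 kHz). Startup
  transients decay in a few cycles (slowest viscous mode ~ν π²/H²).
  Convergence is declared when consecutive cycle-averaged velocity fields
  differ by <10⁻³ (relative L2); since cycle-averaging annihilates the
  oscillation, this metric tracks the drift itself. Non-convergence is
  flagged, never silent.
- **Drift**: mean of the Eulerian field over one converged cycle (uniform
  sampling of a periodic function — trapezoid-exact). Reported diagnostics:
  max |u_D|, per-layer cross-section fluxes, and the *pumping rate* (x-mean
  Corti-layer flux), the directed-transport metric that separates traveling
  from standing forcing (standing-wave envelopes still drive closed
  Rayleigh-type cells of comparable local |u_D|, but ~200× less directed
  transport).

Desk-scale defaults (120×31 cells, 100 steps/cycle) run to steady state in
~1 s; near-wall cells are well under the boundary-layer thickness
√(ν/ω) ≈ 150 μm at 1 kHz.

### Streaming structure at desk scale

The converged field shows an apical stream through the Corti layer over the
wave's tail, a basal return concentrated in the uppermost ~120 μm of the
scala (immediately under the membrane — the strip resolved by the reference
simulations), and a weaker apical limb closing the loop lower in the scala.
Net cross-section flux balances to ~10⁻⁷ of the single-layer maximum.
The return flow hugging the membrane rather than the bottom wall is a
property of this surrogate's forcing (top-wall area wave over a
pressure-transparent membrane) and is documented as such.

## Transport stage

Conservative finite volumes on the flow grid (so the MAC drift field is
discretely divergence-free on the transport mesh — uniform fields are
preserved and the maximum principle holds): explicit van-Leer-limited
upwind advection under a CFL bound of 0.4, implicit backward-Euler
diffusion (prefactorized), D = 8×10⁻¹⁰ m²/s (small-molecule scale; the
oracles are parameterized in D). The basilar membrane is no barrier to the
solute: membrane faces carry the ordinary diffusive conductance plus the
advective Darcy flux.

- **Round window**: Dirichlet patch at C₀ = 10 mM on the basal 0.2 mm of
  the scala-tympani bottom boundary (configurable; an end-wall variant
  spanning the full basal wall makes the silence case exactly 1-D for the
  erfc oracle). `patch_extent = 0` seals the domain for conservation tests.
- **Stepping**: starts at the acoustic-period scale (1 ms) and grows
  geometrically (×1.2) to a 10-s cap — the cap resolves minute-scale effect
  times to ~1–2% — and the CFL bound. Boundary influx is integrated from
  the same discrete fluxes as the implicit solve, so the mass budget closes
  to roundoff.
- **Effect time**: first crossing of `f_thr·C₀` (default 1%) on the
  observation line, linearly interpolated between steps; unreached points
  are flagged, as is a run where nothing new crosses in the final 10% of
  the horizon. The observation line defaults to Corti-fluid mid-height (the
  inner-hair-cell row surrogate) with `scala_mid` and explicit-row
  alternatives.
- **Verification**: silence-case t_E matches `x²/(4D erfc⁻¹(0.01)²)` to
  <2.5% beyond 2 mm (the residual is time-step-dominated and converges
  away); t_E changes <0.3% under 2× grid refinement; a synthetic
  two-cell counter-circulation field reproduces the fast-track/stalling
  phenomenology (flattened t_E inside the advancing cell, ≥3× steepened
  rise at the cell boundary).

Under the default conditions the 1-kHz drift field shortens tail-region
effect times by ~10–30% over two simulated hours, strictly at every tail
observation point, and extends the reach of delivery; with
`active_gain = 0` the effect-time map is identical to pure diffusion. A
weak (<5%) *retardation* appears basal of ~3.5 mm where the sub-membrane
return opposes outward transport — a genuine feature of the circulation,
not an artifact.

## Analysis chain

Teager energy is the exact discrete operator (ends dropped); segment means
follow the 57.2-s protocol (48 noise + 1 pause + 3 tone segments × 1.1 s);
driven response = own-CF tone mean − pause mean per sequence; baseline =
mean driven response over all pre-application sequences. The effect time is
the first *sustained* (≥2 consecutive sequences) drop below 75% of
baseline, linearly interpolated; a rebound above criterion + 0.1 afterwards
sets a bimodal-decay audit flag (smoothing is available but off by
default — crossing rules and smoothing are config, not silent choices).
The diffusion trend `t = a·x²` is fitted in log space (geometric mean of
t/x², matching the dB comparisons; the threshold fraction inside
erfc⁻¹ is fixed by configuration, as it is not identifiable from t_E data
alone). Group comparisons use two-tailed Welch t-tests with 95% CIs.
DPOAE sweep levels come from least-squares quadrature fits at the
instantaneous 2f₁−f₂ frequency in 100-ms Hann windows stepped by 20 ms;
the noise floor applies the same fit to half the difference of even- and
odd-presentation averages.

## Synthetic data

Recordings are white Gaussian with per-segment variance equal to the target
mean Teager level (E[Ψ] = σ² for white noise): pauses at the spontaneous
level (1.0), own-CF tones at spontaneous + driven·g(t) with driven = 4.0,
noise pips at half the driven excess. The decay g is logistic
(τ = 1.5 min) crossing 0.75 exactly at the channel's ground-truth t_E
(defaults 4/8/14 min at CFs 9/3.8/1.8 kHz, 20 sequences, 2 pre-drug); an
optional two-step variant exercises the bimodal flag. Effect-time datasets
scatter log-normally (0.83 dB ≈ 10%) about `t = a₀x²` with
a₀ = 9.4×10⁷ s/m² — the value implied by D = 8×10⁻¹⁰ m²/s at the 1%
threshold, which also matches the observed ~50-min scale at mid-cochlear
distances. All randomness uses `numpy.random.default_rng` (PCG64), one
stream per generated object; fixed seeds are bit-reproducible.

What passing these tests shows: the chain recovers known effect times to
well within one sequence (57.2 s) and trend parameters to <10% at the
studied sample sizes, under Gaussian, stationary, schedule-locked noise.
What it does not show: robustness to real multi-unit data's
non-stationarities — electrode drift, bursting, movement artifacts,
probe-level changes (re-baselining after salicylate is supported but not
exercised by the generator), or non-logistic decay shapes beyond the
two-step variant.

## Known limitations

- The wave is kinematic; there is no fluid–structure feedback, no
  compressive nonlinearity, and the amplitude calibration is an assumption
  exposed in configuration, not a prediction.
- Streaming magnitudes are desk-scale: orders of magnitude below the
  reference simulations' mm/s, so only directions, scalings and relative
  (paired) effects are meaningful; absolute effect times in the sound case
  inherit this conservatism.
- Two layers only (no scala media/vestibuli); uniform duct heights; rigid
  ends (no helicotrema or window compliance in the flow stage).
- The transport stage ignores binding, clearance and electrochemical
  gradients.
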