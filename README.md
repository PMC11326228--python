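# cochstream

Sound-driven cochlear fluid streaming, intracochlear drug transport, and
effect-time analysis.

## The problem

Drugs applied at the round window of the cochlea must travel centimetres
along a narrow, closed, fluid-filled duct. Perilymph is normally stationary,
so transport is diffusion-limited: reaching the apex takes hours to days.
Sound changes this. Active outer hair cells deform the organ of Corti (OoC)
like a peristaltic tube as the traveling wave passes, and the retained
nonlinear (advective) term of the Navier–Stokes equations turns that
zero-mean oscillation into a steady *drift* flow — an apical stream along
the tunnel of Corti with a basal return in the scala tympani — which stirs
the fluids and speeds up delivery.

`cochstream` implements this model end to end, at desk scale, together with
the experimental analysis used to observe the effect in vivo:

1. **`travelwave`** — a parametric kinematic traveling wave: amplitude
   envelope `A(x)` peaking at the characteristic-frequency (CF) place with a
   long shallow basal tail and a stall just apical of the peak; phase
   `φ(x) = −∫k dx` with phase velocity decaying toward the apex; wall motion
   `u_m(x,t) = A(x) cos(2πft + φ(x))`. A Greenwood-form gerbil map links CF
   and place.
2. **`driftflow`** — a two-layer (Corti fluid over scala tympani) 2-D
   incompressible Navier–Stokes solver (staggered grid, Crank–Nicolson
   viscosity, explicit advection, pressure projection) with the moving wall
   on top and a Darcy-permeable basilar membrane (`u_p = −K Δp`, K = 1
   m/(s·Pa)) between the layers. Run to a periodic steady state, the
   period-averaged velocity is the drift field
   `u_D = (1/T)∫ u_E dτ`; it scales as amplitude², vanishes without phase
   propagation, and circulates apically in the Corti layer / basally in the
   scala.
3. **`transport`** — conservative finite-volume advection–diffusion
   (`∂C/∂t = D∇²C − u_D·∇C`, D = 8×10⁻¹⁰ m²/s) of a 10-mM round-window
   application, with the effect time `t_E(x)` defined as the first crossing
   of 1% of the applied concentration (100 μM). With `u_D = 0` it reduces
   to pure diffusion, `t_E = x²/(4D·erfc⁻¹(0.01)²)`.
4. **`neuro`** — the measurement pipeline: Teager energy
   `Ψ[n] = x[n]² − x[n−1]x[n+1]` of multi-unit recordings, per-segment means
   over the 57.2-s stimulus sequences (48 noise pips + 1 pause + 3 CF tone
   pips × 1.1 s), driven responses (tone − pause), normalization to the
   pre-drug baseline, effect time at the 75% criterion, the 1-D diffusion
   trend fit `t = a·x²`, dB normalization `20 log₁₀(t_E/t_Trend)`, Welch
   t-tests, and swept-tone DPOAE levels at 2f₁−f₂ with an even/odd noise
   floor.
5. **`synthdata`** — seeded generators for protocol-structured recordings
   with known per-channel effect times, effect-time datasets on a known
   trend, and wall-motion fixtures (including standing-wave nulls).

## Worked example

```python
import numpy as np
from cochstream.travelwave import CochlearGeometry, TravelingWaveParams, wall_motion
from cochstream.driftflow import two_layer_grid, solve_drift, SolverConfig
from cochstream.transport import TransportConfig, run_delivery

geom = CochlearGeometry()                  # 12-mm gerbil duct
params = TravelingWaveParams()             # 1 kHz, 80 dB SPL, active OHCs
grid = two_layer_grid()

wave = wall_motion(geom, params)
flow = solve_drift(grid, wave, config=SolverConfig(store_last_cycle=False))
drift = flow.drift
print(f"periodic steady state in {drift.n_cycles} cycles; "
      f"max |u_D| = {1e6 * drift.max_speed():.1f} um/s")

cfg = TransportConfig(horizon=7200.0)      # 2 h of kainic-acid delivery
silence = run_delivery(grid, cfg, None)
sound = run_delivery(grid, cfg, drift)
for name, res in [("silence", silence), ("1-kHz tone", sound)]:
    etm = res.effect_times
    t6 = np.interp(6e-3, etm.x[etm.reached], etm.t_e[etm.reached]) / 60
    print(f"{name:10s}: t_E at 6 mm = {t6:5.1f} min")
```

prints

```
periodic steady state in 3 cycles; max |u_D| = 15.2 um/s
silence   : t_E at 6 mm =  60.4 min
1-kHz tone: t_E at 6 mm =  51.8 min
```

The traveling wave converges to a time-periodic flow within a few cycles;
its drift peaks at ~15 μm/s at desk scale. Two hours of simulated delivery
show the sound condition reaching the 6-mm place (CF ≈ 4.7 kHz) about nine
minutes — here ~15% — sooner than diffusion alone, with the facilitation
concentrated in the tail region of the wave, and disappearing entirely when
`active_gain = 0` emulates salicylate suppression of outer-hair-cell
motility.

A thin CLI mirrors the stages: `cochstream waves | drift | transport |
synth | analyze` (CSV/JSON/NPZ/HDF5 outputs).

## Scope

The full finite-element OoC model that generates wave parameters from first
principles is out of scope; the kinematic surrogate exposes its outputs
(envelope, phase velocity, amplitude) as configuration. Hair-cell
transduction kinetics, compressive nonlinearity, drug binding/clearance and
the scala media/vestibuli are likewise not modeled. See `docs/methods.md`
for assumptions, parameter choices and limitations.
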