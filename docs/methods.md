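# Methods and model notes

This document records the physical model behind the simulator, the defaults of
every analysis constant, and the rationale for choices that are package
decisions rather than measured quantities.

## Motor model (`motortrap.simulate`)

The motor is simulated as a continuous-time Markov jump process with the exact
Gillespie algorithm; propensities depend only on the current motor position,
so between events they are constant and the simulation is exact.

States and reactions (position `x` in nm along the microtubule, lattice
spacing `step_size` = 8.2 nm):

- **Forward step** (attached): rate `k_forward_0 · exp(−F·d_f/kT)` with
  `k_forward_0` = 110 s⁻¹ and `d_f` = 2.5 nm. The Bell form makes stepping
  slow down under load `F`.
- **Backslip start** (attached): rate `k_backslip_0 · exp(+F·d_b/kT)` with
  `k_backslip_0` = 0.5 s⁻¹ and `d_b` = 1.5 nm — slipping is promoted by load.
  During a slip the motor slides backward at `slip_speed` = 1500 nm/s and
  re-engages at rate `backslip_reengage_rate` = 75 s⁻¹, snapping to the
  nearest lattice site. The mean slip is therefore ~20 nm, and slips
  interrupted early produce the short (≤12 nm) backslips used in the
  fore/backstep ratio.
- **Detachment** (attached): constant rate `k_detach` = 0.8 s⁻¹; the bead
  returns to the trap center.
- **Reattachment** (detached): waiting time drawn from a three-component
  exponential mixture, fractions (0.31, 0.39, 0.30) with half-times
  (74 ms, 300 ms, 1.5 s). This gives the restart-time analysis a known
  ground-truth mixture to recover.

The force on the motor is `F = κ_eff · x` with
`κ_eff = κ_link·κ_trap/(κ_link+κ_trap)`.

The fore/backslip **balance force** — where the two Bell propensities cross —
is `F* = kT·ln(k_forward_0/k_backslip_0)/(d_f+d_b)`; `balance_force(config)`
returns it, and the test configurations invert this formula to place the
balance at a chosen force.

### Bead rendering

The bead is an overdamped particle coupled to the motor by a linear linkage
(`linkage_stiffness`, default 2.0 pN/nm) and held by the trap
(`trap_stiffness` = 0.065 pN/nm); thermal noise enters as an
Ornstein–Uhlenbeck process with stationary variance `kT/(κ_link+κ_trap)`
(kT = 4.06 pN·nm at 22 °C) and relaxation time `γ/(κ_link+κ_trap)` with
`bead_drag` γ = 4.7×10⁻⁶ pN·s/nm (a ~0.5-µm bead in water). The discretised
update is the exact AR(1) solution of the OU stochastic differential
equation, applied to the deviation from the (linkage-filtered) motor
position. Sampling is at 20 kHz.

**Linkage stiffness is a package choice.** Trap experiments rarely report a
motor–bead linkage model. We default to a taut linkage of
2.0 pN/nm so the bead transmits `κ_link/(κ_link+κ_trap)` ≈ 96.9% of a motor
step; the 8.2-nm lattice then reads out as ≈7.95 nm at the bead, consistent
with 8-nm steps being directly observable in bead records. A soft linkage
(e.g. 0.2 pN/nm) would attenuate steps by 25% and is available by
configuration but is not the default.

### Other generators

- **Kymograph tracks** are polylines of (frame, pixel) vertices at
  162 nm/pixel and 0.2 s/frame. Three populations are generated: processive
  (runs at 800 ± 100 nm/s, ≥500 nm/s, exponential run durations ≥1 s, optional
  pauses), static (jitter of 0.15 px around a fixed position) and diffusing
  (1-D random walk, D = 0.1 µm²/s, duration ≥8 s). The duration and speed
  floors make each population self-consistent with its class definition
  (e.g. a "processive" track always covers ≥500 nm of run length); without
  them the generator emits tracks whose ground-truth label contradicts the
  classification rules, which is a defect of the label, not the classifier.
- **Linescans**: a cell's center-to-tip profile starts flat at 1 over
  [0, 0.2], flat at 0.75 over [0.8, 1] (periphery 25% dimmer) and linear
  between; the end profile has the same integral (mass conservation) with a
  periphery/perinuclear ratio of 1.6. Intermediate timepoints interpolate
  linearly; noise is mean-subtracted per profile so each cell's total
  intensity is conserved to machine precision.

## Analysis constants

| Constant | Default | Module |
|---|---|---|
| Event force threshold / minimum duration | 0.5 pN / >200 ms | trace_events |
| Event smoothing | 2000 samples (100 ms at 20 kHz) | trace_events |
| Force–velocity smoothing / bins | 200 samples (10 ms) / 0.5 pN | trace_events |
| Stall minimum duration / fluctuation | 10 ms / 8 nm | trace_events |
| Backslip distance defining a release | 24 nm | trace_events |
| Detachment force cutoff | 1.2 pN | trace_events, steps |
| Encounter restart window | 100 ms | trace_events |
| Step t-score threshold / min size / min force | 30 / 5 nm / 1 pN | steps |
| Step pre-average / t-test window | 20 / 50 samples | steps |
| Ratio backslip maximum / force bin | 12 nm / 1 pN | steps |
| Pause speed threshold | 25 nm/s | kymo |
| Static run-length cutoff | 500 nm | kymo |
| Bidirectional excursion | 324 nm (2 px) | kymo |
| Linescan bins / windows | 100 / 0.8–1.0 vs 0.0–0.2 | cells |
| Significance level | 0.05 | stats |

Notes on specific choices:

- **t-test window (50 samples per side).** The per-side window length of the
  moving-window Welch test is not a standard constant; 50 samples (2.5 ms)
  resolves 8-nm steps against the default bead noise with t ≫ 30 while
  limiting the merging of short stepping dwells. Windows much shorter than
  twice the 20-sample pre-average lose power because both test windows then
  overlap the smeared transition (`window_sensitivity` exposes this trade-off;
  the unit tests demonstrate it at window 30).
- **Stall scoring is release-anchored.** Stalls are the maximal intervals of
  ≤8-nm excursion that *precede a release* (a ≥24-nm drop from the running
  maximum, or the terminal return toward the trap center). Anchoring at
  releases prevents low-force plateaus during force ramp-up from being
  scored as stalls.
- **Kymograph average speed uses path length by default.** `classify_track`
  computes average speed as total distance covered per unit time
  (`speed_definition="path"`); net displacement per unit time is available as
  `"net"`. Under the net definition an unbiased random walk is frequently
  classified static (its net speed concentrates near zero), which makes the
  three classes mutually inconsistent; the path definition keeps a diffusing
  motor out of the static class while leaving genuinely stationary motors
  static.
- **Conover–Iman post-hoc is implemented in-package** (no installed package
  provides it): pooled-rank t statistics with the tie-corrected rank variance
  and the Kruskal–Wallis correction factor, df = N − k, Holm-adjusted. The
  omnibus and all other tests delegate to scipy/statsmodels.
- **Exponential mixtures are fitted by EM** (closed-form M-step, multi-start,
  BIC comparison of 1/2/3 components) rather than generic curve fitting;
  a least-squares CDF fit (`fit_triexponential_cdf`) is provided as an
  independent cross-check. Fast-detachment reassignment refuses mixtures
  whose two fastest half-times are within a factor of 1.5 (not identifiable).
- **Baseline correction** estimates drift as a running median over 5-s
  windows restricted to sub-threshold (quiet) samples and interpolates across
  events. It requires quiet support; driftless synthetic records can be
  analysed with `baseline=False`.

## Validation strategy

- **Step detection** is compared against an exact dynamic-programming
  piecewise-constant changepoint oracle (optimal partitioning) on noiseless
  and noisy staircases: identical counts, indices within one sample on
  noiseless data, sizes within 0.1 nm.
- **The Gillespie simulator** is compared against a dense-time (1–10 µs)
  kinetic Monte Carlo discretisation with geometric waiting times — same
  reaction scheme, independent time handling — via chi-square tests on event
  counts and plateau forces.
- **Bead noise** is checked against the OU closed forms (stationary variance,
  zero-temperature low-pass limit, Hooke's law for a parked motor).
- **Cell redistribution** is checked against the closed-form interpolated
  profiles to 1e-6, including the exact 0.75 initial periphery ratio.
- **Statistics** are calibrated on a three-group null simulation: the
  Holm-corrected family-wise error of the Kruskal–Wallis + Conover pipeline
  is ≤5% over 1,000 replicates.

Problem sizes in the acceptance suite (e.g. 20 staircases, ≥200 force events
from 12-s balanced-motor records, 5,000 mixture draws, 1,000 fuzzed
configurations, 100 tracks per class) are package choices sized to run the
full suite in well under five minutes on one CPU while keeping Monte Carlo
error far below the asserted tolerances.

## Limitations

- The simulator is a single-motor, single-lattice model: no protofilament
  switching, no limping, no ATP dependence (rates are lumped at saturating
  ATP), and slips are kinematically linear rather than diffusive.
- The OU bead model uses a constant drag (no surface proximity corrections)
  and a linear linkage (no worm-like-chain compliance).
- Kymograph generation draws hand-tracing-like polylines, not images; tracking
  error is modelled only as vertex jitter for static motors.
- Linescan profiles are one-dimensional and noise is Gaussian, not Poisson.
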