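# Methods

## The measurement principle

A sealed cultivation bottle holds a liquid culture of an autotrophic,
hydrogenotrophic methanogen under a pressurized 4:1 H2/CO2 headspace. The
organism runs 4 H2 + CO2 → CH4 + 2 H2O; water condenses, CH4 accumulates in
the gas phase, so for every mol of CH4 formed five mol of gas disappear and
one reappears — a net loss of four "pressure units" per unit of CH4 partial
pressure. The controller logs absolute headspace pressure (nominally every
10 s), re-pressurizes to a target whenever the programmed per-cycle drop
(Δpressure, in bar) has been consumed, and pauses for sampling. The decaying
segments of the resulting sawtooth carry all the kinetic information.

Quantification inverts the stoichiometry:

* p_CH4 = (p_before − p_after)/4 in mbar,
* n = 0.1 · p · V / (R · T_K) in mmol, with p in mbar and V in mL
  (the effective headspace: bottle plus tubing, at cultivation temperature),
* MER = Δn_CH4/(Δt · V_culture) in mmol L⁻¹ h⁻¹.

Canonical internal units are mbar, mL, h, mmol, g and °C; Kelvin appears
only inside the ideal-gas conversion. Raw logs use seconds, derived series
hours. Gas-phase ideality is assumed (error < 1% below ~4 bar absolute),
and water-vapor partial pressure is neglected throughout, consistently on
both the simulation and the quantification side. The tubing share of the
headspace is treated as being at cultivation temperature; its cooler actual
temperature is a known, unmodelled bias.

## Trimming filters

Filters run strictly in this order; each is idempotent.

1. **Minimum pressure (i).** Readings below `min_pressure` (mbar, absolute)
   are discarded: the experiment stops below this floor, and flush/vent
   excursions dip through it.
2. **Cycle segmentation (ii).** A re-pressurization is a maximal run of
   strictly increasing steps with a total rise of at least
   `refill_threshold` (default 200 mbar — far above manometer noise, far
   below any programmed Δpressure; the raw data never defines how a "maximum
   pressure" should be found among noise, so the rise threshold is the
   package's own, configurable convention). A cycle runs from the pressure
   maximum of the stretch between rises to the first point at or below
   `p_max − Δpressure·1000`, or to the local minimum before the next rise.
   Rising points and post-threshold tails are discarded.
3. **Short cycles (iii).** Cycles with fewer than `len_cycles` points are
   valve chatter and are removed.
4. **Inactive cycles (iv).** Cycles whose total drop is below
   `pressure_drop_min` (default 50 mbar) show no catalytic activity and are
   removed. The bound is inclusive: exactly 50 mbar counts as active.
5. **Consecutive timestamps (v).** Within a cycle, a point whose gap to the
   previous *retained* point exceeds twice the sampling interval is dropped,
   in one forward pass. Once a gap is hit every later point violates the
   same bound against the last retained point, so the cycle is effectively
   truncated at the first oversized gap — data beyond an interruption is not
   trusted. A gap of exactly 2× is retained. This truncating convention was
   chosen over "drop only the first post-gap point" because it is idempotent
   and never leaves a hidden discontinuity inside a cycle.

Then two cosmetic stages:

* **move_max.** Fresh gas dissolving into the liquid right after
  re-pressurization causes an aberrant early pressure loss that would appear
  as a spurious CH4 spike. `move_max > 0` erases the peak reading and the
  `move_max` points after it (the recorded maximum itself is unreliable when
  this artifact is present); `move_max = 0` leaves the cycle untouched.
* **average.** A centred moving mean of width `average`; the window shrinks
  at the series edges rather than padding, so no data is invented.
  `average = 1` disables smoothing.

## Rates, accumulation, inflection

* **Conversion rate.** For every sliding window of `calculation` consecutive
  points the rate is the negated ordinary-least-squares slope of pressure
  against time (mbar h⁻¹). Regression was chosen over endpoint differencing
  because it is exact on linear segments and maximally noise-robust for a
  fixed window; windows are demeaned per window, which keeps the estimate
  exact to rounding on linear data.
* **MER series.** Each window's Δp is the regression slope times the window
  duration, pushed through the stoichiometric and ideal-gas conversions and
  divided by the *current* culture volume. Using the slope rather than the
  literal window endpoints is identical on clean data and more robust under
  noise, and it keeps the maxima of conversion rate and MER co-located, as
  the inflection definition assumes.
* **Cumulative CH4.** Accumulation tiles each cycle with back-to-back
  windows sharing boundary points (the last one shortened to the final
  point) and applies the pressure-drop quantification to each window's
  endpoints. The sum telescopes exactly to the single-step value on
  (p_max, p_end), so no mole is ever double-counted; sliding windows are for
  rate display only.
* **Cultivation time.** T_cult accumulates only in-cycle elapsed time:
  cycle k starts on the T_cult axis where cycle k−1 ended. Metabolic
  activity during controller pauses is negligible (the headspace pressure
  holds while shaking is off), so pauses are excluded from every rate
  denominator. Each window is stamped with the T_cult of its end point.
* **Inflection.** The report returns the window of maximal conversion rate
  (ties broken toward the earliest T_cult), the maximum pressure-loss rate
  `k_min` in bar h⁻¹ — the field's name for what is numerically the most
  negative raw slope — and MER_max. This point marks the switch from
  gas-unlimited (biology-limited) to liquid-limited operation.

## Biomass coupling

OD578 readings taken at the end of cycles convert to dry biomass via the
strain coefficient α (g L⁻¹ per OD unit). qCH4 uses the final MER window of
the observed cycle (the moment growth was monitored) over x. µ is computed
for every consecutive OD pair as ln(OD_b/OD_a)/ΔT_cult and the maximum is
reported as µ_max — a reproducible convention where manual interval picking
would not be. Y_CH4 is Δx over the volumetric CH4 produced in the interval
(per-cycle totals divided by the culture volume in effect during each
cycle); this is the only combination of the available quantities with units
g mmol⁻¹. Sampling bookkeeping moves 0.7 mL from culture to headspace after
every sampled cycle, before the next cycle's rates; the total volume is
conserved exactly.

## The simulator

The simulator exists so that every stage can be validated against known
truth. It drives the bottle through a gassing program (flush, pressurize,
methanation, vent; methanation steps loop with re-pressurization) with a
deliberately minimal hybrid kinetic model:

* volumetric CH4 rate r(t) = min(qCH4_true · x(t), GTR_coeff · p(t)/1000),
  i.e. biology below a gas-transfer ceiling proportional to headspace
  pressure (constant kLa);
* gas uptake 5·r, CH4 return 1·r, net headspace loss 4·r, converted to a
  pressure decrement by the ideal-gas law on the current headspace volume;
* dx/dt = µ_true·x while biology-limited, x frozen while transfer-limited
  (real cultures keep growing slowly under limitation; freezing is the
  simplest convention that still produces the characteristic accelerating
  drop, inflection and first-order tail);
* no uptake until the lag time has elapsed;
* i.i.d. Gaussian noise on every reading (manometer quantization is not
  modelled).

Integration is an explicit fixed step at the sampling interval (10 s); at
these rates the step error is far below the manometer noise, and the
left-endpoint update makes the simulated mole balance exact by construction,
which the tests exploit. Pressurization ramps at a fixed rate
(default 200 mbar s⁻¹) and flushes vent to ambient — phase timing inside
flushes is a free parameter of the simulator, not a claim about any
instrument. A watchdog ends a methanation phase after `max_cycle_h` hours
so an inactive culture still yields a finite trace.

The artifact injector splices in, each individually switchable and logged:
short spurious valve cycles, long near-flat "inactive" cycles, readings
below the pressure floor, timestamp gaps, and a persistent post-peak
dissolution loss. Artifacts are inserted at cycle boundaries so ground-truth
cycles stay intact — which is exactly what lets tests assert that the
filters remove all of the former and none of the latter.

What the simulator does **not** emulate: pH and CO2-solubility chemistry,
temperature transients after sampling pauses, manometer drift or
quantization, biological heterogeneity (flocculation, lysis), and slow
growth under transfer limitation. Passing recovery tests therefore shows
the *analysis* is correct under the stated model, not that the model
captures every behaviour of a real culture.

## Default study conditions

The per-organism presets carry the published cultivation parameterization
(temperature, pH, volumes, Δpressure, α, and the trimming variables in
points). Synthetic validation runs use an *M. marburgensis*-like setting:
µ_true 0.55 h⁻¹ and qCH4_true 170 mmol g⁻¹ h⁻¹ (the strain's reported
maxima), x0 0.02 g L⁻¹ (an OD578 of ~0.05 at α 0.393, the standard
inoculation density), 5 mbar manometer noise, 4 bar absolute starts with
1 bar per cycle, and a transfer ceiling of 20 mmol L⁻¹ h⁻¹ bar⁻¹ for
gas-unlimited growth runs or 5 mmol L⁻¹ h⁻¹ bar⁻¹ for runs designed to
cross into transfer limitation mid-decay. Recovery runs use 12-cycle
programs (~3 × 10³ samples each); filter-suite checks use 8-cycle programs
across 100 seeds; inflection checks use a single long 2.5 bar decay across
50 seeds.

## Known estimator biases and limitations

* **qCH4 lags truth by the window curvature.** The end-of-cycle MER is a
  regression over the last `calculation` window, i.e. a window-averaged
  rate; for an exponentially accelerating culture it equals the
  instantaneous end rate times (1 − e^(−µT))/(µT) for window span T. With
  the reference 129-point window and µ = 0.55 h⁻¹ that is ≈ 0.91, so the
  recovered qCH4_max sits ~9% below truth while µ itself is recovered
  within ~1%. Shorter windows shrink the bias (~2% at 30 points) at the
  price of noisier rates.
* **Late, fast cycles drop out.** Once a cycle has fewer points than the
  rate window it is skipped with a warning; kinetics from the fastest phase
  of a run may therefore be truncated. Choose `calculation` with the
  expected cycle length in mind.
* **Cycle indices must align.** Biomass observations are matched to retained
  cycles by chronological index; if trimming were to discard a genuine
  sampled cycle the downstream matching would shift. The filter-suite tests
  guard this for the artifact classes modelled.
* **Degenerate inputs.** Empty traces, all-rising traces and dead cultures
  yield empty cycle lists (with warnings), not errors; zero biomass or zero
  CH4 flag the affected quantity as NaN rather than failing the run.
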