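# gpckin — pressure kinetics of automated closed-batch gas fermentation

`gpckin` turns raw headspace-pressure logs from an automated gas-and-pressure
controller into the physiological rates of gas-utilizing methanogens grown in
sealed, pressurized bottles. In such closed-batch cultivations the 4:1
H2/CO2 headspace is the sole feed: hydrogenotrophic methanogens run

    4 H2 + CO2  →  CH4 + 2 H2O

so five mol of gas are consumed per mol of CH4 formed and, because the CH4
stays in the headspace, each mbar of CH4 partial pressure corresponds to four
mbar of net pressure loss:

    p_CH4 = (p_before − p_after) / 4

Amounts follow from the ideal-gas law on the effective headspace volume
(bottle plus tubing), and the volumetric methane evolution rate normalizes by
culture volume:

    MER = Δn_CH4 / (Δt · V)        [mmol L⁻¹ h⁻¹]

From a single pressure log the package derives, per sliding window of
`calculation` points: the conversion rate (mbar h⁻¹, an OLS pressure slope),
p_CH4, n_CH4 (window and cumulative, with exact telescoping), MER, and the
cultivation time T_cult (in-cycle time only; pauses between cycles are
excluded). Coupled with end-of-cycle OD578 readings it adds the biomass
concentration x = α·OD578, the specific production rate qCH4 = MER_end/x,
the biomass rate r_x, the growth yield Y_CH4 = Δx per volumetric CH4, and
the specific growth rate µ = ln(OD_b/OD_a)/ΔT_cult. The operating point of
maximum conversion (`k_min`, bar h⁻¹, coinciding with MER_max) marks the
inflection from gas-unlimited to liquid-limited operation.

Raw logs are messy: valves chatter, manometers drift through re-gassing,
sampling interrupts logging, and freshly pressurized gas dissolves into the
liquid. The package implements the standard sequential trimming filters —
(i) minimum-pressure floor, (ii) segmentation into peak-to-threshold
methanation cycles, (iii) removal of short valve cycles (`len_cycles`),
(iv) removal of inactive cycles (< 50 mbar drop), (v) truncation at
non-consecutive timestamps — followed by the `move_max` post-peak trim and a
centred moving-mean smoother (`average`).

A closed-batch methanation **simulator** ships as first-class, tested code:
it drives a virtual bottle through a programmed gassing sequence
(flush / pressurize / methanation loops), models gas uptake as
`min(qCH4·x, GTR·p)` with exponential growth below the gas-transfer ceiling,
adds manometer noise and optional measurement artifacts, and exports the
ground truth — so every pipeline stage is testable without instrument data.

## Worked example

Simulate a 20-cycle cultivation of an *M. marburgensis*-like culture
(65 °C, 30 mL culture, 38.228 mL headspace, 1 bar per cycle, true
µ = 0.55 h⁻¹, true qCH4 = 170 mmol g⁻¹ h⁻¹, transfer ceiling
20 mmol L⁻¹ h⁻¹ bar⁻¹, 5 mbar manometer noise), then analyze it:

```sh
gpckin simulate --organism "M. marburgensis" --seed 1 --gtr 20 --out demo/sim
gpckin analyze  --organism "M. marburgensis" \
    --input demo/sim/raw_log.csv --biomass demo/sim/biomass.csv --out demo/res
```

which prints

```
replicate  n_cycles  mer_max_mmol_L_h  k_min_bar_h  inflection_t_cult_h  total_ch4_mmol  mu_max_h  qch4_max_mmol_g_h
     run1      20.0         70.530759     2.818577             8.161111        8.023284  0.554508         154.351986
     mean      20.0         70.530759     2.818577             8.161111        8.023284  0.554508         154.351986
       sd       NaN               NaN          NaN                  NaN             NaN       NaN                NaN
```

Reading the numbers: all 20 programmed methanation cycles survived the
trimming filters; the culture converted gas fastest at T_cult ≈ 8.2 h
(`k_min` 2.82 bar h⁻¹, MER_max 70.5 mmol L⁻¹ h⁻¹) — the inflection where the
gas-liquid transfer ceiling takes over from biology; 8.0 mmol CH4 were
produced in total. The recovered µ_max (0.5545 h⁻¹) matches the simulated
truth within 1%; the recovered qCH4_max (154 mmol g⁻¹ h⁻¹) sits ~9% below
the true 170 because a windowed end-of-cycle MER lags the instantaneous rate
of an exponentially accelerating culture (see `docs/methods.md`). With
several `--input` replicates the mean and sd rows summarize the group;
without `--biomass` the biomass-specific columns are omitted and the
analysis is kinetics-only. `gpckin plot --results demo/res` renders the
MER-versus-T_cult figures from the result CSVs.

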