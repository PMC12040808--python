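"""Closed-batch methanation simulator with exported ground truth.

Emulates a gas-and-pressure controller driving a sealed cultivation bottle
through a programmed gassing sequence (flush / pressurize / methanation /
vent) while an autotrophic, hydrogenotrophic methanogen consumes the 4:1
H2/CO2 headspace.  During a methanation phase the volumetric gas uptake is

    r_gas(t) = 5 * min(qch4_true * x(t),  gtr_coeff * p(t) / 1000)

in mmol per litre of culture per hour: five mol of gaseous substrate are
consumed per mol CH4 formed, biology sets the rate while the culture is
below the gas-transfer ceiling, and the ceiling itself is proportional to
the instantaneous headspace pressure (a constant-kLa transfer limit).
The CH4 formed stays in the headspace, so the net pressure loss is four
pressure units per unit of CH4 partial pressure — the same 4:1 accounting
the downstream quantification inverts.  Headspace pressure follows from
the ideal-gas law on the net loss; biomass grows
exponentially while uptake is biology-limited and is frozen while
transfer-limited.  Every reading carries additive Gaussian manometer noise.

The simulator writes everything a test needs into a truth sidecar: phase
boundaries, per-cycle true MER, the biology-to-transfer crossover time and
the true inflection point, all reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import OrganismConfig
from .types import BiomassObservation, PressureTrace

__all__ = [
    "GassingStep",
    "GassingProgram",
    "SimulationTruth",
    "ArtifactSpec",
    "simulate_run",
    "inject_artifacts",
    "default_program",
]

AMBIENT_MBAR = 1013.0

_PHASES = ("flush", "pressurize", "methanation", "vent")


class ProgramError(ValueError):
    """A gassing program violates an invariant."""


@dataclass
class GassingStep:
    """One step of the gassing program.

    For a methanation step ``target_mbar`` is the start pressure; the stop
    threshold is ``target_mbar - delta_p_cycle * 1000`` from the organism
    configuration.  ``loops`` repeats the step (a looped methanation step is
    re-pressurized before every repetition).
    """

    phase: str
    target_mbar: float
    loops: int = 1


@dataclass
class GassingProgram:
    steps: list[GassingStep]

    def validate(self, config: OrganismConfig) -> None:
        if not any(s.phase == "methanation" for s in self.steps):
            raise ProgramError("program contains no methanation step")
        for s in self.steps:
            if s.phase not in _PHASES:
                raise ProgramError(f"unknown phase {s.phase!r}")
            if s.target_mbar <= 0:
                raise ProgramError(f"{s.phase}: target pressure must be > 0 mbar")
            if s.loops < 1:
                raise ProgramError(f"{s.phase}: loops must be >= 1")
            if s.phase == "methanation":
                stop = config.stop_pressure(s.target_mbar)
                if stop >= s.target_mbar:
                    raise ProgramError("methanation stop threshold >= start pressure")
                if stop <= 0:
                    raise ProgramError(
                        f"methanation stop threshold {stop:.0f} mbar is not positive; "
                        f"lower delta_p_cycle or raise the start pressure")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [{"phase": s.phase, "target_mbar": s.target_mbar, "loops": s.loops}
             for s in self.steps]
        ).to_csv(path, index=False)


def default_program(start_mbar: float = 4000.0, loops: int = 20) -> GassingProgram:
    """Flush once, then loop pressurize-and-methanate ``loops`` times."""
    return GassingProgram(steps=[
        GassingStep("flush", start_mbar, 1),
        GassingStep("methanation", start_mbar, loops),
    ])


@dataclass
class SimulationTruth:
    """Ground-truth parameters (inputs) and recorded truth (outputs).

    Parameters
    ----------
    mu_true : float
        Specific growth rate while biology-limited, h^-1.
    qch4_true : float
        Specific CH4 production rate, mmol g^-1 h^-1.
    x0 : float
        Initial dry biomass concentration, g L^-1.
    gtr_coeff : float
        Gas-transfer ceiling per bar of headspace pressure,
        mmol L^-1 h^-1 bar^-1 (``inf`` = never transfer-limited).
    noise_sd : float
        Additive Gaussian manometer noise, mbar.
    seed : int
        Random seed; identical inputs and seed give identical traces.
    lag_h : float
        Lag phase: no uptake occurs until this many hours have elapsed.
    sample_each_cycle : bool
        Withdraw ``config.sample_draw`` mL of culture after every
        methanation cycle (shifts volume from culture to headspace).
    max_cycle_h : float
        Watchdog: a methanation phase ends after this many hours even if
        the stop threshold was never reached (inactive culture).
    ramp_rate, vent_rate : float
        Pressurization / venting speed, mbar s^-1.
    """

    mu_true: float
    qch4_true: float
    x0: float
    gtr_coeff: float = math.inf
    noise_sd: float = 0.0
    seed: int = 0
    lag_h: float = 0.0
    sample_each_cycle: bool = True
    max_cycle_h: float = 6.0
    ramp_rate: float = 200.0
    vent_rate: float = 400.0

    # --- filled in by simulate_run ---
    cycles: pd.DataFrame | None = None
    mer_max_true: float = float("nan")
    inflection_t_cult_h: float = float("nan")
    crossover_t_cult_h: float | None = None
    total_ch4_mmol: float = 0.0
    final_x: float = float("nan")

    def validate(self) -> None:
        for name in ("mu_true", "qch4_true", "x0", "gtr_coeff", "noise_sd", "lag_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def as_sidecar(self) -> dict:
        """JSON/YAML-serializable summary of parameters and recorded truth."""
        d = {
            "mu_true": self.mu_true, "qch4_true": self.qch4_true, "x0": self.x0,
            "gtr_coeff": None if math.isinf(self.gtr_coeff) else self.gtr_coeff,
            "noise_sd": self.noise_sd, "seed": self.seed, "lag_h": self.lag_h,
            "mer_max_true": self.mer_max_true,
            "inflection_t_cult_h": self.inflection_t_cult_h,
            "crossover_t_cult_h": self.crossover_t_cult_h,
            "total_ch4_mmol": self.total_ch4_mmol,
            "final_x": self.final_x,
        }
        if self.cycles is not None:
            d["cycles"] = self.cycles.to_dict(orient="records")
        return d


def simulate_run(config: OrganismConfig, program: GassingProgram,
                 truth: SimulationTruth,
                 ) -> tuple[PressureTrace, list[BiomassObservation], SimulationTruth]:
    """Run the closed-batch methanation model under a gassing program.

    Returns the noisy pressure trace, end-of-cycle biomass observations
    (empty when the configuration has no OD coefficient), and the truth
    object with its recorded-output fields filled in.
    """
    truth.validate()
    program.validate(config)
    rng = np.random.default_rng(truth.seed)

    dt = config.sample_interval
    dt_h = dt / 3600.0
    R = config.gas_constant
    T_K = config.temperature_K

    p = AMBIENT_MBAR
    x = truth.x0
    v_c = config.v_culture
    v_h = config.v_headspace

    times: list[float] = []
    pressures: list[float] = []
    t = 0.0
    t_cult_h = 0.0

    cycle_rows: list[dict] = []
    biomass: list[BiomassObservation] = []
    mer_max = 0.0
    t_at_mer_max = float("nan")
    crossover: float | None = None
    total_ch4 = 0.0
    cycle_idx = 0

    def record(value: float) -> None:
        nonlocal t
        noise = rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0
        times.append(t)
        pressures.append(value + noise)
        t += dt

    def ramp_to(target: float, rate: float) -> None:
        nonlocal p
        while abs(p - target) > 1e-9:
            step = rate * dt
            p = min(p + step, target) if target > p else max(p - step, target)
            record(p)

    record(p)  # initial ambient reading

    for step in program.steps:
        for _ in range(step.loops):
            if step.phase == "flush":
                ramp_to(step.target_mbar, truth.ramp_rate)
                ramp_to(AMBIENT_MBAR, truth.vent_rate)
            elif step.phase == "pressurize":
                ramp_to(step.target_mbar, truth.ramp_rate)
            elif step.phase == "vent":
                ramp_to(step.target_mbar, truth.vent_rate)
            else:  # methanation
                ramp_to(step.target_mbar, truth.ramp_rate)
                stop = config.stop_pressure(step.target_mbar)
                cycle_idx += 1
                start_idx = len(times)
                t_cult_start = t_cult_h
                rates: list[float] = []
                # mbar of headspace pressure per mmol of headspace gas
                mbar_per_mmol = 10.0 * R * T_K / v_h
                elapsed = 0.0
                while p > stop and elapsed < truth.max_cycle_h:
                    active = (t / 3600.0) >= truth.lag_h
                    ceiling = truth.gtr_coeff * p / 1000.0
                    biology = truth.qch4_true * x
                    r_ch4 = min(biology, ceiling) if active else 0.0
                    limited = active and ceiling < biology
                    if active and not limited:
                        x *= math.exp(truth.mu_true * dt_h)
                    if active and limited and crossover is None:
                        crossover = t_cult_h
                    if r_ch4 > mer_max:
                        mer_max = r_ch4
                        t_at_mer_max = t_cult_h
                    dn_ch4 = r_ch4 * (v_c / 1000.0) * dt_h  # mmol in this step
                    total_ch4 += dn_ch4
                    # 5 mmol gas consumed, 1 mmol CH4 returned: net loss 4
                    p -= 4.0 * dn_ch4 * mbar_per_mmol
                    t_cult_h += dt_h
                    elapsed += dt_h
                    rates.append(r_ch4)
                    record(p)
                od = (x / config.alpha_od) if config.alpha_od else None
                cycle_rows.append({
                    "cycle": cycle_idx,
                    "start_index": start_idx,
                    "end_index": len(times) - 1,
                    "t_cult_start_h": t_cult_start,
                    "t_cult_end_h": t_cult_h,
                    "p_start_mbar": step.target_mbar,
                    "p_stop_mbar": stop,
                    "mer_end_true": rates[-1] if rates else 0.0,
                    "mer_mean_true": float(np.mean(rates)) if rates else 0.0,
                    "ch4_mmol_true": sum(rates) * (v_c / 1000.0) * dt_h,
                    "x_end": x,
                    "od_end": od,
                    "v_culture_mL": v_c,
                    "v_headspace_mL": v_h,
                })
                if od is not None:
                    biomass.append(BiomassObservation(
                        cycle_index=cycle_idx, od578=od, time_h=t_cult_h,
                        x=x))
                if truth.sample_each_cycle:
                    if v_c - config.sample_draw <= 0:
                        raise ValueError("culture volume exhausted by sampling")
                    v_c -= config.sample_draw
                    v_h += config.sample_draw

    truth.cycles = pd.DataFrame(cycle_rows)
    truth.mer_max_true = mer_max
    truth.inflection_t_cult_h = t_at_mer_max
    truth.crossover_t_cult_h = crossover
    truth.total_ch4_mmol = total_ch4
    truth.final_x = x
    trace = PressureTrace(np.asarray(times), np.asarray(pressures), channel="sim")
    return trace, biomass, truth


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

@dataclass
class ArtifactSpec:
    """Which measurement artifacts to splice into a simulated trace.

    Every artifact class is individually switchable; the injector returns a
    log describing exactly what was inserted and where, so tests can verify
    that the trimming filters remove all of it and nothing else.
    """

    spurious_cycles: int = 0       # short valve cycles (decay < len_cycles points)
    spurious_len: int = 4          # points in each spurious decay
    spurious_rise: float = 400.0   # mbar rise that fakes a re-pressurization
    inactive_cycles: int = 0       # long cycles with < pressure_drop_min drop
    inactive_len: int = 60         # points in each inactive decay
    inactive_drop: float = 30.0    # total drop, mbar (< 50 by default)
    below_min_points: int = 0      # readings below the min_pressure floor
    gaps: list[float] = field(default_factory=list)  # timestamp gaps, s
    dissolution_spike_mbar: float = 0.0  # extra loss right after one peak
    dissolution_spike_points: int = 10
    seed: int = 0


def _refill_onsets(pressures: np.ndarray, min_step: float = 150.0) -> np.ndarray:
    """Indices of the last point before each steep re-pressurization rise."""
    d = np.diff(pressures)
    big = d >= min_step
    onset = big & ~np.concatenate(([False], big[:-1]))
    return np.flatnonzero(onset)


def inject_artifacts(trace: PressureTrace, spec: ArtifactSpec,
                     config: OrganismConfig | None = None,
                     ) -> tuple[PressureTrace, list[dict]]:
    """Splice the requested artifacts into a trace.

    Returns the corrupted trace and a log: one dict per artifact with its
    kind, output-index span and parameters.  An all-zero spec returns the
    input unchanged (with an empty log).
    """
    if len(trace) == 0:
        raise ValueError("cannot inject artifacts into an empty trace")
    t = trace.times.copy()
    p = trace.pressures.copy()
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 10.0
    min_pressure = config.min_pressure if config is not None else 1100.0
    rng = np.random.default_rng(spec.seed)
    log: list[dict] = []

    onsets = _refill_onsets(p)
    # keep artifacts away from the trace ends
    onsets = onsets[(onsets > 5) & (onsets < len(p) - 5)]
    n_sites = (spec.spurious_cycles + spec.inactive_cycles
               + (1 if spec.below_min_points else 0))
    if n_sites > len(onsets):
        raise ValueError(
            f"not enough cycle boundaries ({len(onsets)}) to place {n_sites} artifacts")
    chosen = rng.choice(len(onsets), size=n_sites, replace=False) if n_sites else []
    sites = sorted(int(onsets[i]) for i in chosen)

    inserts: list[tuple[int, np.ndarray, str, dict]] = []
    site_iter = iter(sites)
    for _ in range(spec.spurious_cycles):
        i = next(site_iter)
        base = p[i]
        seg = np.concatenate((
            [base + spec.spurious_rise],
            base + spec.spurious_rise - 20.0 * np.arange(1, spec.spurious_len),
        ))
        inserts.append((i, seg, "spurious_cycle",
                        {"decay_points": spec.spurious_len}))
    for _ in range(spec.inactive_cycles):
        i = next(site_iter)
        base = p[i]
        top = base + max(spec.spurious_rise, 600.0)
        seg = np.concatenate((
            [top],
            top - spec.inactive_drop * np.arange(1, spec.inactive_len) / (spec.inactive_len - 1),
        ))
        inserts.append((i, seg, "inactive_cycle",
                        {"drop_mbar": spec.inactive_drop, "points": spec.inactive_len}))
    if spec.below_min_points:
        i = next(site_iter)
        seg = np.full(spec.below_min_points, min_pressure - 100.0)
        inserts.append((i, seg, "below_min", {"points": spec.below_min_points}))

    # splice segments in ascending order, tracking the index shift
    offset = 0
    for i, seg, kind, params in inserts:
        j = i + offset
        seg_t = t[j] + dt * np.arange(1, len(seg) + 1)
        t = np.concatenate((t[: j + 1], seg_t, t[j + 1:] + dt * len(seg)))
        p = np.concatenate((p[: j + 1], seg, p[j + 1:]))
        log.append({"kind": kind, "start": j + 1, "stop": j + 1 + len(seg), **params})
        offset += len(seg)

    # timestamp gaps: widen the spacing inside the latter half of a decay
    if spec.gaps:
        onsets_now = _refill_onsets(p)
        for gap_s in spec.gaps:
            # pick a point mid-decay: halfway between two refill onsets
            if len(onsets_now) >= 2:
                a = int(rng.integers(len(onsets_now) - 1))
                idx = int((onsets_now[a] + onsets_now[a + 1]) // 2)
            else:
                idx = len(t) // 2
            shift = gap_s - (t[idx + 1] - t[idx])
            t[idx + 1:] += shift
            log.append({"kind": "gap", "index": idx, "gap_s": gap_s})

    # dissolution spike: extra, persistent pressure loss after one peak
    if spec.dissolution_spike_mbar > 0:
        onsets_now = _refill_onsets(p)
        if len(onsets_now) == 0:
            peak = int(np.argmax(p))
        else:
            onset = int(onsets_now[rng.integers(len(onsets_now))])
            # the peak is where the steep rise tops out
            k = onset + 1
            while k + 1 < len(p) and p[k + 1] > p[k]:
                k += 1
            peak = k
        n = spec.dissolution_spike_points
        ramp = spec.dissolution_spike_mbar * np.minimum(
            1.0, np.arange(1, len(p) - peak) / n)
        p[peak + 1:] -= ramp
        log.append({"kind": "dissolution_spike", "peak": peak,
                    "points": n, "mbar": spec.dissolution_spike_mbar})

    out = PressureTrace(t, p, channel=trace.channel)
    return out, log
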