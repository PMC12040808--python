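"""Stoichiometric CH4 quantification and rate series from clean cycles.

The net biomethanation reaction 4 H2 + CO2 -> CH4 + 2 H2O consumes five mol
of gas and returns one mol of CH4 to the headspace, so each mbar of CH4
partial pressure formed corresponds to four mbar of net pressure loss:

    p_CH4 = (p_before - p_after) / 4

Amounts follow from the ideal-gas law on the effective headspace volume,
and the volumetric methane evolution rate normalizes by culture volume:

    MER = dn_CH4 / (dt * V)          [mmol L^-1 h^-1]

Rates are estimated as ordinary-least-squares pressure slopes over sliding
windows of ``calculation`` consecutive points; cumulative CH4 uses exact
endpoint telescoping over non-overlapping windows so no mole is counted
twice.  All derived series live on the cultivation clock T_cult, which
accumulates only in-cycle time (pauses between cycles carry no significant
activity and are excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import OrganismConfig
from .types import Cycle

__all__ = [
    "methane_partial_pressure",
    "pressure_to_moles",
    "conversion_rate_series",
    "analyze_kinetics",
    "cumulative_ch4",
    "cultivation_time",
    "detect_inflection",
    "InflectionReport",
]

log = logging.getLogger(__name__)

KINETICS_COLUMNS = [
    "cycle", "t_cult_h", "conv_rate_mbar_h", "pch4_mbar",
    "nch4_mmol", "nch4_cum_mmol", "mer_mmol_L_h",
]


def methane_partial_pressure(p_before: float, p_after: float) -> float:
    """CH4 partial pressure formed over a net pressure drop, mbar."""
    if p_after > p_before:
        raise ValueError(
            f"negative pressure drop ({p_before} -> {p_after} mbar): "
            "an unfiltered re-pressurization lies inside the window")
    return (p_before - p_after) / 4.0


def pressure_to_moles(p_mbar: float, v_headspace_ml: float,
                      temperature_c: float, gas_constant: float = 8.314) -> float:
    """Ideal-gas conversion of a (partial) pressure to an amount, mmol.

    n = p V / (R T) with p in mbar (1 mbar = 100 Pa), V in mL (1e-6 m3) and
    the result in mmol, which collapses to ``0.1 * p * V / (R * T_K)``.
    """
    if v_headspace_ml <= 0:
        raise ValueError(f"headspace volume must be > 0 mL, got {v_headspace_ml}")
    if temperature_c <= -273.15:
        raise ValueError(f"temperature below absolute zero: {temperature_c}")
    if np.any(np.asarray(p_mbar) < 0):
        raise ValueError("partial pressure must be >= 0")
    return 0.1 * p_mbar * v_headspace_ml / (gas_constant * (temperature_c + 273.15))


def _window_slopes(t_h: np.ndarray, p: np.ndarray, w: int) -> np.ndarray:
    """OLS slope of p vs t (per hour) for every sliding window of w points.

    Per-window demeaning keeps the estimate exact (to rounding) on linear
    data, which endpoint or running-sum formulations would not guarantee.
    """
    tw = np.lib.stride_tricks.sliding_window_view(t_h, w)
    pw = np.lib.stride_tricks.sliding_window_view(p, w)
    tc = tw - tw.mean(axis=1, keepdims=True)
    pc = pw - pw.mean(axis=1, keepdims=True)
    return (tc * pc).sum(axis=1) / (tc * tc).sum(axis=1)


def conversion_rate_series(cycle: Cycle, config: OrganismConfig) -> pd.DataFrame:
    """Sliding-window conversion rates for one cycle, in mbar h^-1.

    Each window spans ``calculation`` consecutive points and advances by
    one; the rate is the negated OLS slope of pressure against time, so a
    positive rate is a pressure loss.  Returns one row per window with the
    window's span and duration; an empty frame if the cycle is too short.
    """
    w = config.calculation
    if cycle.n_points < w:
        log.warning("cycle %d has %d points < calculation window %d; skipped",
                    cycle.index, cycle.n_points, w)
        return pd.DataFrame(columns=["start", "end", "dt_h", "conv_rate_mbar_h"])
    t_h = (cycle.times - cycle.times[0]) / 3600.0
    slopes = _window_slopes(t_h, cycle.pressures, w)
    i = np.arange(cycle.n_points - w + 1)
    return pd.DataFrame({
        "start": i,
        "end": i + w - 1,
        "dt_h": t_h[i + w - 1] - t_h[i],
        "conv_rate_mbar_h": -slopes,
    })


def cultivation_time(cycles: list[Cycle]) -> list[float]:
    """T_cult offset (h) at which each cycle starts.

    Only in-cycle elapsed time accumulates: cycle k starts where cycle k-1
    ended, regardless of the pause between them.
    """
    offsets = []
    acc = 0.0
    for c in cycles:
        offsets.append(acc)
        acc += c.duration_h
    return offsets


def analyze_kinetics(cycles: list[Cycle], config: OrganismConfig,
                     volumes: list[tuple[float, float]] | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windowed kinetics series and per-cycle totals for a cleaned run.

    Parameters
    ----------
    cycles : list of Cycle
        Output of :func:`gpckin.preprocess.preprocess`.
    config : OrganismConfig
    volumes : list of (v_culture_mL, v_headspace_mL), optional
        Effective volumes during each cycle; defaults to the configured
        volumes for every cycle (no sampling bookkeeping).

    Returns
    -------
    kinetics : DataFrame
        One row per sliding window: cycle, t_cult_h (at the window end),
        conv_rate_mbar_h, pch4_mbar, nch4_mmol, nch4_cum_mmol, mer_mmol_L_h.
    per_cycle : DataFrame
        One row per cycle: t_cult bounds, pressure drop, total and
        cumulative CH4 (exact endpoint telescoping), final-window MER
        (mer_end) and the volumes in effect.
    """
    if volumes is None:
        volumes = [(config.v_culture, config.v_headspace)] * len(cycles)
    if len(volumes) != len(cycles):
        raise ValueError("volumes must supply one (v_culture, v_headspace) per cycle")

    offsets = cultivation_time(cycles)
    rows = []
    cyc_rows = []
    cum = 0.0
    for c, t0, (v_c, v_h) in zip(cycles, offsets, volumes):
        if v_c <= 0:
            raise ValueError(f"culture volume must be > 0 mL, got {v_c}")
        win = conversion_rate_series(c, config)
        t_h = (c.times - c.times[0]) / 3600.0
        mer_end = float("nan")
        if not win.empty:
            dt = win["dt_h"].to_numpy()
            rate = win["conv_rate_mbar_h"].to_numpy()
            pch4 = rate * dt / 4.0
            nch4 = 0.1 * pch4 * v_h / (config.gas_constant * config.temperature_K)
            mer = nch4 / (dt * v_c / 1000.0)
            end = win["end"].to_numpy().astype(int)
            # telescoping cumulative: exact from the cycle start to each window end
            drop_from_start = np.maximum(c.pressures[0] - c.pressures[end], 0.0)
            cum_at_end = cum + 0.1 * (drop_from_start / 4.0) * v_h / (
                config.gas_constant * config.temperature_K)
            rows.append(pd.DataFrame({
                "cycle": c.index,
                "t_cult_h": t0 + t_h[end],
                "conv_rate_mbar_h": rate,
                "pch4_mbar": pch4,
                "nch4_mmol": nch4,
                "nch4_cum_mmol": cum_at_end,
                "mer_mmol_L_h": mer,
            }))
            mer_end = float(mer[-1])
        n_cycle = cumulative_ch4(c, config, v_headspace=v_h)
        cum += n_cycle
        cyc_rows.append({
            "cycle": c.index,
            "t_cult_start_h": t0,
            "t_cult_end_h": t0 + c.duration_h,
            "duration_h": c.duration_h,
            "n_points": c.n_points,
            "p_max_mbar": c.p_max,
            "p_end_mbar": c.p_end,
            "drop_mbar": c.pressure_drop,
            "nch4_mmol": n_cycle,
            "nch4_cum_mmol": cum,
            "mer_end_mmol_L_h": mer_end,
            "v_culture_mL": v_c,
            "v_headspace_mL": v_h,
        })
    kinetics = (pd.concat(rows, ignore_index=True)
                if rows else pd.DataFrame(columns=KINETICS_COLUMNS))
    per_cycle = pd.DataFrame(cyc_rows)
    return kinetics, per_cycle


def cumulative_ch4(cycle: Cycle, config: OrganismConfig, *,
                   v_headspace: float | None = None) -> float:
    """Total CH4 of one cycle, mmol, by non-overlapping window telescoping.

    The cycle is tiled with back-to-back windows of ``calculation`` points
    (the last window is shortened to reach the final point); each window
    applies the 4:1 drop-to-CH4 rule to its endpoints.  The sum telescopes
    to the same rule applied once on
    (p_max, p_end) exactly, so accumulation never double-counts a mole.
    """
    v_h = config.v_headspace if v_headspace is None else v_headspace
    w = config.calculation
    p = cycle.pressures
    bounds = list(range(0, len(p) - 1, max(w - 1, 1))) + [len(p) - 1]
    total_pch4 = 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        total_pch4 += (p[a] - p[b]) / 4.0
    return pressure_to_moles(max(total_pch4, 0.0), v_h, config.temperature,
                             config.gas_constant)


@dataclass
class InflectionReport:
    """The operating point of maximum conversion.

    ``k_min`` is the field's name for the maximum windowed pressure-loss
    rate (bar h^-1) — the most negative raw pressure slope; its time point
    marks the switch from gas-unlimited to liquid-limited operation and
    coincides with the MER peak.
    """

    cycle_index: int
    t_cult_h: float
    k_min_bar_h: float
    mer_max_mmol_L_h: float


def detect_inflection(kinetics: pd.DataFrame) -> InflectionReport | None:
    """Locate the window of maximal conversion rate (ties: earliest T_cult)."""
    if kinetics.empty:
        return None
    df = kinetics.sort_values("t_cult_h", kind="stable").reset_index(drop=True)
    i = int(df["conv_rate_mbar_h"].to_numpy().argmax())
    return InflectionReport(
        cycle_index=int(df.loc[i, "cycle"]),
        t_cult_h=float(df.loc[i, "t_cult_h"]),
        k_min_bar_h=float(df["conv_rate_mbar_h"].max() / 1000.0),
        mer_max_mmol_L_h=float(df["mer_mmol_L_h"].max()),
    )
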