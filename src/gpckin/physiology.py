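"""Biomass-coupled physiology: qCH4, growth rate, biomass rate and yield.

End-of-cycle optical density observations are coupled to the kinetics
series: the specific CH4 production rate qCH4 uses the final MER of each
cycle (the moment growth was monitored), the specific growth rate uses the
exponential formulation on the cultivation clock (pauses between cycles
carry no significant activity), and the growth yield Y_CH4 relates biomass
formed to volumetric CH4 produced over the same interval.  Sampling
bookkeeping moves 0.7 mL from culture to headspace after every sampled
cycle, and every downstream rate uses the volumes in effect at its time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import OrganismConfig
from .types import BiomassObservation

__all__ = [
    "VolumeState",
    "volume_update",
    "qch4_per_cycle",
    "growth_rate_mu",
    "biomass_rate",
    "yield_ych4",
    "compute_physiology",
    "volume_schedule",
]

PHYSIOLOGY_COLUMNS = [
    "cycle", "t_cult_h", "od578", "x_g_L", "mer_end", "qch4", "r_x",
    "y_ch4", "mu", "v_culture_mL", "v_headspace_mL",
]


@dataclass(frozen=True)
class VolumeState:
    """Culture and headspace volume, mL, at a point in the run."""

    v_culture: float
    v_headspace: float


def volume_update(state: VolumeState, n_samples: int,
                  sample_draw: float = 0.7) -> VolumeState:
    """Move ``n_samples * sample_draw`` mL from culture to headspace."""
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    taken = n_samples * sample_draw
    if state.v_culture - taken <= 0:
        raise ValueError(
            f"sampling {taken} mL would exhaust the {state.v_culture} mL culture")
    return VolumeState(state.v_culture - taken, state.v_headspace + taken)


def volume_schedule(config: OrganismConfig, n_cycles: int,
                    sampled_cycles: set[int] | None = None,
                    ) -> list[tuple[float, float]]:
    """Volumes (v_culture, v_headspace) in effect during each cycle 1..n.

    ``sampled_cycles`` are the chronological cycle indices after which one
    sample was drawn; ``None`` means every cycle was sampled (the standard
    protocol pauses after each cycle to measure OD).
    """
    state = VolumeState(config.v_culture, config.v_headspace)
    out = []
    for k in range(1, n_cycles + 1):
        out.append((state.v_culture, state.v_headspace))
        if sampled_cycles is None or k in sampled_cycles:
            state = volume_update(state, 1, config.sample_draw)
    return out


def qch4_per_cycle(mer_end: float, x: float) -> float:
    """Specific CH4 production rate, mmol g^-1 h^-1 (NaN when x is 0)."""
    if x < 0:
        raise ValueError(f"biomass concentration must be >= 0, got {x}")
    if x == 0 or not np.isfinite(mer_end):
        return float("nan")
    return mer_end / x


def growth_rate_mu(obs_a: BiomassObservation, obs_b: BiomassObservation) -> float:
    """Specific growth rate, h^-1: ln(OD_b / OD_a) / (t_b - t_a) on T_cult."""
    if obs_a.od578 <= 0 or obs_b.od578 <= 0:
        raise ValueError("growth rate needs strictly positive OD values")
    if obs_a.time_h is None or obs_b.time_h is None or obs_b.time_h <= obs_a.time_h:
        raise ValueError("observations must be ordered in cultivation time")
    return math.log(obs_b.od578 / obs_a.od578) / (obs_b.time_h - obs_a.time_h)


def biomass_rate(obs_a: BiomassObservation, obs_b: BiomassObservation) -> float:
    """Volumetric biomass production rate r_x, g L^-1 h^-1."""
    if obs_a.time_h is None or obs_b.time_h is None or obs_b.time_h <= obs_a.time_h:
        raise ValueError("observations must be ordered in cultivation time")
    if obs_a.x is None or obs_b.x is None:
        return float("nan")
    return (obs_b.x - obs_a.x) / (obs_b.time_h - obs_a.time_h)


def yield_ych4(obs_a: BiomassObservation, obs_b: BiomassObservation,
               ch4_volumetric: float) -> float:
    """Growth yield Y_CH4, g mmol^-1: biomass formed per volumetric CH4.

    ``ch4_volumetric`` is the CH4 produced between the observations in
    mmol per litre of culture; g L^-1 over mmol L^-1 leaves g mmol^-1.
    Returns NaN (flagged, not an error) when no CH4 was produced.
    """
    if obs_a.x is None or obs_b.x is None:
        return float("nan")
    if ch4_volumetric <= 0:
        return float("nan")
    return (obs_b.x - obs_a.x) / ch4_volumetric


def compute_physiology(per_cycle: pd.DataFrame,
                       observations: list[BiomassObservation],
                       config: OrganismConfig) -> pd.DataFrame:
    """Per-cycle physiology table from kinetics totals and OD observations.

    ``per_cycle`` is the cycle summary from
    :func:`gpckin.kinetics.analyze_kinetics` (already carrying the volumes
    in effect).  Observations are matched to cycles by chronological index;
    pairwise quantities (mu, r_x, Y_CH4) span consecutive observations.
    """
    obs = sorted(observations, key=lambda o: o.cycle_index)
    by_cycle = per_cycle.set_index("cycle")
    rows = []
    prev: BiomassObservation | None = None
    prev_row = None
    for o in obs:
        if o.cycle_index not in by_cycle.index:
            raise ValueError(
                f"biomass observation references cycle {o.cycle_index}, "
                "which is not among the retained cycles")
        row = by_cycle.loc[o.cycle_index]
        o = BiomassObservation(
            cycle_index=o.cycle_index, od578=o.od578,
            time_h=float(row["t_cult_end_h"]),
            x=(config.alpha_od * o.od578) if config.alpha_od else o.x)
        mer_end = float(row["mer_end_mmol_L_h"])
        qch4 = qch4_per_cycle(mer_end, o.x) if o.x is not None else float("nan")
        mu = r_x = y = float("nan")
        if prev is not None and o.od578 > 0 and prev.od578 > 0:
            mu = growth_rate_mu(prev, o)
            r_x = biomass_rate(prev, o)
            # volumetric CH4 over the interval: per-cycle totals over the
            # culture volume in effect during each contributing cycle
            sel = by_cycle.loc[(by_cycle.index > prev.cycle_index)
                               & (by_cycle.index <= o.cycle_index)]
            ch4_vol = float((sel["nch4_mmol"] / (sel["v_culture_mL"] / 1000.0)).sum())
            y = yield_ych4(prev, o, ch4_vol)
        rows.append({
            "cycle": o.cycle_index,
            "t_cult_h": o.time_h,
            "od578": o.od578,
            "x_g_L": o.x if o.x is not None else float("nan"),
            "mer_end": mer_end,
            "qch4": qch4,
            "r_x": r_x,
            "y_ch4": y,
            "mu": mu,
            "v_culture_mL": float(row["v_culture_mL"]),
            "v_headspace_mL": float(row["v_headspace_mL"]),
        })
        prev, prev_row = o, row
    return pd.DataFrame(rows, columns=PHYSIOLOGY_COLUMNS)
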