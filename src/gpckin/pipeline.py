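"""End-to-end analysis: raw trace -> cleaned cycles -> kinetics -> physiology."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import OrganismConfig
from .kinetics import InflectionReport, analyze_kinetics, detect_inflection
from .physiology import compute_physiology, volume_schedule
from .preprocess import preprocess
from .types import BiomassObservation, Cycle, PressureTrace

__all__ = ["AnalysisResult", "analyze_run", "summarize_replicates"]


@dataclass
class AnalysisResult:
    """Everything one replicate's analysis produces."""

    cycles: list[Cycle]
    kinetics: pd.DataFrame
    per_cycle: pd.DataFrame
    physiology: pd.DataFrame | None
    inflection: InflectionReport | None

    @property
    def mu_max(self) -> float:
        """Maximum pairwise specific growth rate, h^-1 (NaN without biomass)."""
        if self.physiology is None or self.physiology.empty:
            return float("nan")
        vals = self.physiology["mu"].dropna()
        return float(vals.max()) if len(vals) else float("nan")

    @property
    def qch4_max(self) -> float:
        """Maximum per-cycle specific CH4 production rate, mmol g^-1 h^-1."""
        if self.physiology is None or self.physiology.empty:
            return float("nan")
        vals = self.physiology["qch4"].dropna()
        return float(vals.max()) if len(vals) else float("nan")

    def summary(self) -> dict:
        d = {
            "n_cycles": len(self.cycles),
            "mer_max_mmol_L_h": self.inflection.mer_max_mmol_L_h if self.inflection else float("nan"),
            "k_min_bar_h": self.inflection.k_min_bar_h if self.inflection else float("nan"),
            "inflection_t_cult_h": self.inflection.t_cult_h if self.inflection else float("nan"),
            "total_ch4_mmol": float(self.per_cycle["nch4_cum_mmol"].iloc[-1])
            if len(self.per_cycle) else 0.0,
        }
        d["mu_max_h"] = self.mu_max
        d["qch4_max_mmol_g_h"] = self.qch4_max
        return d


def analyze_run(trace: PressureTrace, config: OrganismConfig,
                biomass: list[BiomassObservation] | None = None, *,
                apply_smoothing: bool = True,
                sampling_follows_biomass: bool = True) -> AnalysisResult:
    """Run trimming, kinetics and (when biomass is given) physiology.

    Without biomass observations the result degrades gracefully to a
    kinetics-only analysis (``physiology is None``) and the configured
    volumes apply throughout.  With biomass, one sample (``sample_draw``
    mL) is booked after every observed cycle, so later cycles see a smaller
    culture and a larger headspace.
    """
    cycles = preprocess(trace, config, apply_smoothing=apply_smoothing)
    if biomass and sampling_follows_biomass:
        sampled = {o.cycle_index for o in biomass}
    else:
        sampled = set()
    volumes = volume_schedule(config, len(cycles),
                              sampled_cycles=sampled or set())
    kinetics, per_cycle = analyze_kinetics(cycles, config, volumes)
    physiology = None
    if biomass:
        physiology = compute_physiology(per_cycle, biomass, config)
    return AnalysisResult(
        cycles=cycles, kinetics=kinetics, per_cycle=per_cycle,
        physiology=physiology, inflection=detect_inflection(kinetics))


def summarize_replicates(results: list[AnalysisResult]) -> pd.DataFrame:
    """Per-replicate headline numbers plus mean and sd rows (ddof=1)."""
    rows = [r.summary() for r in results]
    df = pd.DataFrame(rows)
    df.insert(0, "replicate", [f"run{i + 1}" for i in range(len(rows))])
    numeric = df.drop(columns=["replicate"])
    mean = numeric.mean()
    sd = numeric.std(ddof=1) if len(rows) > 1 else numeric.iloc[0] * np.nan
    stats = pd.DataFrame([mean, sd])
    stats.insert(0, "replicate", ["mean", "sd"])
    return pd.concat([df, stats], ignore_index=True)
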