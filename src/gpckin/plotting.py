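"""Static figures regenerated deterministically from result CSVs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_pressure_kinetics", "plot_mer"]


def plot_pressure_kinetics(cycles, kinetics: pd.DataFrame, out_path, *,
                           title: str = "") -> Path:
    """Pressure vs. run time with windows coloured by conversion rate.

    Mirrors the classic view of a closed-batch run: sawtooth pressure decay
    per cycle, warm colours where conversion is fastest.
    """
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(8, 4))
    if not cycles:
        ax.text(0.5, 0.5, "no retained cycles", ha="center", va="center")
    else:
        for c in cycles:
            ax.plot(c.times / 3600.0, c.pressures, color="0.6", lw=0.5, zorder=1)
        if not kinetics.empty:
            # colour each window's end point by its conversion rate
            for c in cycles:
                rows = kinetics[kinetics["cycle"] == c.index]
                if rows.empty:
                    continue
                n = len(rows)
                ax.scatter(c.times[-n:] / 3600.0, c.pressures[-n:],
                           c=rows["conv_rate_mbar_h"], cmap="viridis",
                           s=4, zorder=2)
    ax.set_xlabel("run time / h")
    ax.set_ylabel("headspace pressure / mbar")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120, metadata={"Software": None})
    plt.close(fig)
    return out_path


def plot_mer(kinetics: pd.DataFrame, out_path, *, title: str = "") -> Path:
    """MER over the cultivation time T_cult."""
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(8, 4))
    if kinetics.empty:
        ax.text(0.5, 0.5, "empty kinetics series", ha="center", va="center")
    else:
        for cyc, grp in kinetics.groupby("cycle"):
            ax.plot(grp["t_cult_h"], grp["mer_mmol_L_h"], lw=1.0,
                    label=f"cycle {cyc}")
    ax.set_xlabel("T$_{cult}$ / h")
    ax.set_ylabel("MER / mmol L$^{-1}$ h$^{-1}$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120, metadata={"Software": None})
    plt.close(fig)
    return out_path
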