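"""Readers and writers for every file the pipeline touches.

Raw logs are plain CSV with columns ``time_s`` and ``pressure_mbar``; the
gassing program is CSV with columns ``phase,target_mbar,loops``; biomass
tables are CSV with columns ``cycle,od578``; results are tidy CSV, one row
per rate window and one row per cycle.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import OrganismConfig
from .types import BiomassObservation, PressureTrace

__all__ = [
    "read_pressure_log",
    "emit_raw_log",
    "read_biomass_table",
    "write_results",
    "read_gassing_program",
]

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not match the expected layout."""


class EmptyInputError(ValueError):
    """A file parsed fine but contains no data rows."""


def emit_raw_log(trace: PressureTrace, path) -> Path:
    """Write a pressure trace as a raw-log CSV (``time_s,pressure_mbar``).

    Serialization uses repr-round-trip float formatting so that
    :func:`read_pressure_log` recovers the trace exactly.
    """
    path = Path(path)
    try:
        with open(path, "w", newline="") as fh:
            fh.write("time_s,pressure_mbar\n")
            for t, p in zip(trace.times, trace.pressures):
                fh.write(f"{float(t)!r},{float(p)!r}\n")
    except OSError as exc:
        raise OSError(f"could not write raw log to {path}: {exc}") from exc
    return path


def read_pressure_log(path, *, channel: str | None = None,
                      time_column: str = "time_s",
                      pressure_column: str = "pressure_mbar",
                      pressure_offset: float = 0.0) -> PressureTrace:
    """Parse a raw pressure log CSV into a :class:`PressureTrace`.

    Rows whose time or pressure field cannot be parsed as a number are
    dropped with a logged count.  ``pressure_offset`` is added to every
    reading, which converts gauge-pressure logs to absolute
    (e.g. ``pressure_offset=1013``).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (time_column, pressure_column):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r} "
                              f"(found: {', '.join(df.columns)})")
    t = pd.to_numeric(df[time_column], errors="coerce")
    p = pd.to_numeric(df[pressure_column], errors="coerce")
    good = t.notna() & p.notna()
    n_bad = int((~good).sum())
    if n_bad:
        log.warning("%s: dropped %d unparseable row(s)", path, n_bad)
    if not good.any():
        raise EmptyInputError(f"{path}: no data rows")
    return PressureTrace(
        times=t[good].to_numpy(dtype=float),
        pressures=p[good].to_numpy(dtype=float) + pressure_offset,
        channel=channel or path.stem,
    )


def read_biomass_table(path, config: OrganismConfig) -> list[BiomassObservation]:
    """Read end-of-cycle OD578 observations and attach dry-mass values.

    Requires columns ``cycle`` and ``od578``.  The dry biomass concentration
    ``x = alpha_od * od578`` is filled in when the configuration carries an
    OD-to-dry-mass coefficient; otherwise ``x`` stays ``None`` and biomass-
    specific quantities are left uncomputed downstream.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("cycle", "od578"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    obs = []
    for _, row in df.iterrows():
        od = float(row["od578"])
        if od < 0:
            raise ValueError(f"{path}: negative od578 {od} in cycle {row['cycle']}")
        obs.append(BiomassObservation(
            cycle_index=int(row["cycle"]),
            od578=od,
            x=(config.alpha_od * od) if config.alpha_od is not None else None,
        ))
    return obs


def write_results(kinetics: pd.DataFrame, physiology: pd.DataFrame | None,
                  out_dir, *, prefix: str = "") -> dict[str, Path]:
    """Write the windowed kinetics series and per-cycle physiology as tidy CSV.

    Returns a mapping of logical name -> written path.  An empty physiology
    table produces a header-only file; passing ``None`` skips the file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    kpath = out_dir / f"{prefix}kinetics.csv"
    kinetics.to_csv(kpath, index=False, float_format="%.10g")
    written["kinetics"] = kpath
    if physiology is not None:
        ppath = out_dir / f"{prefix}physiology.csv"
        physiology.to_csv(ppath, index=False, float_format="%.10g")
        written["physiology"] = ppath
    return written


def read_gassing_program(path):
    """Read a gassing-program CSV (``phase,target_mbar,loops``).

    Returns the :class:`~gpckin.simulate.GassingProgram` the simulator
    consumes.  Implemented here so that every on-disk format lives in one
    module; the class itself is defined with the simulator.
    """
    from .simulate import GassingProgram, GassingStep

    path = Path(path)
    df = pd.read_csv(path)
    for col in ("phase", "target_mbar", "loops"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise EmptyInputError(f"{path}: no program steps")
    steps = [
        GassingStep(phase=str(r["phase"]).strip().lower(),
                    target_mbar=float(r["target_mbar"]),
                    loops=int(r["loops"]))
        for _, r in df.iterrows()
    ]
    return GassingProgram(steps=steps)
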