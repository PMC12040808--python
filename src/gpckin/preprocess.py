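"""Sequential trimming filters that turn a raw pressure log into clean cycles.

The filters run strictly in this order:

(i)    drop readings below the absolute ``min_pressure`` floor;
(ii)   segment the trace into methanation cycles (peak -> stop threshold or
       the local minimum before the next re-pressurization; rising points
       are discarded);
(iii)  drop cycles shorter than ``len_cycles`` points (valve chatter);
(iv)   drop cycles whose total pressure drop is below ``pressure_drop_min``
       (no catalytic activity; boundary inclusive, a drop of exactly the
       threshold is kept);
(v)    within each cycle, truncate at the first timestamp gap exceeding
       twice the sampling interval (boundary inclusive, a gap of exactly
       2x is kept);

then the ``move_max`` trim erases the peak reading and the ``move_max``
points after it (mitigating the aberrant early pressure loss caused by gas
dissolving into the fresh liquid), and finally a centred moving mean of
width ``average`` smooths each cycle.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import OrganismConfig
from .types import Cycle, PressureTrace

__all__ = [
    "filter_min_pressure",
    "segment_cycles",
    "drop_short_cycles",
    "drop_inactive_cycles",
    "enforce_consecutive",
    "trim_after_max",
    "smooth",
    "preprocess",
]

log = logging.getLogger(__name__)


def filter_min_pressure(trace: PressureTrace, config: OrganismConfig) -> PressureTrace:
    """Filter (i): drop every reading below the ``min_pressure`` floor."""
    keep = trace.pressures >= config.min_pressure
    if not keep.any():
        log.warning("min-pressure filter removed every point of %s", trace.channel)
    return PressureTrace(trace.times[keep], trace.pressures[keep], trace.channel)


def _rise_runs(p: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of strictly increasing steps with total rise >= threshold.

    Returns (start, top) index pairs: ``start`` is the local minimum the rise
    departs from, ``top`` the index where it peaks.
    """
    runs = []
    n = len(p)
    i = 0
    while i < n - 1:
        if p[i + 1] > p[i]:
            j = i
            while j < n - 1 and p[j + 1] > p[j]:
                j += 1
            if p[j] - p[i] >= threshold:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def segment_cycles(trace: PressureTrace, config: OrganismConfig) -> list[Cycle]:
    """Filter (ii): cut the trace into methanation cycles.

    A cycle starts at the pressure maximum that follows a re-pressurization
    (a monotone rise of at least ``refill_threshold`` mbar) or the trace
    start, and ends at the stop threshold ``p_max - delta_p_cycle * 1000``
    or at the local minimum before the next re-pressurization, whichever
    comes first.  Rising points and post-threshold tails are discarded.
    """
    t, p = trace.times, trace.pressures
    n = len(p)
    if n == 0:
        return []
    runs = _rise_runs(p, config.refill_threshold)

    # blocks of candidate decay data: peak-to-minimum stretches between rises
    blocks: list[tuple[int, int]] = []  # inclusive [a, b]
    prev_top = 0
    for start, top in runs:
        if start >= prev_top:
            blocks.append((prev_top, start))
        prev_top = top
    blocks.append((prev_top, n - 1))

    cycles: list[Cycle] = []
    for a, b in blocks:
        if b - a + 1 < 2:
            continue
        peak = a + int(np.argmax(p[a:b + 1]))
        if b - peak + 1 < 2:
            continue
        stop_threshold = p[peak] - config.delta_p_cycle * 1000.0
        below = np.flatnonzero(p[peak:b + 1] <= stop_threshold)
        end = peak + int(below[0]) if below.size else b
        if end - peak + 1 < 2:
            continue
        cycles.append(Cycle(
            index=len(cycles) + 1,
            times=t[peak:end + 1].copy(),
            pressures=p[peak:end + 1].copy(),
            start=peak, stop=end + 1,
        ))
    if not cycles:
        log.warning("no methanation cycle found in %s", trace.channel)
    return cycles


def drop_short_cycles(cycles: list[Cycle], config: OrganismConfig) -> list[Cycle]:
    """Filter (iii): remove cycles with fewer than ``len_cycles`` points."""
    return [c for c in cycles if c.n_points >= config.len_cycles]


def drop_inactive_cycles(cycles: list[Cycle], config: OrganismConfig) -> list[Cycle]:
    """Filter (iv): remove cycles whose drop is below ``pressure_drop_min``.

    A drop of exactly the threshold is retained.
    """
    return [c for c in cycles if c.pressure_drop >= config.pressure_drop_min]


def enforce_consecutive(cycle: Cycle, config: OrganismConfig) -> Cycle:
    """Filter (v): truncate a cycle at the first oversized timestamp gap.

    A point whose gap to the previous retained point exceeds twice the
    sampling interval is dropped, in a single forward pass; once a gap is
    hit, every later point of the cycle necessarily violates the same bound
    and the cycle is effectively truncated there.  A gap of exactly twice
    the interval is retained.
    """
    t = cycle.times
    limit = 2.0 * config.sample_interval
    keep = [0]
    for j in range(1, len(t)):
        if t[j] - t[keep[-1]] <= limit:
            keep.append(j)
    if len(keep) == len(t):
        return cycle
    idx = np.asarray(keep)
    return cycle.replace(times=t[idx], pressures=cycle.pressures[idx])


def trim_after_max(cycle: Cycle, config: OrganismConfig) -> Cycle | None:
    """``move_max`` trim: erase the peak and the ``move_max`` points after it.

    With ``move_max = 0`` the cycle is untouched.  Returns ``None`` (cycle
    dropped) when fewer than two points would remain.
    """
    m = config.move_max
    if m == 0:
        return cycle
    if cycle.n_points - (m + 1) < 2:
        log.warning("cycle %d too short for move_max trim; dropped", cycle.index)
        return None
    return cycle.replace(times=cycle.times[m + 1:], pressures=cycle.pressures[m + 1:])


def smooth(series: np.ndarray, window: int) -> np.ndarray:
    """Centred moving mean of odd-or-even width ``window``.

    The window shrinks at the edges (no padding, no invented data); the
    output has the input's length.  ``window = 1`` is the identity.
    """
    if window < 1:
        raise ValueError(f"smoothing window must be >= 1, got {window}")
    if window == 1:
        return np.asarray(series, dtype=float)
    return (
        pd.Series(np.asarray(series, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def preprocess(trace: PressureTrace, config: OrganismConfig, *,
               apply_smoothing: bool = True,
               keep_short: bool = False,
               keep_inactive: bool = False) -> list[Cycle]:
    """Run the full trimming pipeline (i)->(v), move_max, then smoothing.

    Returns clean cycles re-indexed 1..n in chronological order.  The debug
    switches disable individual stages for inspection; the default applies
    everything in the canonical order.
    """
    clean = filter_min_pressure(trace, config)
    cycles = segment_cycles(clean, config)
    if not keep_short:
        cycles = drop_short_cycles(cycles, config)
    if not keep_inactive:
        cycles = drop_inactive_cycles(cycles, config)
    out: list[Cycle] = []
    for c in cycles:
        c = enforce_consecutive(c, config)
        trimmed = trim_after_max(c, config)
        if trimmed is None or trimmed.n_points < 2:
            continue
        out.append(trimmed)
    if apply_smoothing and config.average > 1:
        out = [c.replace(pressures=smooth(c.pressures, config.average)) for c in out]
    return [c.replace(index=i + 1) for i, c in enumerate(out)]
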