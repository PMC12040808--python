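"""Core in-memory containers shared across the pipeline.

Internal unit conventions: pressures in mbar absolute, volumes in mL,
raw-log time in seconds since run start, derived series in hours,
amounts in mmol, biomass in g L^-1, temperatures in degrees Celsius
(converted to Kelvin only inside mole arithmetic).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PressureTrace", "BiomassObservation", "Cycle"]


@dataclass
class PressureTrace:
    """A time-stamped headspace pressure series for one cultivation bottle.

    Parameters
    ----------
    times : array of float
        Seconds since the start of the run; must be strictly increasing.
    pressures : array of float
        Absolute pressures in mbar; must be finite.
    channel : str
        Identifier of the manometer channel / bottle.
    """

    times: np.ndarray
    pressures: np.ndarray
    channel: str = "ch1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.times.shape != self.pressures.shape:
            raise ValueError(
                f"times and pressures differ in length "
                f"({self.times.size} vs {self.pressures.size})"
            )
        if self.times.ndim != 1:
            raise ValueError("trace arrays must be one-dimensional")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.pressures)):
            raise ValueError("pressures must be finite")

    def __len__(self) -> int:
        return int(self.times.size)

    def copy(self) -> "PressureTrace":
        return PressureTrace(self.times.copy(), self.pressures.copy(), self.channel)


@dataclass
class BiomassObservation:
    """An end-of-cycle optical density reading and its dry-mass conversion.

    ``x`` is the dry biomass concentration alpha_od * od578 in g L^-1; it is
    ``None`` when no OD-to-dry-mass coefficient is configured.
    """

    cycle_index: int
    od578: float
    time_h: float | None = None  # on the cultivation (in-cycle) clock
    x: float | None = None

    def __post_init__(self) -> None:
        if self.od578 < 0:
            raise ValueError(f"od578 must be >= 0, got {self.od578}")


@dataclass
class Cycle:
    """One methanation cycle: the decaying pressure segment between refills.

    Holds its own (already trimmed) slice of the parent trace.  ``index`` is
    the 1-based chronological number among retained cycles; ``start``/``stop``
    are the half-open span into the filtered parent trace the cycle was cut
    from, retained for provenance.
    """

    index: int
    times: np.ndarray  # s, strictly increasing
    pressures: np.ndarray  # mbar
    start: int = 0
    stop: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    @property
    def p_max(self) -> float:
        return float(self.pressures[0])

    @property
    def p_end(self) -> float:
        return float(self.pressures[-1])

    @property
    def pressure_drop(self) -> float:
        return self.p_max - self.p_end

    @property
    def duration_h(self) -> float:
        return float(self.times[-1] - self.times[0]) / 3600.0

    def replace(self, **kw) -> "Cycle":
        return replace(self, **kw)
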