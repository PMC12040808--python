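import numpy as np
import pytest

from gpckin.config import OrganismConfig, PRESETS
from gpckin.simulate import GassingProgram, GassingStep, SimulationTruth, default_program, simulate_run
from gpckin.types import PressureTrace


@pytest.fixture
def mm_config() -> OrganismConfig:
    """The thermophile reference parameterization (65 C, 30 mL culture)."""
    return PRESETS["M. marburgensis"]


@pytest.fixture
def small_config() -> OrganismConfig:
    """A compact configuration for hand-constructed traces."""
    return OrganismConfig(
        name="test", temperature=65.0, ph=7.0, v_culture=30.0,
        v_headspace=38.228, delta_p_cycle=1.0, alpha_od=0.4,
        calculation=5, average=1, move_max=0, min_pressure=1100.0,
        len_cycles=3, refill_threshold=200.0)


def sawtooth_trace(n_cycles=2, peak=2500.0, trough=2000.0, step=50.0, dt=10.0):
    """Rise-then-fall sawtooth: each decay runs peak -> trough in even steps."""
    p = [1013.0]
    for _ in range(n_cycles):
        p.append(peak)
        v = peak
        while v > trough:
            v = max(v - step, trough)
            p.append(v)
    t = np.arange(len(p)) * dt
    return PressureTrace(t, np.array(p), channel="sawtooth")


@pytest.fixture
def mm_run(mm_config):
    """A standard noisy growth run: 12 cycles, gas-unlimited, sampled."""
    truth = SimulationTruth(mu_true=0.55, qch4_true=170.0, x0=0.02,
                            gtr_coeff=20.0, noise_sd=5.0, seed=7)
    trace, biomass, truth = simulate_run(
        mm_config, default_program(4000.0, loops=12), truth)
    return trace, biomass, truth


def crossover_run(config, seed, noise_sd=5.0):
    """A single long decay crossing from biology- to transfer-limited."""
    cfg = config.replace(delta_p_cycle=2.5)
    prog = GassingProgram([GassingStep("flush", 4000.0, 1),
                           GassingStep("methanation", 4000.0, 1)])
    truth = SimulationTruth(mu_true=0.55, qch4_true=170.0, x0=0.02,
                            gtr_coeff=5.0, noise_sd=noise_sd, seed=seed,
                            sample_each_cycle=False, max_cycle_h=8.0)
    trace, biomass, truth = simulate_run(cfg, prog, truth)
    return cfg, trace, truth
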