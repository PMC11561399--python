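import numpy as np
import pytest

from cytoloop import EventTable, GateConfig
from cytoloop.gating import PopulationStats

CHANNELS = ("FSC-H", "SSC-H", "FL1-H", "FL3-H")


def random_event_table(rng: np.random.Generator, n: int,
                       high: float = 1e5, sample_id: str = "rnd",
                       t: float = 1.0) -> EventTable:
    events = rng.uniform(0.0, high, size=(n, 4))
    return EventTable(sample_id=sample_id, acquired_at=t,
                      dilution_factor=100.0, channels=CHANNELS,
                      events=events)


def make_stats(t: float, mfi: float, pct_pi: float,
               usable: bool = True, sample_id: str = "s") -> PopulationStats:
    """Hand-built per-sample statistics for controller-level tests."""
    return PopulationStats(
        sample_id=sample_id, t=t, n_total=1000, n_debris=100,
        n_damaged=int(round(9 * pct_pi)),
        n_intact_gfp_pos=450, n_intact_gfp_neg=450 - int(round(9 * pct_pi)),
        mfi_gfp=mfi, pct_pi=pct_pi, usable=usable)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gate_cfg():
    return GateConfig(fsc_min=100.0, fl3_threshold=1000.0,
                      fl1_threshold=500.0, min_events=1)
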