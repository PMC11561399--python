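"""Decision engine for the secondary furfural feed pump.

The biosensor MFI rises on furfural exposure and falls again as the cells
adapt; a negative three-point MFI slope therefore marks the moment more
furfural can be tolerated.  The controller starts the secondary pump at the
bottom of the rate ladder on the first such decline, escalates one ladder
step at a time when the decline persists at the current rate, and a
viability safeguard — rising %PI slope or smoothed %PI above a ceiling —
overrides everything and stops the pump.

Transitions are evaluated in strict priority order (safeguard > start >
escalate > hold) and every evaluation is bound to an audit record carrying
the exact slopes and thresholds that produced it, so the command sequence is
replayable from the log alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable

from .errors import OrderingError, ValidationError
from .gating import PopulationStats
from .trend import TrendSeries

#: decision causes
START = "induction_decline_start"
ESCALATE = "escalate"
SAFEGUARD_STOP = "safeguard_stop"
HOLD = "hold"


@dataclass(frozen=True)
class ControllerConfig:
    """Tunables of the pump state machine.

    ``rate_ladder`` is the ordered sequence of secondary-pump rates (mL/hr);
    escalation never skips a rung and the top rung is absorbing.  ``pi_max``
    is the safeguard ceiling on the smoothed percentage of PI-stained cells.
    ``dwell_samples`` usable samples must accrue at the current rate before
    an escalation is considered (anti-chatter; also the minimum needed for a
    fresh three-point slope).  With ``safeguard_latching`` the pump stays off
    permanently after a safeguard stop; by default it may restart from the
    bottom rung once the safeguard clears.
    """

    rate_ladder: tuple = (1.0, 1.5, 3.0, 5.0)
    pi_max: float = 35.0
    dwell_samples: int = 3
    safeguard_latching: bool = False
    alpha: float = 0.5
    slope_k: int = 3
    slope_on: str = "ema"
    pi_average: str = "ema"  # or "last_k_mean"

    def __post_init__(self):
        ladder = tuple(float(r) for r in self.rate_ladder)
        object.__setattr__(self, "rate_ladder", ladder)
        if not ladder or any(r <= 0 for r in ladder) or \
                any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValidationError("rate_ladder must be strictly increasing and positive")
        if not 0 < self.pi_max < 100:
            raise ValidationError("pi_max must be in (0, 100)")
        if self.dwell_samples < 1:
            raise ValidationError("dwell_samples must be >= 1")
        if self.pi_average not in ("ema", "last_k_mean"):
            raise ValidationError(f"unknown pi_average {self.pi_average!r}")


@dataclass
class PumpCommand:
    t: float
    rate: float
    cause: str


@dataclass
class AuditRecord:
    """Why the pump did what it did, at one evaluation."""

    t: float
    sample_id: str
    mfi: float | None
    mfi_ema: float | None
    mfi_slope: float | None
    pct_pi: float | None
    pct_pi_ema: float | None
    pi_slope: float | None
    pi_max: float
    cause: str
    rate: float
    samples_at_rate: int
    time_source: str = "keyword"

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


class ControllerState:
    """Mutable pump state plus the MFI and %PI trend histories."""

    def __init__(self, cfg: ControllerConfig):
        self.cfg = cfg
        self.pump_on = False
        self.ladder_index: int | None = None
        self.samples_at_rate = 0
        self.safeguard_active = False
        self.mfi_series = TrendSeries(alpha=cfg.alpha, k=cfg.slope_k,
                                      slope_on=cfg.slope_on)
        self.pi_series = TrendSeries(alpha=cfg.alpha, k=cfg.slope_k,
                                     slope_on=cfg.slope_on)

    @property
    def rate(self) -> float:
        if not self.pump_on or self.ladder_index is None:
            return 0.0
        return self.cfg.rate_ladder[self.ladder_index]

    def _pi_average(self) -> float | None:
        if self.cfg.pi_average == "ema":
            return self.pi_series.last_ema
        k = self.cfg.slope_k
        if len(self.pi_series) == 0:
            return None
        vals = self.pi_series.raw[-k:]
        return sum(vals) / len(vals)


def evaluate(state: ControllerState, new_stats: PopulationStats,
             cfg: ControllerConfig | None = None
             ) -> tuple[ControllerState, PumpCommand, AuditRecord]:
    """Fold one usable sample into the state and emit the pump command.

    Priority order: (1) safeguard — positive %PI slope or smoothed %PI above
    the ceiling forces rate 0; (2) start — pump off and MFI slope strictly
    negative starts the bottom rung; (3) escalate — dwell met, slope still
    negative, not at the top; (4) hold.  Undefined slopes always resolve to
    hold, so no action is possible until a full slope window exists.
    """
    cfg = cfg or state.cfg
    if not new_stats.usable:
        raise ValidationError(
            f"sample {new_stats.sample_id!r} is unusable; caller must skip it")

    state.mfi_series.append(new_stats.t, new_stats.mfi_gfp
                            if new_stats.mfi_gfp is not None else 0.0)
    state.pi_series.append(new_stats.t, new_stats.pct_pi
                           if new_stats.pct_pi is not None else 0.0)

    mfi_slope = state.mfi_series.slope_last_k()
    pi_slope = state.pi_series.slope_last_k()
    pi_avg = state._pi_average()

    safeguard = (pi_slope is not None and pi_slope > 0) or \
                (pi_avg is not None and pi_avg > cfg.pi_max)

    if safeguard:
        state.pump_on = False
        state.ladder_index = None
        state.samples_at_rate = 0
        state.safeguard_active = True
        cause = SAFEGUARD_STOP
    else:
        if state.safeguard_active and not cfg.safeguard_latching:
            state.safeguard_active = False
        decline = mfi_slope is not None and mfi_slope < 0
        if (not state.pump_on and not state.safeguard_active and decline):
            state.pump_on = True
            state.ladder_index = 0
            state.samples_at_rate = 0
            cause = START
        elif (state.pump_on and decline
                and state.samples_at_rate >= cfg.dwell_samples
                and state.ladder_index is not None
                and state.ladder_index < len(cfg.rate_ladder) - 1):
            state.ladder_index += 1
            state.samples_at_rate = 0
            cause = ESCALATE
        else:
            state.samples_at_rate += 1
            cause = HOLD

    command = PumpCommand(t=new_stats.t, rate=state.rate, cause=cause)
    audit = AuditRecord(
        t=new_stats.t,
        sample_id=new_stats.sample_id,
        mfi=new_stats.mfi_gfp,
        mfi_ema=state.mfi_series.last_ema,
        mfi_slope=mfi_slope,
        pct_pi=new_stats.pct_pi,
        pct_pi_ema=pi_avg,
        pi_slope=pi_slope,
        pi_max=cfg.pi_max,
        cause=cause,
        rate=command.rate,
        samples_at_rate=state.samples_at_rate,
    )
    return state, command, audit


def run_session(stats_stream: Iterable[PopulationStats],
                cfg: ControllerConfig | None = None,
                state: ControllerState | None = None
                ) -> tuple[list[PumpCommand], list[AuditRecord]]:
    """Fold :func:`evaluate` over an ordered stats stream.

    Unusable samples are skipped (they still check the time ordering but add
    neither a trend point nor a command).  Replaying the returned audit
    records reproduces the command sequence exactly.
    """
    cfg = cfg or ControllerConfig()
    state = state or ControllerState(cfg)
    commands: list[PumpCommand] = []
    audits: list[AuditRecord] = []
    last_t = None
    for stats in stats_stream:
        if last_t is not None and stats.t <= last_t:
            raise OrderingError(
                f"stats at t={stats.t} not after previous t={last_t}")
        last_t = stats.t
        if not stats.usable:
            continue
        state, cmd, audit = evaluate(state, stats, cfg)
        commands.append(cmd)
        audits.append(audit)
    return commands, audits
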