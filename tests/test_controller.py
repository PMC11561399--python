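"""Pump state machine: priority order, ladder discipline, safeguard safety."""

import itertools

import numpy as np
import pytest

from cytoloop import (ControllerConfig, ControllerState, MockActuator,
                      SerialActuator, evaluate, run_session)
from cytoloop.controller import ESCALATE, HOLD, SAFEGUARD_STOP, START
from cytoloop.errors import ActuatorAlarm, OrderingError, ValidationError

from conftest import make_stats

LADDER = (1.0, 1.5, 3.0, 5.0)


def feed(state, cfg, points):
    """Evaluate a sequence of (t, mfi, pct_pi) through the controller."""
    out = []
    for t, mfi, pct in points:
        state, cmd, audit = evaluate(state, make_stats(t, mfi, pct), cfg)
        out.append((cmd, audit))
    return state, out


class TestScenarios:
    def test_start_at_bottom_rung_on_first_decline(self):
        cfg = ControllerConfig()
        state = ControllerState(cfg)
        pts = [(0.5, 100, 10), (1.0, 300, 10), (1.5, 600, 10),
               (2.0, 500, 10), (2.5, 380, 10), (3.0, 250, 9)]
        state, results = feed(state, cfg, pts)
        causes = [c.cause for c, _ in results]
        assert causes.count(START) == 1
        first = causes.index(START)
        assert results[first][0].rate == 1.0
        assert all(c.rate == 0 for c, _ in results[:first])

    def test_escalation_walks_ladder_without_skips_and_holds_at_top(self):
        cfg = ControllerConfig(dwell_samples=1)
        state = ControllerState(cfg)
        # strictly decreasing MFI forever: start, then escalate each time
        # the dwell (1 usable sample at the rate) has elapsed
        pts = [(0.5 * i, 1000 - 40 * i, 10) for i in range(1, 16)]
        state, results = feed(state, cfg, pts)
        rates = [c.rate for c, _ in results if c.rate > 0]
        assert sorted(set(rates)) == list(LADDER)
        # never skips a rung on the way up
        idx = [LADDER.index(r) for r in rates]
        assert all(b - a in (0, 1) for a, b in zip(idx, idx[1:]))
        assert rates[-1] == 5.0  # top rung is absorbing

    def test_safeguard_ceiling_stops_regardless_of_mfi(self):
        cfg = ControllerConfig(dwell_samples=1)
        state = ControllerState(cfg)
        state, results = feed(state, cfg, [
            (0.5, 900, 10), (1.0, 800, 10), (1.5, 700, 10),   # start
            (2.0, 600, 9), (2.5, 500, 8)])                    # escalating
        assert results[-1][0].rate > 0
        # %PI jumps: EMA (0.5*60 + 0.5*~8.5) > 35 -> stop
        state, results = feed(state, cfg, [(3.0, 400, 70)])
        assert results[0][0].cause == SAFEGUARD_STOP
        assert results[0][0].rate == 0.0

    def test_no_action_before_three_usable_samples(self):
        cfg = ControllerConfig()
        state = ControllerState(cfg)
        state, results = feed(state, cfg, [(0.5, 100, 5), (1.0, 90, 5)])
        assert all(c.cause == HOLD and c.rate == 0 for c, _ in results)

    def test_restart_after_safeguard_clears_is_at_bottom_rung(self):
        cfg = ControllerConfig(dwell_samples=1)
        state = ControllerState(cfg)
        state, _ = feed(state, cfg, [
            (0.5, 900, 10), (1.0, 800, 10), (1.5, 700, 10),
            (2.0, 600, 10), (2.5, 500, 10)])   # at 1.5 mL/hr by now
        state, res = feed(state, cfg, [(3.0, 450, 80)])
        assert res[0][0].cause == SAFEGUARD_STOP
        # PI falls back: slope becomes negative, EMA sinks below ceiling
        state, res = feed(state, cfg, [(3.5, 400, 2), (4.0, 380, 1),
                                       (4.5, 360, 1)])
        restart = [c for c, _ in res if c.cause == START]
        assert restart and restart[0].rate == 1.0

    def test_latching_safeguard_never_restarts(self):
        cfg = ControllerConfig(safeguard_latching=True)
        state = ControllerState(cfg)
        pts = [(0.5, 900, 10), (1.0, 800, 80), (1.5, 700, 2),
               (2.0, 600, 1), (2.5, 500, 1), (3.0, 400, 1)]
        state, results = feed(state, cfg, pts)
        assert all(c.cause != START for c, _ in results)
        assert all(c.rate == 0 for c, _ in results)


def expected_transition(pump_on, mfi_sign, pi_sign, pi_above,
                        dwell_met, at_top):
    """Independent statement of the decision flow chart."""
    if pi_sign == "+" or pi_above:
        return SAFEGUARD_STOP
    if mfi_sign == "u":
        return HOLD
    if not pump_on and mfi_sign == "-":
        return START
    if pump_on and mfi_sign == "-" and dwell_met and not at_top:
        return ESCALATE
    return HOLD


MFI_PRIOR = {"-": (30.0, 20.0), "0": (10.0, 10.0), "+": (5.0, 7.0)}
MFI_NEW = {"-": 10.0, "0": 10.0, "+": 9.0}
PI_PRIOR = {("-", False): (12.0, 11.0), ("0", False): (10.0, 10.0),
            ("+", False): (8.0, 9.0), ("-", True): (50.0, 45.0),
            ("0", True): (40.0, 40.0), ("+", True): (36.0, 38.0)}
PI_NEW = {("-", False): 10.0, ("0", False): 10.0, ("+", False): 10.0,
          ("-", True): 40.0, ("0", True): 40.0, ("+", True): 40.0}


class TestTruthTable:
    @pytest.mark.parametrize(
        "pump_on,mfi_sign,pi_sign,pi_above,dwell_met,at_top",
        list(itertools.product([False, True], "-0+", "-0+",
                               [False, True], [False, True], [False, True])))
    def test_every_cell_matches_flow_chart(self, pump_on, mfi_sign, pi_sign,
                                           pi_above, dwell_met, at_top):
        cfg = ControllerConfig(alpha=1.0)  # EMA == raw: exact slope control
        state = ControllerState(cfg)
        for t, (m, p) in zip((0.0, 0.5),
                             zip(MFI_PRIOR[mfi_sign],
                                 PI_PRIOR[(pi_sign, pi_above)])):
            state.mfi_series.append(t, m)
            state.pi_series.append(t, p)
        state.pump_on = pump_on
        state.ladder_index = (len(LADDER) - 1 if at_top else 0) if pump_on \
            else None
        state.samples_at_rate = cfg.dwell_samples if dwell_met else 0

        stats = make_stats(1.0, MFI_NEW[mfi_sign],
                           PI_NEW[(pi_sign, pi_above)])
        state, cmd, audit = evaluate(state, stats, cfg)
        want = expected_transition(pump_on, mfi_sign, pi_sign, pi_above,
                                   dwell_met, at_top)
        assert cmd.cause == want
        if want == SAFEGUARD_STOP:
            assert cmd.rate == 0.0
        if want == START:
            assert cmd.rate == LADDER[0]
        if want == ESCALATE:
            assert cmd.rate == LADDER[1]

    @pytest.mark.parametrize("pi_above", [False, True])
    def test_undefined_slopes_resolve_to_hold_unless_ceiling_hit(self, pi_above):
        cfg = ControllerConfig(alpha=1.0)
        state = ControllerState(cfg)
        state.mfi_series.append(0.0, 100.0)
        state.pi_series.append(0.0, 40.0 if pi_above else 10.0)
        stats = make_stats(0.5, 50.0, 40.0 if pi_above else 10.0)
        state, cmd, _ = evaluate(state, stats, cfg)
        assert cmd.cause == (SAFEGUARD_STOP if pi_above else HOLD)
        assert cmd.rate == 0.0

    def test_priority_safeguard_beats_start(self):
        cfg = ControllerConfig(alpha=1.0)
        state = ControllerState(cfg)
        # MFI slope strictly negative AND %PI above ceiling simultaneously
        pts = [(0.5, 900, 40), (1.0, 800, 40), (1.5, 700, 40)]
        state, results = feed(state, cfg, pts)
        assert results[-1][0].cause == SAFEGUARD_STOP
        assert all(c.cause != START for c, _ in results)


def random_stream(rng, n=8):
    mfi = 1000.0
    out = []
    for i in range(n):
        mfi = max(mfi + rng.normal(0, 200), 1.0)
        out.append(make_stats(0.5 * (i + 1), mfi, rng.uniform(0, 60),
                              usable=rng.random() > 0.1,
                              sample_id=f"s{i}"))
    return out


class TestInvariantsFuzz:
    def test_safety_and_ladder_on_random_streams(self):
        rng = np.random.default_rng(7)
        cfg = ControllerConfig()
        for _ in range(300):
            stream = random_stream(rng)
            commands, audits = run_session(stream, cfg)
            for cmd, audit in zip(commands, audits):
                if audit.pct_pi_ema is not None and \
                        audit.pct_pi_ema > cfg.pi_max:
                    assert cmd.rate == 0.0
                if audit.pi_slope is not None and audit.pi_slope > 0:
                    assert cmd.rate == 0.0
                assert cmd.rate in (0.0,) + cfg.rate_ladder
            idx = [LADDER.index(c.rate) if c.rate else -1 for c in commands]
            prev = -1
            for i in idx:
                if i >= 0:
                    assert i == 0 if prev < 0 else i - prev in (0, 1)
                prev = i

    def test_identical_streams_give_byte_identical_audit_logs(self):
        cfg = ControllerConfig()
        stream = random_stream(np.random.default_rng(42), n=20)
        _, a1 = run_session(stream, cfg)
        _, a2 = run_session(stream, cfg)
        assert "\n".join(r.to_json() for r in a1) == \
            "\n".join(r.to_json() for r in a2)


class TestRunSession:
    def test_monotone_rise_never_triggers(self):
        stream = [make_stats(0.5 * i, 100.0 * i, 5.0) for i in range(1, 11)]
        commands, _ = run_session(stream)
        assert all(c.cause == HOLD for c in commands)

    def test_rise_then_fall_starts_exactly_once_at_first_negative_slope(self):
        mfi = [100, 400, 900, 1500, 2200, 3000, 2500, 1800, 1200]
        stream = [make_stats(0.5 * (i + 1), m, 5.0)
                  for i, m in enumerate(mfi)]
        commands, audits = run_session(stream)

        # hand-simulation: EMA recursion then 3-point OLS slope sign
        ema = []
        for x in mfi:
            ema.append(x if not ema else 0.5 * x + 0.5 * ema[-1])
        first_neg = next(i for i in range(2, len(ema))
                         if (ema[i] - ema[i - 2]) < 0)
        causes = [c.cause for c in commands]
        assert causes.count(START) == 1
        assert causes.index(START) == first_neg

    def test_empty_stream_gives_empty_outputs(self):
        commands, audits = run_session([])
        assert commands == [] and audits == []

    def test_out_of_order_stats_raise(self):
        stream = [make_stats(1.0, 10, 5), make_stats(0.5, 20, 5)]
        with pytest.raises(OrderingError):
            run_session(stream)

    def test_unusable_samples_are_skipped_not_counted(self):
        stream = [make_stats(0.5, 100, 5), make_stats(1.0, 90, 5, usable=False),
                  make_stats(1.5, 80, 5)]
        commands, audits = run_session(stream)
        assert len(commands) == 2
        assert [a.t for a in audits] == [0.5, 1.5]

    def test_unusable_sample_rejected_by_evaluate(self):
        cfg = ControllerConfig()
        with pytest.raises(ValidationError):
            evaluate(ControllerState(cfg), make_stats(1.0, 5, 5, usable=False),
                     cfg)


class _Transport:
    def __init__(self, ok_after=0):
        self.ok_after = ok_after
        self.written = []

    def write(self, b):
        self.written.append(b)
        return len(b)

    def readline(self):
        if len(self.written) > self.ok_after:
            return b"OK\n"
        return b""  # timeout


class TestActuators:
    def test_mock_records_commands(self):
        from cytoloop.controller import PumpCommand
        act = MockActuator()
        act.send(PumpCommand(1.0, 1.5, "escalate"))
        act.stop()
        assert act.rates == [1.5, 0.0]

    def test_serial_protocol_line_and_ack(self):
        from cytoloop.controller import PumpCommand
        tr = _Transport()
        SerialActuator(tr).send(PumpCommand(1.0, 1.5, "escalate"))
        assert tr.written == [b"RATE 1.5\n"]

    def test_serial_retries_once_then_succeeds(self):
        from cytoloop.controller import PumpCommand
        tr = _Transport(ok_after=1)
        SerialActuator(tr).send(PumpCommand(1.0, 3.0, "escalate"))
        assert len(tr.written) == 2

    def test_serial_alarms_after_retry_exhausted(self):
        from cytoloop.controller import PumpCommand
        tr = _Transport(ok_after=99)
        with pytest.raises(ActuatorAlarm):
            SerialActuator(tr).send(PumpCommand(1.0, 3.0, "escalate"))
        assert len(tr.written) == 2
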