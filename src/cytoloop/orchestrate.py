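"""Workflow glue: live control, offline analysis, in-silico experiments.

Each workflow is a plain function over :class:`~cytoloop.config.RunConfig`
so it is scriptable without the CLI; the CLI commands are thin wrappers.
"""

from __future__ import annotations

import logging
import shutil
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .actuator import Actuator, MockActuator
from .config import RunConfig
from .controller import PumpCommand, evaluate
from .errors import CytoloopError
from .fcs_io import discover_new_samples, read_fcs
from .gating import gate_sample
from .persist import (append_audit, append_stats, resume_controller_state,
                      stats_row, write_stats_header)
from . import simulator

log = logging.getLogger("cytoloop")


def _process_file(path: Path, cfg: RunConfig, state):
    table = read_fcs(path, channel_map=cfg.channel_map or None)
    stats = gate_sample(table, cfg.gate)
    return table, stats


def analyze_directory(cfg: RunConfig, in_dir: Path | None = None,
                      histograms: bool = False) -> pd.DataFrame:
    """Batch pipeline over a directory of FCS files; no actuation.

    Emits the stats CSV (with trend columns) and, optionally, per-sample
    FL1-H histogram tables alongside it.  Deterministic: re-running over the
    same directory reproduces the CSV byte for byte.
    """
    in_dir = Path(in_dir or cfg.watch_dir)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    cfg.stats_csv.parent.mkdir(parents=True, exist_ok=True)
    cfg.stats_csv.write_text("")
    write_stats_header(cfg.stats_csv)

    from .controller import ControllerState
    state = ControllerState(cfg.controller)
    for path in discover_new_samples(in_dir):
        table, stats = _process_file(path, cfg, state)
        if stats.usable:
            state.mfi_series.append(stats.t, stats.mfi_gfp or 0.0)
            state.pi_series.append(stats.t, stats.pct_pi or 0.0)
        append_stats(cfg.stats_csv, stats_row(stats, state))
        if histograms:
            fl1 = table.column("FL1-H")
            counts, edges = np.histogram(np.log10(np.maximum(fl1, 1.0)),
                                         bins=64, range=(0, 7))
            pd.DataFrame({"log10_fl1_left": edges[:-1], "count": counts}).to_csv(
                cfg.out_dir / f"hist_{path.stem}.csv", index=False)
    return pd.read_csv(cfg.stats_csv) if cfg.stats_csv.stat().st_size else \
        pd.DataFrame()


def control_loop(cfg: RunConfig, actuator: Actuator | None = None,
                 max_polls: int | None = None,
                 poll_interval: float | None = None) -> list[PumpCommand]:
    """Poll the watch directory and drive the pump; the live workflow.

    For each new FCS file: read -> gate -> trend -> evaluate -> actuate,
    appending to the stats CSV and audit log.  Malformed files are moved to
    a ``quarantine/`` subdirectory and the loop continues.  On shutdown
    (KeyboardInterrupt or ``max_polls`` reached) the pump is commanded to 0
    and that final command is audited, so the process never exits with the
    pump running.

    Restarting against an existing stats CSV resumes the trend state from
    the persisted EMA columns.
    """
    actuator = actuator or MockActuator()
    interval = cfg.poll_interval if poll_interval is None else poll_interval
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    cfg.stats_csv.parent.mkdir(parents=True, exist_ok=True)
    quarantine = cfg.watch_dir / "quarantine"
    write_stats_header(cfg.stats_csv)

    state = resume_controller_state(cfg.stats_csv, cfg.controller,
                                    cfg.audit_log)
    # names of files handled in previous sessions, so a restart neither
    # re-actuates nor double-counts them
    processed_log = cfg.out_dir / "processed.txt"
    seen: set = set()
    if processed_log.exists():
        seen = {cfg.watch_dir / name
                for name in processed_log.read_text().split()
                if (cfg.watch_dir / name).exists()}
    commands: list[PumpCommand] = []
    polls = 0
    try:
        while True:
            for path in discover_new_samples(cfg.watch_dir, seen):
                seen.add(path)
                with open(processed_log, "a") as fh:
                    fh.write(path.name + "\n")
                try:
                    table, stats = _process_file(path, cfg, state)
                except (CytoloopError, ValueError) as exc:
                    quarantine.mkdir(exist_ok=True)
                    shutil.move(str(path), quarantine / path.name)
                    log.warning("quarantined %s: %s", path.name, exc)
                    continue
                if stats.usable:
                    state, cmd, audit = evaluate(state, stats, cfg.controller)
                    append_stats(cfg.stats_csv, stats_row(stats, state))
                    append_audit(cfg.audit_log, audit)
                    try:
                        actuator.send(cmd)
                    except CytoloopError as exc:
                        log.error("actuator alarm: %s; assuming pump stopped",
                                  exc)
                    commands.append(cmd)
                else:
                    append_stats(cfg.stats_csv, stats_row(stats, state))
                    log.info("skipped unusable sample %s", stats.sample_id)
            polls += 1
            if max_polls is not None and polls >= max_polls:
                break
            time.sleep(interval)
    except KeyboardInterrupt:
        log.info("shutdown signal received")
    finally:
        final = PumpCommand(t=state.mfi_series.times[-1]
                            if len(state.mfi_series) else 0.0,
                            rate=0.0, cause="shutdown")
        try:
            actuator.send(final)
        except CytoloopError:
            pass
        commands.append(final)
        from .controller import AuditRecord
        append_audit(cfg.audit_log, AuditRecord(
            t=final.t, sample_id="<shutdown>", mfi=None, mfi_ema=None,
            mfi_slope=None, pct_pi=None, pct_pi_ema=None, pi_slope=None,
            pi_max=cfg.controller.pi_max, cause="shutdown", rate=0.0,
            samples_at_rate=state.samples_at_rate))
    return commands


def simulate(cfg: RunConfig, duration: float = 30.0, mode: str = "controlled",
             seed: int | None = None, write_fcs_files: bool = True
             ) -> simulator.SimResult:
    """Front end to :func:`cytoloop.simulator.run_closed_loop`.

    Writes the trajectory CSV, stats CSV, audit log and (optionally) the
    synthesized FCS directory under ``cfg.out_dir``.
    """
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    result = simulator.run_closed_loop(
        p=cfg.sim, cfg=cfg.controller, gate=cfg.gate, duration=duration,
        mode=mode, seed=seed,
        outdir=cfg.out_dir / "fcs" if write_fcs_files else None)
    result.trajectory.to_csv(cfg.out_dir / "trajectory.csv", index=False)
    result.stats_frame().to_csv(cfg.stats_csv, index=False)
    with open(cfg.audit_log, "w") as fh:
        for a in result.audits:
            fh.write(a.to_json() + "\n")
    return result
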