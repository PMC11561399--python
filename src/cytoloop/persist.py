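"""Monitoring artifacts: the stats CSV time series and the JSON-lines audit log.

The stats CSV is append-only, one row per sample, and also persists the EMA
state (``mfi_ema``, ``pi_ema`` columns) so a restarted control session can
resume the trend exactly instead of recomputing it from raw values.  The
audit log is the single source of truth for "why did the pump change".
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import pandas as pd

from .controller import AuditRecord, ControllerConfig, ControllerState
from .gating import PopulationStats

STATS_COLUMNS = [
    "t", "sample_id", "n_total", "n_debris", "n_damaged",
    "n_intact_gfp_pos", "n_intact_gfp_neg", "mfi_gfp", "pct_pi", "usable",
    "mfi_ema", "mfi_slope", "pi_ema", "pi_slope",
]


def stats_row(stats: PopulationStats, state: ControllerState | None = None) -> dict:
    row = {
        "t": stats.t, "sample_id": stats.sample_id,
        "n_total": stats.n_total, "n_debris": stats.n_debris,
        "n_damaged": stats.n_damaged,
        "n_intact_gfp_pos": stats.n_intact_gfp_pos,
        "n_intact_gfp_neg": stats.n_intact_gfp_neg,
        "mfi_gfp": stats.mfi_gfp, "pct_pi": stats.pct_pi,
        "usable": int(stats.usable),
        "mfi_ema": "", "mfi_slope": "", "pi_ema": "", "pi_slope": "",
    }
    if state is not None and stats.usable and len(state.mfi_series):
        row["mfi_ema"] = state.mfi_series.last_ema
        row["pi_ema"] = state.pi_series.last_ema
        ms = state.mfi_series.slope_last_k()
        ps = state.pi_series.slope_last_k()
        row["mfi_slope"] = "" if ms is None else ms
        row["pi_slope"] = "" if ps is None else ps
    return row


def append_stats(path: Path, row: dict) -> None:
    path = Path(path)
    new = not path.exists() or path.stat().st_size == 0
    with open(path, "a", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=STATS_COLUMNS)
        if new:
            writer.writeheader()
        writer.writerow({k: ("" if row.get(k) is None else row.get(k, ""))
                         for k in STATS_COLUMNS})


def write_stats_header(path: Path) -> None:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        with open(path, "w", newline="") as fh:
            csv.DictWriter(fh, fieldnames=STATS_COLUMNS).writeheader()


def stats_to_frame(stats_list) -> pd.DataFrame:
    return pd.DataFrame([stats_row(s) for s in stats_list],
                        columns=STATS_COLUMNS)


def append_audit(path: Path, record: AuditRecord) -> None:
    with open(path, "a") as fh:
        fh.write(record.to_json() + "\n")


def read_audit(path: Path) -> list[dict]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out


def resume_controller_state(stats_csv: Path, cfg: ControllerConfig,
                            audit_log: Path | None = None) -> ControllerState:
    """Rebuild controller + trend state from persisted artifacts.

    The EMA is reconstructed from the persisted ``*_ema`` columns (not
    recomputed from raw values, so resuming is exact even if alpha changed
    historically).  Pump state is recovered from the last audit record when
    an audit log is available.
    """
    state = ControllerState(cfg)
    path = Path(stats_csv)
    if path.exists() and path.stat().st_size > 0:
        df = pd.read_csv(path)
        usable = df[df["usable"] == 1]
        for _, r in usable.iterrows():
            state.mfi_series.times.append(float(r["t"]))
            state.mfi_series.raw.append(float(r["mfi_gfp"]))
            state.mfi_series.ema.append(float(r["mfi_ema"]))
            state.pi_series.times.append(float(r["t"]))
            state.pi_series.raw.append(float(r["pct_pi"]))
            state.pi_series.ema.append(float(r["pi_ema"]))
    if audit_log is not None and Path(audit_log).exists():
        records = read_audit(Path(audit_log))
        if records:
            last = records[-1]
            rate = float(last["rate"])
            state.pump_on = rate > 0
            state.safeguard_active = (last["cause"] == "safeguard_stop"
                                      and cfg.safeguard_latching)
            if state.pump_on:
                ladder = list(cfg.rate_ladder)
                state.ladder_index = ladder.index(rate) if rate in ladder else 0
            state.samples_at_rate = int(last.get("samples_at_rate", 0))
    return state
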