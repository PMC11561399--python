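"""Plain-text run configuration (INI-style sectioned ``key = value``).

Sections: ``[paths]``, ``[gate]``, ``[controller]``, ``[trend]``, ``[sim]``,
``[actuator]``, ``[run]``.  Every key is optional; omitted keys take the
package defaults, so a minimal config can be a single section or even empty.
"""

from __future__ import annotations

import configparser
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .controller import ControllerConfig
from .errors import ValidationError
from .gating import GateConfig
from .simulator import SimParams


@dataclass
class RunConfig:
    gate: GateConfig = field(default_factory=GateConfig)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    sim: SimParams = field(default_factory=SimParams)
    watch_dir: Path = Path("fcs_in")
    out_dir: Path = Path("out")
    stats_csv: Path = Path("out/stats.csv")
    audit_log: Path = Path("out/audit.jsonl")
    actuator: str = "mock"        # mock | serial
    serial_port: str = ""
    serial_timeout: float = 2.0
    poll_interval: float = 60.0   # seconds
    channel_map: dict = field(default_factory=dict)


def _coerce(raw: str, like):
    if isinstance(like, bool):
        return raw.strip().lower() in ("1", "true", "yes", "on")
    if isinstance(like, int) and not isinstance(like, bool):
        return int(raw)
    if isinstance(like, float):
        return float(raw)
    if isinstance(like, tuple):
        return tuple(float(x) for x in raw.replace(",", " ").split())
    return raw


def _build(dc_type, section) -> object:
    defaults = dc_type()
    kwargs = {}
    names = {f.name for f in dataclasses.fields(dc_type)}
    for key in section:
        if key not in names:
            raise ValidationError(
                f"unknown key {key!r} in [{section.name}] "
                f"(valid: {', '.join(sorted(names))})")
        kwargs[key] = _coerce(section[key], getattr(defaults, key))
    return dc_type(**kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    cfg = RunConfig()
    if path is None:
        return cfg
    parser = configparser.ConfigParser(inline_comment_prefixes=("#", ";"))
    parser.optionxform = str  # keep case: SimParams fields like Ks_glc, F0
    read = parser.read(str(path))
    if not read:
        raise ValidationError(f"config file not found: {path}")

    if parser.has_section("gate"):
        cfg.gate = _build(GateConfig, parser["gate"])
    if parser.has_section("controller"):
        cfg.controller = _build(ControllerConfig, parser["controller"])
    if parser.has_section("sim"):
        cfg.sim = _build(SimParams, parser["sim"])
    if parser.has_section("trend"):
        # trend knobs live on the controller config (shared alpha/k)
        tr = parser["trend"]
        updates = {}
        for key in tr:
            if key not in ("alpha", "k", "slope_on"):
                raise ValidationError(f"unknown key {key!r} in [trend]")
            if key == "k":
                updates["slope_k"] = int(tr[key])
            elif key == "alpha":
                updates["alpha"] = float(tr[key])
            else:
                updates["slope_on"] = tr[key]
        cfg.controller = dataclasses.replace(cfg.controller, **updates)
    if parser.has_section("paths"):
        sec = parser["paths"]
        cfg.watch_dir = Path(sec.get("watch_dir", str(cfg.watch_dir)))
        cfg.out_dir = Path(sec.get("out_dir", str(cfg.out_dir)))
        cfg.stats_csv = Path(sec.get("stats_csv", str(cfg.out_dir / "stats.csv")))
        cfg.audit_log = Path(sec.get("audit_log", str(cfg.out_dir / "audit.jsonl")))
    if parser.has_section("actuator"):
        sec = parser["actuator"]
        cfg.actuator = sec.get("kind", cfg.actuator)
        cfg.serial_port = sec.get("port", cfg.serial_port)
        cfg.serial_timeout = float(sec.get("timeout", cfg.serial_timeout))
        if cfg.actuator not in ("mock", "serial"):
            raise ValidationError(f"unknown actuator kind {cfg.actuator!r}")
    if parser.has_section("run"):
        cfg.poll_interval = float(parser["run"].get(
            "poll_interval", cfg.poll_interval))
    if parser.has_section("channel_map"):
        cfg.channel_map = dict(parser["channel_map"])
    return cfg
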