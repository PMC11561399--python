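"""Closed-loop fed-batch cultivation simulator.

Stands in for the shake flask, the yeast, and the cytometer: a
phenomenological ODE model of biomass growth, furfural detoxification,
biosensor induction/adaptation and membrane damage, integrated with
fixed-step RK4, plus event-level synthesis of FCS samples so the whole
gate -> trend -> controller chain can be exercised through the same file
interface a real instrument would feed.

Model (all concentrations g/L, volume L, time h; F = inflow L/h):

* dilution by feed:      d = F / V,  dV/dt = F  (no outflow)
* diauxic Monod growth:  mu_g = mu_max Sg/(Ks_glc+Sg);
  xylose uptake is glucose-repressed, mu_x = mu_max_xyl Sx/(Ks_xyl+Sx)
  * K_rep/(K_rep+Sg)
* furfural:  dCf/dt = inflow/V - d*Cf - q_eff * X * Cf/(Cf+K_f), where the
  effective specific detox rate q_eff = q_detox * (a0 + (1-a0) * A) grows
  with adaptation (adapted cells detoxify more per gram)
* adaptation (dimensionless, 0..1):  dA/dt = k_adapt * 1[Cf>0] * (1-A)
* biosensor fluorescence, driven by the unadapted stress signal
  s = Cf (1-A):  dFl/dt = k_ind * s - k_relax * (Fl - F0)
* damaged fraction, also stress-driven (adapted cells resist damage)
  plus a small furfural-independent background:
  dD/dt = (k_dam * s + k_dam_bg) * (1-D) - k_rec * D

The transient single peak of the fluorescence trajectory under a fixed
feed, its re-induction when extra furfural is added after adaptation, and
the early damage peak (~30-40% near 3 h) relaxing to a ~10% plateau are
emergent from these equations with the default constants; the constants
are phenomenological calibrations, not measured quantities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .controller import (AuditRecord, ControllerConfig, ControllerState,
                         PumpCommand, evaluate)
from .errors import IntegrityError, ValidationError
from .fcs_io import EventTable, read_fcs, write_fcs
from .gating import GateConfig, PopulationStats, gate_sample

ML_PER_L = 1000.0


@dataclass(frozen=True)
class SimParams:
    """Rate constants, feed composition and acquisition model.

    Feed facts mirror the bench setup: primary feed fixed at 6.24 mL/hr
    carrying 20 g/L glucose, 20 g/L xylose and 6.9 g/L furfural; the
    secondary feed carries 50 g/L furfural only.  Kinetic and noise
    constants are phenomenological (see module docstring).
    """

    # growth
    mu_max: float = 0.22          # 1/h, on glucose
    mu_max_xyl: float = 0.05      # 1/h, on xylose (repressed by glucose)
    Ks_glc: float = 0.5           # g/L
    Ks_xyl: float = 1.0           # g/L
    K_rep: float = 0.1            # g/L, glucose repression of xylose uptake
    Yxs: float = 0.11             # g CDW / g sugar

    # furfural detoxification: the effective specific rate scales from a
    # basal fraction up to q_detox as the culture adapts (adaptation is an
    # upregulated NADPH supply, i.e. more reduction capacity)
    q_detox: float = 0.45         # g furfural / g CDW / h, fully adapted
    detox_base_frac: float = 0.10  # fraction of q_detox available at A = 0
    K_f: float = 0.5              # g/L, detox saturation

    # biosensor
    k_ind: float = 23000.0        # (intensity/h) per (g/L furfural)
    k_relax: float = 0.70         # 1/h
    F0: float = 500.0             # basal fluorescence, intensity units
    k_adapt: float = 0.15         # 1/h

    # membrane damage
    k_dam: float = 0.36           # (fraction/h) per (g/L) unadapted stress
    k_rec: float = 0.30           # 1/h
    k_dam_bg: float = 0.025       # 1/h, furfural-independent background damage

    # feeds
    primary_rate: float = 6.24    # mL/hr
    feed_glc: float = 20.0        # g/L
    feed_xyl: float = 20.0        # g/L
    feed_fur: float = 6.9         # g/L
    secondary_fur: float = 50.0   # g/L

    # batch phase (before feed start; time is re-zeroed at feed start)
    V0: float = 0.050             # L
    X0: float = 0.05              # g CDW/L at inoculation
    batch_glc: float = 40.0       # g/L
    batch_xyl: float = 40.0       # g/L
    glc_depleted: float = 0.1     # g/L, batch-end / diauxie threshold

    # acquisition / event synthesis
    events_per_sample: int = 5000
    debris_frac: float = 0.15
    cv_fl1: float = 0.35
    cv_fl3: float = 0.40
    cv_scatter: float = 0.30
    fsc_yeast: float = 50_000.0
    fsc_debris: float = 2_000.0
    ssc_yeast: float = 20_000.0
    ssc_debris: float = 1_000.0
    fl3_damaged: float = 5_000.0
    fl3_intact: float = 50.0
    dilution_ladder: tuple = (10.0, 100.0, 1000.0)
    acq_events_per_g: float = 1.25e6   # predicted events per g CDW sampled, undiluted
    dilution_band: float = 1.5         # upper band = band * events_per_sample

    # integration
    dt: float = 0.01              # h
    seed: int = 0

    def __post_init__(self):
        numeric = {f.name: getattr(self, f.name)
                   for f in dataclasses.fields(self)
                   if f.name not in ("dilution_ladder", "seed")}
        if any(v < 0 for v in numeric.values()):
            raise ValidationError("all rates and concentrations must be >= 0")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if min(self.cv_fl1, self.cv_fl3, self.cv_scatter) <= 0:
            raise ValidationError("cv values must be positive")
        object.__setattr__(self, "dilution_ladder",
                           tuple(sorted(float(d) for d in self.dilution_ladder)))


@dataclass
class SimState:
    """Instantaneous broth state; time in hours from feed start."""

    t: float = 0.0
    V: float = 0.050        # L
    X: float = 4.0          # g CDW/L
    Sg: float = 0.0         # g/L glucose
    Sx: float = 30.0        # g/L xylose
    Cf: float = 0.0         # g/L furfural
    A: float = 0.0          # adaptation, 0..1
    Fl: float = 500.0       # population-mean biosensor fluorescence
    D: float = 0.0          # damaged-cell fraction, 0..1
    cumulative_fur_in: float = 0.0      # mg since feed start
    cumulative_fur_detox: float = 0.0   # mg since feed start
    clip_events: int = 0

    _VEC = ("V", "X", "Sg", "Sx", "Cf", "A", "Fl", "D",
            "cumulative_fur_in", "cumulative_fur_detox")

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self._VEC], dtype=float)

    def with_vector(self, v: np.ndarray, t: float) -> "SimState":
        s = dataclasses.replace(self, t=t)
        for name, val in zip(self._VEC, v):
            setattr(s, name, float(val))
        return s


def _derivatives(v: np.ndarray, p: SimParams, secondary_rate: float) -> np.ndarray:
    V, X, Sg, Sx, Cf, A, Fl, D, _, _ = v
    Sg, Sx, Cf = max(Sg, 0.0), max(Sx, 0.0), max(Cf, 0.0)
    A, D = min(max(A, 0.0), 1.0), min(max(D, 0.0), 1.0)

    Fp = p.primary_rate / ML_PER_L     # L/h
    Fs = secondary_rate / ML_PER_L
    F = Fp + Fs
    d = F / V

    mu_g = p.mu_max * Sg / (p.Ks_glc + Sg)
    mu_x = p.mu_max_xyl * Sx / (p.Ks_xyl + Sx) * p.K_rep / (p.K_rep + Sg)
    mu = mu_g + mu_x

    fur_in = Fp * p.feed_fur + Fs * p.secondary_fur          # g/h
    q_eff = p.q_detox * (p.detox_base_frac
                         + (1.0 - p.detox_base_frac) * A)
    detox = q_eff * X * Cf / (Cf + p.K_f)                    # g/L/h
    stress = Cf * (1.0 - A)

    return np.array([
        F,                                                   # dV
        (mu - d) * X,                                        # dX
        Fp * p.feed_glc / V - d * Sg - mu_g * X / p.Yxs,     # dSg
        Fp * p.feed_xyl / V - d * Sx - mu_x * X / p.Yxs,     # dSx
        fur_in / V - d * Cf - detox,                         # dCf
        p.k_adapt * (1.0 if Cf > 1e-9 else 0.0) * (1.0 - A), # dA
        p.k_ind * stress - p.k_relax * (Fl - p.F0),          # dFl
        (p.k_dam * stress + p.k_dam_bg) * (1.0 - D)
        - p.k_rec * D,                                       # dD
        fur_in * 1000.0,                                     # mg/h in
        detox * V * 1000.0,                                  # mg/h detoxified
    ])


def step(state: SimState, p: SimParams, secondary_rate: float = 0.0) -> SimState:
    """Advance one fixed RK4 step of length ``p.dt``.

    State invariants (non-negative concentrations, A and D in [0, 1]) are
    enforced by clipping after the step; each clip beyond numerical noise is
    counted on the state.  A cumulative-furfural decrease raises
    :class:`~cytoloop.errors.IntegrityError`.
    """
    if secondary_rate < 0:
        raise ValidationError("secondary_rate must be >= 0")
    v = state.vector()
    h = p.dt
    k1 = _derivatives(v, p, secondary_rate)
    k2 = _derivatives(v + h / 2 * k1, p, secondary_rate)
    k3 = _derivatives(v + h / 2 * k2, p, secondary_rate)
    k4 = _derivatives(v + h * k3, p, secondary_rate)
    new = v + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

    clipped = 0
    lo = np.array([1e-9, 0, 0, 0, 0, 0, 0, 0, v[8], v[9]])
    hi = np.array([np.inf, np.inf, np.inf, np.inf, np.inf, 1.0, np.inf, 1.0,
                   np.inf, np.inf])
    for i in range(len(new)):
        if new[i] < lo[i] - 1e-9 or new[i] > hi[i] + 1e-9:
            clipped += 1
        new[i] = min(max(new[i], lo[i]), hi[i])
    if new[8] < v[8] - 1e-9:
        raise IntegrityError("cumulative furfural input decreased")

    out = state.with_vector(new, t=state.t + h)
    out.clip_events = state.clip_events + clipped
    return out


def furfural_balance_error(state: SimState, initial: SimState) -> float:
    """Relative closure error of the furfural mass balance, dimensionless.

    added - detoxified - accumulated-in-broth, relative to total added.
    """
    added = state.cumulative_fur_in - initial.cumulative_fur_in
    detox = state.cumulative_fur_detox - initial.cumulative_fur_detox
    in_broth = (state.Cf * state.V - initial.Cf * initial.V) * 1000.0
    if added == 0:
        return 0.0
    return abs(added - detox - in_broth) / added


def initial_feeding_state(p: SimParams, max_batch_h: float = 40.0) -> SimState:
    """Integrate the glucose batch phase and re-zero time at feed start.

    The batch runs with both feeds off until glucose falls below
    ``p.glc_depleted`` (capped at ``max_batch_h``); the returned state has
    ``t = 0`` and zeroed furfural accumulators, matching the convention that
    time 0 is the beginning of the feeding phase.
    """
    s = SimState(t=0.0, V=p.V0, X=p.X0, Sg=p.batch_glc, Sx=p.batch_xyl,
                 Cf=0.0, A=0.0, Fl=p.F0, D=0.0,
                 cumulative_fur_in=0.0, cumulative_fur_detox=0.0)
    batch = dataclasses.replace(p, primary_rate=0.0)
    while s.Sg > p.glc_depleted and s.t < max_batch_h:
        s = step(s, batch, 0.0)
    s.t = 0.0
    s.cumulative_fur_in = 0.0
    s.cumulative_fur_detox = 0.0
    s.clip_events = 0
    return s


# ---------------------------------------------------------------------------
# event-level acquisition
# ---------------------------------------------------------------------------

def _lognormal(rng: np.random.Generator, median: float, cv: float,
               size: int) -> np.ndarray:
    sigma = np.sqrt(np.log1p(cv * cv))
    return median * np.exp(sigma * rng.standard_normal(size))


def choose_dilution(cell_density_proxy: float, target_events: int,
                    ladder: Sequence[float],
                    events_per_g: float = SimParams.acq_events_per_g,
                    band: float = SimParams.dilution_band) -> float:
    """Smallest ladder factor keeping predicted events below the upper band.

    The predictor is linear: ``predicted = proxy * events_per_g / factor``.
    A prediction exactly at the band edge steps up to the next factor
    (strictly-below rule); the ladder saturates at both extremes.
    """
    if not ladder:
        raise ValidationError("dilution ladder must be non-empty")
    upper = band * target_events
    for f in sorted(ladder):
        if cell_density_proxy * events_per_g / f < upper:
            return float(f)
    return float(sorted(ladder)[-1])


def synthesize_sample(state: SimState, p: SimParams,
                      rng: np.random.Generator,
                      sample_id: str | None = None) -> EventTable:
    """Draw one synthetic cytometry sample from the current broth state.

    Events split into debris (fixed fraction, low scatter), damaged cells
    (fraction ``D`` of cells: PI-bright, FL1 around basal since damaged
    cells do not respond to furfural) and intact cells (FL1 lognormal with
    median at the model fluorescence ``Fl``).  Deterministic for a given
    generator state.
    """
    n = p.events_per_sample
    n_debris = int(rng.binomial(n, p.debris_frac)) if n else 0
    n_cells = n - n_debris
    n_damaged = int(rng.binomial(n_cells, state.D)) if n_cells else 0
    n_intact = n_cells - n_damaged

    def block(count, fsc_med, ssc_med, fl1_med, fl3_med):
        return np.column_stack([
            _lognormal(rng, fsc_med, p.cv_scatter, count),
            _lognormal(rng, ssc_med, p.cv_scatter, count),
            _lognormal(rng, fl1_med, p.cv_fl1, count),
            _lognormal(rng, fl3_med, p.cv_fl3, count),
        ]) if count else np.empty((0, 4))

    debris = block(n_debris, p.fsc_debris, p.ssc_debris, 50.0, 50.0)
    damaged = block(n_damaged, 0.9 * p.fsc_yeast, p.ssc_yeast,
                    p.F0, p.fl3_damaged)
    intact = block(n_intact, p.fsc_yeast, p.ssc_yeast,
                   max(state.Fl, 1.0), p.fl3_intact)
    events = np.vstack([debris, damaged, intact])
    if len(events):
        events = events[rng.permutation(len(events))]

    dilution = choose_dilution(state.X * state.V, p.events_per_sample,
                               p.dilution_ladder, p.acq_events_per_g,
                               p.dilution_band)
    return EventTable(
        sample_id=sample_id or f"sim_t{state.t:07.2f}",
        acquired_at=state.t,
        dilution_factor=dilution,
        channels=("FSC-H", "SSC-H", "FL1-H", "FL3-H"),
        events=events,
    )


# ---------------------------------------------------------------------------
# closed loop
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    trajectory: pd.DataFrame
    stats: list
    commands: list
    audits: list
    fcs_paths: list = field(default_factory=list)

    def stats_frame(self) -> pd.DataFrame:
        from .persist import stats_to_frame
        return stats_to_frame(self.stats)


def run_closed_loop(p: SimParams | None = None,
                    cfg: ControllerConfig | None = None,
                    gate: GateConfig | None = None,
                    duration: float = 30.0,
                    mode: str = "controlled",
                    outdir: str | Path | None = None,
                    seed: int | None = None,
                    sample_interval: float = 0.5,
                    run_id: str = "sim",
                    pre_sample_hook: Callable[[SimState], SimState] | None = None,
                    ) -> SimResult:
    """Run the full in-silico experiment.

    Every ``sample_interval`` hours of simulated time a cytometry sample is
    synthesized (optionally written to and re-read from an FCS file in
    ``outdir``), gated, folded into the trend series, and — in
    ``controlled`` mode — evaluated by the controller, whose commanded rate
    drives the secondary pump for the subsequent integration steps.  In
    ``fixed`` mode the secondary pump is pinned to 0 (the fixed-feed-rate
    reference arm).

    ``pre_sample_hook`` may rewrite the state just before each acquisition
    (used to inject disturbances such as a forced viability drop).
    """
    if duration <= 0:
        raise ValidationError("duration must be positive")
    if mode not in ("controlled", "fixed"):
        raise ValidationError(f"unknown mode {mode!r}")
    p = p or SimParams()
    cfg = cfg or ControllerConfig()
    gate = gate or GateConfig()
    master = np.random.SeedSequence(p.seed if seed is None else seed)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    state = initial_feeding_state(p)
    ctrl = ControllerState(cfg)
    secondary = 0.0

    traj_rows = []
    stats_list: list[PopulationStats] = []
    commands: list[PumpCommand] = []
    audits: list[AuditRecord] = []
    fcs_paths: list[Path] = []

    n_samples = int(round(duration / sample_interval))
    steps_per_sample = max(int(round(sample_interval / p.dt)), 1)
    sample_streams = master.spawn(n_samples)

    def record(s: SimState, rate: float):
        traj_rows.append(dict(t=s.t, V=s.V, X=s.X, Sg=s.Sg, Sx=s.Sx,
                              Cf=s.Cf, A=s.A, Fl=s.Fl, D=s.D,
                              cumulative_fur_in=s.cumulative_fur_in,
                              secondary_rate=rate))

    record(state, secondary)
    for i in range(n_samples):
        for _ in range(steps_per_sample):
            state = step(state, p, secondary)
            record(state, secondary)
        if pre_sample_hook is not None:
            state = pre_sample_hook(state)
        rng = np.random.default_rng(sample_streams[i])
        table = synthesize_sample(state, p, rng,
                                  sample_id=f"{run_id}_t{state.t:06.2f}")
        if outdir is not None:
            path = outdir / f"{run_id}_t{state.t:06.2f}.fcs"
            write_fcs(table, path)
            fcs_paths.append(path)
            table = read_fcs(path)
        stats = gate_sample(table, gate)
        stats_list.append(stats)
        if mode == "controlled" and stats.usable:
            ctrl, cmd, audit = evaluate(ctrl, stats, cfg)
            commands.append(cmd)
            audits.append(audit)
            secondary = cmd.rate

    return SimResult(trajectory=pd.DataFrame(traj_rows), stats=stats_list,
                     commands=commands, audits=audits, fcs_paths=fcs_paths)
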