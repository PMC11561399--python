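# cytoloop

Reactive flow-cytometry feedback control for biosensor-guided fed-batch
cultivation, with a closed-loop in-silico testbed.

## What it does

In lignocellulosic bioethanol processes, yeast must tolerate inhibitors such
as furfural. A *Saccharomyces cerevisiae* strain carrying a
*TRX2*p-*yEGFP* redox biosensor reports furfural-induced NADPH/NADP+
imbalance as GFP fluorescence; the signal decays as cells adapt. `cytoloop`
turns that decay into a control input: at-line flow cytometry samples the
culture every 30 minutes, an automated two-step gate splits events into
debris / PI-stained ("damaged") / intact GFP± populations, and two
statistics drive a feed-pump state machine —

* **MFI(GFP)**: arithmetic mean FL1-H over intact cells, smoothed with an
  exponential moving average (EMA, `alpha = 0.5`); when the least-squares
  slope of the last three smoothed points turns negative (adaptation), a
  secondary concentrated-furfural feed starts at 1 mL/hr and escalates
  stepwise 1 → 1.5 → 3 → 5 mL/hr while the decline persists;
* **%PI**: percentage of PI-stained cells among gated events; a positive
  %PI slope or a smoothed %PI above 35% is a viability safeguard that stops
  the pump with priority over everything else.

Every decision is bound to an append-only JSON-lines audit record, and the
monitoring time series is an append-only CSV. The package also contains a
fed-batch simulator (ODE model of growth, furfural detoxification,
biosensor induction/adaptation and membrane damage, integrated with RK4)
that synthesizes event-level FCS 3.1 files, so the entire loop — file
discovery, gating, trend, controller, actuation — runs end-to-end with no
hardware. Intended users: bioprocess engineers prototyping reactive-FCM
control strategies, and anyone needing a reproducible software testbed for
cytometry-driven feedback.

## Worked example

Simulate both cultivation arms — fixed feed rate (F-FR) and
sensor-controlled feed rate (SC-FR) — for a 30 h feeding phase:

```sh
cytoloop simulate --config examples/run.ini --mode fixed      --duration 30 --seed 1 --out out_ffr
cytoloop simulate --config examples/run.ini --mode controlled --duration 30 --seed 1 --out out_scfr
```

which prints

```
simulated 30.0 h, 60 samples, 0 pump actions, cumulative furfural 1292 mg
simulated 30.0 h, 60 samples, 24 pump actions, cumulative furfural 4142 mg
```

The fixed arm delivers 1292 mg furfural (6.24 mL/hr × 6.9 g/L × 30 h) and
never actuates. In the controlled arm the MFI rises to a single peak near
4 h, its smoothed slope turns negative, and the pump starts at 7 h at
1 mL/hr; re-induction produces a second MFI peak near 14 h, after which the
rate escalates to 5 mL/hr — 4142 mg of furfural in total, ~3.2× the fixed
arm, while the damaged-cell fraction stays below the 35% safeguard ceiling.
Each run writes `trajectory.csv` (broth state), `stats.csv` (per-sample
gated statistics with EMA columns), `audit.jsonl` (one record per pump
decision) and an `fcs/` directory with one FCS file per sample.

The same pipeline runs against real acquisitions:

```sh
cytoloop analyze --config examples/run.ini --in <fcs_dir>     # offline
cytoloop control --config examples/run.ini                    # live loop
```

`control` polls a watch directory, quarantines malformed files, resumes its
trend state from a previous session's CSV, and commands the pump to 0 on
shutdown. The actuator is either a mock or a serial line speaking
`RATE <ml_per_hr>\n` / `OK\n`.

## Library surface

```python
import cytoloop as cl

table = cl.read_fcs("sample.fcs")                  # EventTable
stats = cl.gate_sample(table, cl.GateConfig())     # counts, MFI, %PI
cmds, audit = cl.run_session(stats_stream, cl.ControllerConfig())
res = cl.run_closed_loop(duration=30.0, mode="controlled", seed=1)
```

See `docs/methods.md` for the model equations, parameter meanings and
calibration rationale.

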