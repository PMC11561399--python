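# Methods

## Problem and approach

`cytoloop` implements a reactive flow-cytometry control loop for fed-batch
yeast cultivation with an intracellular redox biosensor. A *S. cerevisiae*
strain carrying a *TRX2*p-*yEGFP* reporter emits GFP in proportion to the
NADPH/NADP+ imbalance caused by furfural; as cells adapt (upregulated pentose
phosphate pathway, restored NADPH supply) the signal decays even though
furfural feeding continues. The control idea is to treat that decay as
"headroom": when the population-level GFP signal stops rising, more furfural
can be tolerated, so a secondary concentrated-furfural feed is switched on
and escalated, guarded by a viability ceiling on propidium-iodide (PI)
staining.

The package contains the complete at-line chain — FCS file I/O, automated
gating, trend estimation, the pump state machine, actuator back-ends — plus
a closed-loop fed-batch simulator that synthesizes FCS files so every layer
can be exercised end-to-end without a cytometer, a pump, or a culture.

## Gating

Two static steps, applied per event:

1. **Debris gate.** Events with FSC-H below `fsc_min` are debris and are
   excluded from every downstream statistic.
2. **Quadrant classification.** Remaining (yeast) events with FL3-H at or
   above `fl3_threshold` are *damaged* (PI-stained); the rest are *intact*,
   split at `fl1_threshold` on FL1-H into GFP-positive and GFP-negative.

Ties go to the upper/positive class (`>=`), making the partition exhaustive,
disjoint and deterministic. Per-sample statistics are the arithmetic-mean
FL1-H over intact cells (`mfi_gfp`; the population choice and a
geometric-mean option are configurable, since damaged cells do not respond
to furfural and are excluded by default) and the percentage of damaged cells
among gated events (`pct_pi`). A sample with fewer than `min_events` gated
events is flagged unusable and skipped by the trend and controller layers —
logged, never silently dropped. Threshold defaults (`fsc_min` 10 000,
`fl3_threshold` 1 000, `fl1_threshold` 1 500) were calibrated once against
the simulator's synthetic populations; on a real instrument they must be set
from control samples in the run configuration.

## Trend estimation

Both control signals are smoothed with an exponential moving average,
`ema_i = alpha*x_i + (1-alpha)*ema_{i-1}` with `ema_0 = x_0`, then the
trigger statistic is the ordinary least-squares slope of the last `k = 3`
smoothed values against their actual acquisition times (so skipped samples
and irregular intervals are handled without special cases). `alpha = 0.5`
is the span-3 convention `alpha = 2/(k+1)` matched to the three-point
window; both `alpha` and whether the slope is fit to smoothed or raw values
are configuration knobs. With fewer than `k` points the slope is undefined
and no control action can fire.

## Controller

One evaluation per usable sample, in strict priority order:

1. **Safeguard** — if the %PI slope is positive *or* the smoothed %PI
   exceeds `pi_max` (35%), the pump is commanded to 0. "Average number of
   PI-stained cells" is read as the EMA of %PI (a plain last-k mean is a
   config option).
2. **Start** — pump off, safeguard clear, MFI slope strictly negative:
   start at the bottom of the rate ladder (1 mL/hr).
3. **Escalate** — pump on, `dwell_samples` (3) usable samples at the
   current rate, MFI slope negative again: move one rung up the ladder
   (1 → 1.5 → 3 → 5 mL/hr, never skipping; the top rung is absorbing).
4. **Hold** otherwise. A slope of exactly zero never triggers.

The safeguard is non-latching by default: once PI conditions clear, a new
MFI decline restarts the pump at the bottom rung, never at the pre-stop
rate (a latching mode exists). The dwell rule is an anti-chatter addition:
three samples is the minimum for a fresh slope at the new rate. Every
evaluation emits an audit record (timestamp, both EMAs and slopes, the
ceiling, the decision and commanded rate) to a JSON-lines log; replaying
the log reproduces the command sequence exactly, and identical input
streams produce byte-identical logs.

Actuators are pluggable: a mock that records commands, and a serial-line
text protocol (`RATE <ml_per_hr>\n`, expecting `OK\n`) over any transport
object with `write`/`readline` — a pyserial port qualifies, tests use an
in-memory loopback. A missing acknowledgment is retried once, then raises
an alarm and the pump is assumed stopped.

## FCS subset

Files are written as FCS 3.1, single dataset, listmode, `$DATATYPE F`
(little-endian single precision); reading also accepts `$DATATYPE I` with
linear scaling and either byte order. Custom keywords carry the dilution
factor, sample id and the exact decimal-hour timestamp, so a write/read
round trip preserves event values to single-precision resolution and event
counts exactly. Acquisition-time precedence is custom keyword, then
`$BTIM`/`$DATE`, then file mtime, and the source used is recorded for the
audit trail. Multi-dataset files, ASCII/double datatypes, log-amplified
integer data, compensation and display transforms are out of scope.

## Simulator

A phenomenological ODE model integrated with fixed-step classical RK4
(`dt = 0.01 h`; fixed step keeps runs exactly reproducible and
solver-independent). State: volume `V`, biomass `X`, glucose `Sg`, xylose
`Sx`, furfural `Cf`, adaptation `A` in [0, 1], population-mean biosensor
fluorescence `Fl`, damaged fraction `D`, plus cumulative furfural
bookkeeping. With feed `F` (primary 6.24 mL/hr of 20 g/L glucose, 20 g/L
xylose, 6.9 g/L furfural; secondary 50 g/L furfural at the commanded rate):

* dilution `d = F/V`, `dV/dt = F` (no outflow);
* diauxic Monod growth: glucose-repressed xylose uptake
  (`K_rep/(K_rep+Sg)` factor);
* furfural: `dCf/dt = inflow/V − d·Cf − q_eff·X·Cf/(Cf+K_f)` with
  `q_eff = q_detox·(a0 + (1−a0)·A)` — detox capacity grows with
  adaptation, reflecting the upregulated NADPH supply of adapted cells;
* adaptation: `dA/dt = k_adapt·1[Cf>0]·(1−A)`;
* biosensor: stress signal `s = Cf·(1−A)`,
  `dFl/dt = k_ind·s − k_relax·(Fl−F0)`;
* damage: `dD/dt = (k_dam·s + k_dam_bg)·(1−D) − k_rec·D` — stress-driven
  like the biosensor (adapted cells resist furfural damage; this is what
  lets %PI fall to a plateau while feeding continues) plus a small
  furfural-independent background that sets the late plateau.

The glucose batch phase (~20 h, 40 g/L glucose + 40 g/L xylose from an
OD-0.1 inoculum) is simulated and time is re-zeroed at feed start, which is
the clock used in all outputs.

Coupling detox capacity and damage to the *unadapted stress* rather than to
raw furfural is the model's central design choice. With constant-capacity
detox, biomass growth and volume dilution make furfural per cell — and
hence fluorescence — decline even with adaptation switched off, which would
confound the very mechanism the controller exploits. As implemented, with
`k_adapt = 0` furfural rises monotonically under constant feed, the MFI
never turns down, and the pump never starts; with adaptation on, the full
phenomenology emerges: a single transient MFI peak under fixed feed, pump
start shortly after the smoothed MFI turns down (~7–8 h of feeding),
re-induction to a second MFI peak (~13–15 h), stepwise escalation to
5 mL/hr and late furfural accumulation once input outruns detox capacity.

### Event synthesis and acquisition

Each 30-min sample draws `events_per_sample` (5 000) events: a fixed debris
fraction (15%) with low scatter, then damaged vs intact cells split by `D`.
Channel intensities are lognormal per class — intact FL1-H with median at
the model fluorescence, damaged FL1-H around basal (damaged cells do not
respond), FL3-H high for damaged and low for intact — with coefficients of
variation 0.35 (FL1), 0.40 (FL3), 0.30 (scatter). Class separations put
the gate thresholds many sigma from the class medians, so gating error is
negligible by construction; the binomial sampling of class counts is the
realistic noise source the EMA exists to absorb. A dilution factor is
chosen per sample from a (10, 100, 1000) ladder by a linear
events-per-biomass predictor, stepping up when the predicted event count
leaves an upper band around the target — mimicking an adaptive
dilution-step policy that keeps recorded events comparable across the run.
One master seed fans out to independent per-sample substreams, so any
sample is reproducible in isolation and whole runs are deterministic.

### Calibration and what passing tests mean

All kinetic constants are phenomenological, chosen once so the default run
reproduces the qualitative template of the bench system: MFI peak within
3–8 h of feed start returning to near baseline by 30 h; damaged-cell peak
~40% around 4 h relaxing to an ~8% plateau; pump start at 7–8 h;
re-induction peak near 14 h; 2.5–3× more furfural delivered in the
controlled arm. They are not fitted to measurements, and quantitative
outcomes that depend on them (fold-changes, absolute MFI) are not asserted
anywhere — only directional and structural properties are. The synthetic
data also omit real-instrument features: spectral spillover, doublets,
drift in laser power or dilution accuracy, skewed/multimodal
subpopulations, clogging artifacts. Passing tests therefore demonstrate
the correctness of the decision chain and the reachability of its
behaviors, not instrument-grade performance on real acquisitions.

## Numerical and robustness choices

* Furfural mass balance (added − detoxified − in broth) closes to <0.5%
  over 10 h at the default step; the RK4 trajectory matches the closed-form
  fluorescence fixed point `F0 + k_ind·Cf/k_relax` to <1% and converges at
  ~4th order on smooth sub-problems.
* State invariants (non-negative concentrations, `A`, `D` in [0, 1]) are
  enforced by clipping, with clip events counted on the state; cumulative
  counters are monotone by construction and checked.
* Unusable samples, undefined slopes and empty populations are explicit
  flagged values (`None`), never fabricated numbers.
* The live loop persists EMA columns in the stats CSV and a processed-file
  list, so a restarted session resumes the trend exactly rather than
  recomputing it; on any shutdown path the pump is commanded to 0 and that
  command is audited. Malformed FCS files are quarantined and the loop
  continues.
* Polling (default 60 s against a 30-min cadence) rather than filesystem
  events, for portability.

## Known limitations

* The %PI series at its late plateau is statistically flat, so its
  three-point slope is positive roughly half the time on counting noise
  alone; the non-latching safeguard then stops and restarts the pump
  occasionally late in a run (visible as `safeguard_stop`/restart pairs in
  the audit log). This is the literal consequence of the stop rule; a real
  deployment would likely add hysteresis or a minimum-slope threshold.
* The late %PI plateau calibrates to ~8%, slightly under the ~10% template.
* Gating thresholds are static per run; density-based auto-gating, doublet
  discrimination and compensation are out of scope.
* The biosensor and damage kinetics are single-pool first-order models; no
  mechanistic redox/metabolic detail (NADPH pools, thioredoxin kinetics) is
  attempted, and ethanol/byproduct stoichiometry is not tracked.
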