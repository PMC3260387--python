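# Methods

## Scenario model

A scenario is a discrete-event replay of a rescuer-team action stream on an
integer-second clock. The patient starts in cardiac arrest (ASY, cVF or
pVT; sinus is rejected as a start) with the baseline script variables:
cardiac output 0, neuromuscular blockade 100 %, FiO₂ 0.80, ischemic index
averaging 0.99, ischemic index sensitivity 0.5, and both ventricular
contractility factors 0.5. The three initial patients differ only in
rhythm.

Actions are of five kinds: compression start/stop edges, instantaneous
ventilations, defibrillation attempts (with energy), and the six observer
marker clicks. Simultaneous actions at one second are processed in stream
order. After every marker state the scenario returns to *no chest
compression*; if compressions are still running and the systolic pressure
clears the 40 mmHg gate, it passes automatically back into *chest
compression* in the same second.

### Gating chain

`drug_conditioning_armed` is an explicit flag set by the second-adrenaline
and amiodarone markers. The script convention that those markers "set IIS
to 0.5" is ambiguous because IIS is already 0.5 at baseline; the explicit
flag preserves the intended causal chain (drugs → compressions → effective
shock) without overloading a variable that never actually changes value.
IIS, IIA, CF-LV and CF-RV are nevertheless kept on the patient state for
log fidelity. CF-LV latches at 0.8 the moment compressions run while
armed, and stays there.

Shock classification: energy ≤ 10 J is ignored (logged as a warning, not a
shock); otherwise the shock is *indicated* on cVF/pVT and *non-indicated*
on ASY/SR. All thresholds — >10 J, >60 s, >40 mmHg — are strict
inequalities. Shocks above the advisory 200 J cap are processed normally
but flagged: the cap is a safety rule for humans, not an engine rule.

Degeneration: a shockable rhythm with no compressions for strictly more
than 60 s becomes asystole at the first second exceeding the timeout
(second 61 when compressions never started). Asystole is absorbing — no
shock converts it — so abandoning compressions is an unrecoverable failure
mode, which the property tests assert.

### Scenario termination

The scenario ends at ROSC (rhythm change to SR, a ROSC record, and an EXIT
state entry at the shock second) or at the horizon (EXIT at the horizon).
Ending at ROSC reflects how such scenarios are actually run — the team
stops once sinus returns and the observer takes control — and gives every
metric a well-defined assessment window; the alternative (simulating
post-ROSC care) is out of scope.

### Surrogate haemodynamics

The native physiologic model of the commercial simulator this pipeline
emulates is proprietary and unpublished. A three-regime piecewise kernel
stands in: no-flow (SBP 0, CO 0), CPR-flow (SBP 60 mmHg — above the
40 mmHg state gate — and CO equal to the team profile's compression
output), and post-ROSC (SBP 120 mmHg, CO 5 L/min). HR, DBP and SpO₂
channels are filled with fixed per-regime values for log realism only. The
metrics consume only CO and SBP; nothing downstream depends on kernel
realism, and no oxygenation/CO₂ modelling is attempted.

## Log dialect

Three tab-separated UTF-8 files with mandatory one-line headers and
integer-second elapsed times: `event.tsv` (time, code, detail), `physio.tsv`
(time, hr, sbp, dbp, cardiac_output, spo2), `drug.tsv` (time, drug, dose).
The real simulator's log layout is not public; this dialect is defined from
the content the analysis needs. Deliberately, compression edges and
ventilations are first-class event records even though the hardware this
emulates does not log them — otherwise no-flow time and ventilation counts
could not be recovered from files alone. Floats are written in their
shortest exact decimal form, so write→read is a bit-exact identity
(property-tested); readers report malformed or non-monotone lines with
their line number.

Physio samples are taken every 5 s (default) at the *start* of the second,
before any action at that instant. The sample at the ROSC second therefore
still shows pre-shock physiology, which keeps post-ROSC values out of the
median-CO window by construction. A consequence: a compression segment
starting exactly at a sampling instant contributes flow only from the next
sample on.

## Metrics

The assessment window is [0, ROSC], or [0, last record] for scenarios
without ROSC (censored; time-to-ROSC is then NA). Within the window:

- **No-flow time**: window length minus seconds covered by [CC_ON, CC_OFF)
  intervals (an unclosed CC_ON runs to the window end); the fraction is
  no-flow time over window length. The window starts at t = 0, so the
  pre-first-action interval counts as no-flow.
- **Defibrillation metrics**: over all recorded shocks (indicated and
  non-indicated): time of first shock; counts per class and their
  fraction; mean interval = (t_last − t_first)/(n − 1) for n ≥ 2; mean
  absolute deviation of consecutive intervals from the 120 s guideline
  cycle. NA where fewer shocks exist than needed.
- **Adrenaline time**: earliest first-dose marker, falling back to the
  earliest adrenaline drug-log record.
- **Ventilations**: count strictly before the intubation marker (before
  window end if never intubated); frequency uses that same denominator in
  minutes, NA if it is zero. Post-intubation ventilation is out of scope.
- **Cardiac output**: median (and, as a supplementary field, mean) of CO
  samples with time ≤ window end. Median is the primary variable; with the
  even-count midpoint convention.

Cohort summaries report mean and **population** SD (divisor n) per metric,
with NA values excluded pairwise; the cohort is treated as the complete
set of assessed teams, not a sample from a population. Printed precision:
times as mm:ss, fractions to two decimals, rates/counts/volumes to one.

## Synthetic teams

A `TeamProfile` drives the generator: first-shock time and inter-shock
cycle (mean/SD), a peri-shock hands-off pause carved out of compressions
before each shock (default 10 s — rescuers clearing the patient; the main
driver of realistic no-flow fractions), alternating compression
segment/pause lengths (mean/SD), a bag-mask ventilation rate active until
the intubation time, marker times (optional), the compression cardiac
output, the shock energy, and a seed.

Durations are drawn from normal distributions truncated at zero and rounded
to whole seconds, so zero-SD profiles yield exactly predictable schedules:
the parameter-recovery tests assert *exact* recovery of the shock interval,
ventilation frequency and analytic pause fraction at SD = 0, and recovery
within three standard errors over 100 seeded runs at SD > 0. Ventilations
start at t = 0 and recur every 60/rate seconds, which makes the measured
frequency exactly equal the profile rate when the intubation time is a
multiple of the period. A zero-mean, zero-SD segment length encodes a team
that never compresses.

Five fixture profiles (`fixtures/profiles/team*.cfg`) are shipped. They are
tuned only to the order of magnitude of a professional prehospital cohort
(first shock ≈ 0:07–3:00, cycles ≈ 2:20–3:50, no-flow fractions ≈ 0.1–0.3,
ventilation rates ≈ 0.3–1.5 min⁻¹); fitting them to reproduce any
particular team is impossible without the original logs and is not
attempted. The generator emulates event-level behaviour only: no
compression depth/rate waveforms, no fatigue, no team coordination, and
drug effects are binary gates without pharmacokinetics — so passing tests
validate the pipeline's accounting, not human-behaviour realism.

## Validation strategy and numerical choices

- An independent brute-force oracle (a flat per-second scan of the raw
  action stream, in the test suite) must agree with the full pipeline —
  generate → engine → written logs → read back → metrics — on 200 random
  seeded team behaviours at a 20-minute horizon, to 1e-12.
- The conversion, degeneration and pressure gates are checked exhaustively
  over their small input grids.
- The shipped benchmark cohort of five professional teams aggregates to
  its published-precision summary column (e.g. no-flow-time fraction
  0.26 ± 0.10) through `summarize`; per-team rows are inputs, not
  reproduced outputs.
- Log round-trips and the mm:ss utilities are property-tested with
  hypothesis (derandomized).

Problem sizes used by the default suite and the acceptance script —
20-minute horizons, 5 s sampling, 100–200 replicate runs — were chosen so
the statistical assertions are stable at three standard errors while the
whole suite stays fast.

## Known limitations

Ventilation frequencies measured by this class of tool are known to read
far lower than observed clinical rates (the sensing counts discrete
qualifying inflations, and nothing after intubation); the metric is kept
as defined. Mean time-type cohort cells can differ by a second or two from
hand-computed means of rounded per-team mm:ss values, because aggregation
happens on unrounded seconds before formatting. Guideline pass/fail scoring
is deliberately not computed — the variables are descriptive and adherence
judgements are left to the instructor.
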