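# cprsim

Scripted cardiac-arrest scenarios with automated CPR performance metrics.

`cprsim` is for simulation educators and resuscitation researchers who want
**observer-independent, immediately available performance feedback** from
megacode-style training scenarios. It re-creates, in software, the full
pipeline that a scripted high-fidelity patient simulator provides: a dynamic
scenario state machine that reacts to the rescuer team's actions, three
plain-text log streams recorded during the scenario, and a log-mining
analyzer that extracts the per-scenario performance variables used in
debriefing — plus a parameterized synthetic rescuer-team generator so the
whole pipeline can be exercised and validated without mannequin hardware.

## The model

A scenario starts in one of three arrest rhythms — asystole (ASY), coarse
ventricular fibrillation (cVF) or pulseless ventricular tachycardia (pVT) —
with cardiac output zero. The scripted state machine switches between the
states *no chest compression*, *chest compression* (entered when systolic
pressure exceeds 40 mmHg), *ventilation*, *ineffective resuscitation*,
*defibrillation* (→ *indicated* / *non-indicated* by the rhythm at shock
time), six observer-clicked *marker* states (IV line, intubation, first and
second adrenaline, atropine, amiodarone), and *exit*.

The therapeutic chain is gated by internal script variables:

- the **second adrenaline** or **amiodarone** marker sets the ischemic index
  sensitivity (IIS) to 0.5 and arms drug conditioning;
- **chest compressions while armed** raise the left-ventricular
  contractility factor (CF-LV) to 0.8 — modelling drug transport to its
  receptors;
- a **defibrillation above 10 J** then, and only then, converts cVF/pVT to
  sinus rhythm: the ROSC event. Atropine analogously sets CF-RV to 0.8.
- a shockable rhythm left **without compressions for more than 60 s**
  degenerates irreversibly to asystole.

Haemodynamics use a three-regime surrogate kernel (no-flow: SBP 0, CO 0;
CPR-flow: SBP 60 mmHg, CO = the team's compression output; post-ROSC:
SBP 120 mmHg, CO 5 L/min); the metrics need correctly gated CO/SBP signals,
not a physiologic model.

From the three logs the analyzer extracts, per scenario: median cardiac
output; no-flow time and **no-flow-time fraction** (hands-off time over
arrest duration); time to ROSC; time to first adrenaline, and to first
defibrillation; counts and fraction of indicated vs non-indicated shocks;
the mean inter-shock interval and its mean absolute deviation from the
2-minute guideline cycle; and pre-intubation ventilation count and
frequency. Cohorts are summarized as mean ± SD (population convention).

## Worked example

Simulate one scenario with the shipped task-dense fixture team, then
re-analyze its logs:

```sh
$ cprsim simulate --team team3 --rhythm vf --seed 42 --out demo/run1
$ head -12 demo/run1/report.tsv
median_cardiac_output   1.4
mean_cardiac_output     1.0021052631578948
no_flow_time    130.0
no_flow_time_mmss       02:10
no_flow_time_fraction   0.2748414376321353
time_to_rosc    473.0
time_to_rosc_mmss       07:53
time_to_first_epinephrine       305.0
time_to_first_epinephrine_mmss  05:05
time_to_intubation      240.0
time_to_intubation_mmss 04:00
time_to_first_defib     109.0
```

This team reached ROSC after 07:53: it gave adrenaline at 05:05 and
amiodarone shortly after, kept compressing (arming the conversion gate),
and the next shock converted the cVF to sinus. Its many clustered tasks
cost a 27 % no-flow-time fraction. `cprsim analyze --logs demo/run1 --out
report.tsv` recomputes the identical report from the log files alone.

A five-team cohort summary (`cprsim cohort demo/t*/report.tsv --out
summary.tsv`) prints one mean ± SD row per metric:

```text
cohort of 5 scenarios
median cardiac output (L/min)   1.5 ± 0.2   (n=5)
no-flow-time fraction           0.18 ± 0.07 (n=5)
time until ROSC (min:sec)       11:16 ± 02:07 (n=5)
indicated defibrillations (n)   4.4 ± 0.8   (n=5)
mean interval of defibrillations (min:sec)  02:53 ± 00:33 (n=5)
```

The same pipeline is available as a library: `cprsim.teams.run_scenario`
returns the three logs and the `MetricsReport` in one call.

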