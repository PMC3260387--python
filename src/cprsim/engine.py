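"""Deterministic scenario state machine for scripted cardiac-arrest training.

The engine replays a clocked stream of rescuer-team actions (chest
compression start/stop, bag-mask ventilations, defibrillation attempts,
observer-clicked marker states) against a simulated arrest patient and
produces the three log streams a log-mining assessment consumes.

The causal chain the script encodes is: administering the second dose of
adrenaline, or amiodarone, *arms* the patient (ischemic index sensitivity
0.5); subsequent chest compressions transport the drug to its receptors
(left-ventricular contractility factor raised to 0.8); only then can a
defibrillation of more than 10 J convert a shockable rhythm (coarse VF or
pulseless VT) to sinus — the ROSC event.  A shockable rhythm left without
compressions for more than 60 s degenerates irreversibly to asystole.

The native physiologic model of a commercial high-fidelity mannequin is
proprietary, so haemodynamics are a three-regime surrogate kernel
(no-flow / CPR-flow / post-ROSC); the performance metrics only need
cardiac-output and blood-pressure signals with correct gating, not
physiologic realism.

All randomness lives in :mod:`cprsim.teams`; the engine is a pure function
of its inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

from ._flatfile import read_flat, write_flat
from .log_io import (
    Drug,
    DrugLog,
    DrugRecord,
    EventCode,
    EventLog,
    EventRecord,
    PhysioLog,
    PhysioSample,
    format_defib_detail,
)


class Rhythm(str, Enum):
    """Cardiac rhythm: asystole, coarse VF, pulseless VT, or sinus."""

    ASY = "ASY"
    CVF = "cVF"
    PVT = "pVT"
    SR = "SR"

    @classmethod
    def from_string(cls, text: str) -> "Rhythm":
        aliases = {"asy": cls.ASY, "asystole": cls.ASY,
                   "vf": cls.CVF, "cvf": cls.CVF,
                   "pvt": cls.PVT, "vt": cls.PVT,
                   "sr": cls.SR, "sinus": cls.SR}
        try:
            return aliases[text.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown rhythm {text!r}") from None


SHOCKABLE = frozenset({Rhythm.CVF, Rhythm.PVT})
ARREST_RHYTHMS = frozenset({Rhythm.ASY, Rhythm.CVF, Rhythm.PVT})


class ScenarioState(str, Enum):
    NO_CC = "NO_CC"
    CC = "CC"
    VENTILATION = "VENTILATION"
    INEFFECTIVE_RESUSCITATION = "INEFFECTIVE_RESUSCITATION"
    DEFIB = "DEFIB"
    DEFIB_INDICATED = "DEFIB_INDICATED"
    DEFIB_NON_INDICATED = "DEFIB_NON_INDICATED"
    MARKER_IV_LINE = "MARKER_IV_LINE"
    MARKER_INTUBATION = "MARKER_INTUBATION"
    MARKER_EPI_1 = "MARKER_EPI_1"
    MARKER_EPI_2 = "MARKER_EPI_2"
    MARKER_ATROPINE = "MARKER_ATROPINE"
    MARKER_AMIODARONE = "MARKER_AMIODARONE"
    EXIT = "EXIT"


class Marker(str, Enum):
    """The six observer-clicked marker states (non-sensed actions)."""

    IV_LINE = "IV_LINE"
    INTUBATION = "INTUBATION"
    EPI_1 = "EPI_1"
    EPI_2 = "EPI_2"
    ATROPINE = "ATROPINE"
    AMIODARONE = "AMIODARONE"


_MARKER_STATE = {
    Marker.IV_LINE: ScenarioState.MARKER_IV_LINE,
    Marker.INTUBATION: ScenarioState.MARKER_INTUBATION,
    Marker.EPI_1: ScenarioState.MARKER_EPI_1,
    Marker.EPI_2: ScenarioState.MARKER_EPI_2,
    Marker.ATROPINE: ScenarioState.MARKER_ATROPINE,
    Marker.AMIODARONE: ScenarioState.MARKER_AMIODARONE,
}

# standard ALS doses written to the drug log on a marker click
_MARKER_DRUG = {
    Marker.EPI_1: (Drug.ADRENALINE, "1 mg"),
    Marker.EPI_2: (Drug.ADRENALINE, "1 mg"),
    Marker.ATROPINE: (Drug.ATROPINE, "3 mg"),
    Marker.AMIODARONE: (Drug.AMIODARONE, "300 mg"),
}


class DefibClass(str, Enum):
    INDICATED = "indicated"
    NON_INDICATED = "non_indicated"
    IGNORED = "ignored"


class ActionKind(str, Enum):
    CC_START = "cc_start"
    CC_STOP = "cc_stop"
    VENTILATION = "ventilation"
    DEFIBRILLATION = "defibrillation"
    MARKER = "marker"


@dataclass(frozen=True)
class ActionEvent:
    """One timestamped trainee/observer action (integer-second clock)."""

    time: int
    kind: ActionKind
    energy: float | None = None
    marker: Marker | None = None

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"negative event time {self.time}")
        if (self.energy is not None) != (self.kind is ActionKind.DEFIBRILLATION):
            raise ValueError("energy present iff kind is defibrillation")
        if (self.marker is not None) != (self.kind is ActionKind.MARKER):
            raise ValueError("marker present iff kind is marker")
        if self.energy is not None and self.energy < 0:
            raise ValueError(f"negative shock energy {self.energy}")


@dataclass(frozen=True)
class GuidelineConfig:
    """Thresholds of the scripted scenario and the 2-minute shock cycle.

    shock_energy_floor
        shocks at or below this energy (J) are ignored, not recorded.
    shock_energy_cap
        advisory safety cap (J); shocks above it are processed but flagged.
    target_shock_interval
        guideline rhythm-check/shock cycle (s) the interval-deviation
        metric is computed against.
    asystole_degeneration_timeout
        a shockable rhythm without compressions for strictly more than
        this many seconds degenerates to asystole.
    cc_sbp_threshold
        systolic pressure (mmHg) above which compressions count as the
        "chest compression" state rather than "ineffective resuscitation".
    """

    shock_energy_floor: float = 10.0
    shock_energy_cap: float = 200.0
    target_shock_interval: float = 120.0
    asystole_degeneration_timeout: float = 60.0
    cc_sbp_threshold: float = 40.0

    def __post_init__(self):
        for name in ("shock_energy_floor", "shock_energy_cap", "target_shock_interval",
                     "asystole_degeneration_timeout", "cc_sbp_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.shock_energy_floor >= self.shock_energy_cap:
            raise ValueError("shock_energy_floor must be below shock_energy_cap")

    @classmethod
    def from_file(cls, path: str | Path) -> "GuidelineConfig":
        raw = read_flat(path)
        kwargs = {k: float(v) for k, v in raw.items()}
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        write_flat(path, {
            "shock_energy_floor": self.shock_energy_floor,
            "shock_energy_cap": self.shock_energy_cap,
            "target_shock_interval": self.target_shock_interval,
            "asystole_degeneration_timeout": self.asystole_degeneration_timeout,
            "cc_sbp_threshold": self.cc_sbp_threshold,
        })


# surrogate haemodynamic kernel constants
CPR_SBP = 60.0            # mmHg during effective compressions (clears the 40 gate)
POST_ROSC_SBP = 120.0     # mmHg after conversion to sinus
POST_ROSC_CO = 5.0        # L/min after conversion to sinus
_CPR_DBP, _CPR_SPO2 = 20.0, 75.0
_ARREST_SPO2 = 55.0
_POST_ROSC_HR, _POST_ROSC_DBP, _POST_ROSC_SPO2 = 90.0, 80.0, 97.0


@dataclass(frozen=True)
class PatientState:
    """Simulator-side physiologic condition and script gating variables."""

    rhythm: Rhythm
    sbp: float = 0.0
    cardiac_output: float = 0.0
    iis: float = 0.5          # ischemic index sensitivity
    iia: float = 0.99         # ischemic index averaging
    cf_lv: float = 0.5        # left-ventricular contractility factor
    cf_rv: float = 0.5        # right-ventricular contractility factor
    fio2: float = 0.80
    nmb: float = 100.0        # fixed neuromuscular blockade, percent
    drug_conditioning_armed: bool = False
    no_cc_elapsed: float = 0.0


@dataclass(frozen=True)
class ScenarioStatus:
    """Current scenario state plus the second it was entered."""

    state: ScenarioState
    entered_at: int = 0


# ---------------------------------------------------------------------------
# elementary operations

def initialize_patient(initial_rhythm: Rhythm) -> PatientState:
    """Baseline arrest patient; the three start patients differ only in rhythm."""
    if initial_rhythm not in ARREST_RHYTHMS:
        raise ValueError(f"initial rhythm must be an arrest rhythm, got {initial_rhythm}")
    return PatientState(rhythm=initial_rhythm)


def classify_defibrillation(rhythm: Rhythm, energy: float,
                            floor: float = 10.0) -> DefibClass:
    """Indicated on cVF/pVT, non-indicated on ASY/SR; <= floor is ignored."""
    if energy < 0:
        raise ValueError(f"negative shock energy {energy}")
    if energy <= floor:
        return DefibClass.IGNORED
    return DefibClass.INDICATED if rhythm in SHOCKABLE else DefibClass.NON_INDICATED


def apply_marker(state: PatientState, marker: Marker) -> PatientState:
    """Apply a marker click; repeated clicks are idempotent.

    Second adrenaline or amiodarone arms the drug-conditioning gate
    (ischemic index sensitivity 0.5); atropine raises the right-ventricular
    contractility factor to 0.8; the remaining markers are time stamps only.
    """
    if marker in (Marker.EPI_2, Marker.AMIODARONE):
        return replace(state, iis=0.5, drug_conditioning_armed=True)
    if marker is Marker.ATROPINE:
        return replace(state, cf_rv=0.8)
    return state


def condition_on_compressions(state: PatientState,
                              compressions_active: bool) -> PatientState:
    """Compressions after arming transport the drug: CF-LV rises to 0.8."""
    if compressions_active and state.drug_conditioning_armed and state.iis == 0.5:
        return replace(state, cf_lv=0.8)
    return state


def defibrillation_outcome(state: PatientState, energy: float,
                           cfg: GuidelineConfig) -> PatientState:
    """A recorded shock converts cVF/pVT to sinus iff CF-LV is 0.8."""
    cls = classify_defibrillation(state.rhythm, energy, cfg.shock_energy_floor)
    if cls is not DefibClass.IGNORED and state.rhythm in SHOCKABLE and state.cf_lv == 0.8:
        return replace(state, rhythm=Rhythm.SR)
    return state


def degrade_to_asystole(state: PatientState, cfg: GuidelineConfig) -> PatientState:
    """cVF/pVT without compressions for strictly > timeout seconds -> asystole."""
    if state.rhythm in SHOCKABLE and state.no_cc_elapsed > cfg.asystole_degeneration_timeout:
        return replace(state, rhythm=Rhythm.ASY)
    return state


def surrogate_hemodynamics(state: PatientState, compressions_active: bool,
                           profile_cc_output: float) -> PatientState:
    """Three-regime kernel: no-flow, CPR-flow, post-ROSC plateau."""
    if profile_cc_output <= 0:
        raise ValueError("profile_cc_output must be positive")
    if state.rhythm is Rhythm.SR:
        return replace(state, sbp=POST_ROSC_SBP, cardiac_output=POST_ROSC_CO)
    if compressions_active:
        return replace(state, sbp=CPR_SBP, cardiac_output=profile_cc_output)
    return replace(state, sbp=0.0, cardiac_output=0.0)


def _state_sequence(status: ScenarioStatus, patient: PatientState,
                    event: ActionEvent, cfg: GuidelineConfig) -> list[ScenarioState]:
    """States passed through automatically on *event* (may be several)."""
    if event.kind is ActionKind.CC_START:
        effective = CPR_SBP > cfg.cc_sbp_threshold
        return [ScenarioState.CC if effective else ScenarioState.INEFFECTIVE_RESUSCITATION]
    if event.kind is ActionKind.CC_STOP:
        return [ScenarioState.NO_CC]
    if event.kind is ActionKind.VENTILATION:
        back = status.state if status.state in (
            ScenarioState.CC, ScenarioState.INEFFECTIVE_RESUSCITATION) else ScenarioState.NO_CC
        return [ScenarioState.VENTILATION, back]
    if event.kind is ActionKind.MARKER:
        return [_MARKER_STATE[event.marker], ScenarioState.NO_CC]
    if event.kind is ActionKind.DEFIBRILLATION:
        cls = classify_defibrillation(patient.rhythm, event.energy, cfg.shock_energy_floor)
        if cls is DefibClass.IGNORED:
            return []
        seq = [ScenarioState.DEFIB,
               ScenarioState.DEFIB_INDICATED if cls is DefibClass.INDICATED
               else ScenarioState.DEFIB_NON_INDICATED]
        after = defibrillation_outcome(patient, event.energy, cfg)
        if after.rhythm is Rhythm.SR and patient.rhythm in SHOCKABLE:
            seq.append(ScenarioState.EXIT)   # observer takes control at ROSC
        else:
            seq.append(ScenarioState.CC if status.state is ScenarioState.CC
                       else ScenarioState.NO_CC)
        return seq
    raise ValueError(f"unknown action kind {event.kind!r}")


def transition(status: ScenarioStatus, patient: PatientState,
               event: ActionEvent, cfg: GuidelineConfig) -> ScenarioStatus:
    """Resting scenario state after processing one action event."""
    if event.time < status.entered_at:
        raise ValueError(
            f"out-of-order event at {event.time}s (state entered at {status.entered_at}s)")
    seq = _state_sequence(status, patient, event, cfg)
    if not seq:
        return status
    return ScenarioStatus(seq[-1], event.time)


# ---------------------------------------------------------------------------
# engine

def run_engine(actions: Sequence[ActionEvent], initial_rhythm: Rhythm,
               cfg: GuidelineConfig | None = None,
               profile_cc_output: float = 1.5,
               physio_sample_interval: int = 5,
               horizon: int = 600) -> tuple[EventLog, PhysioLog, DrugLog]:
    """Replay an action stream through the state machine; emit the three logs.

    Deterministic: identical inputs yield byte-identical logs.  Vital signs
    are sampled every ``physio_sample_interval`` seconds, at the start of
    the second and before any action at that instant (the sample at the
    ROSC second therefore still shows pre-shock physiology).  The scenario
    ends at ROSC or at ``horizon``, whichever comes first; the final event
    record is always the EXIT state entry.
    """
    cfg = cfg or GuidelineConfig()
    if physio_sample_interval <= 0:
        raise ValueError("physio_sample_interval must be positive")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    _validate_actions(actions, horizon)

    patient = initialize_patient(initial_rhythm)
    status = ScenarioStatus(ScenarioState.NO_CC, 0)
    compressions = False
    last_cc_stop = 0          # compressions "last stopped" at t=0 if never started
    events: list[EventRecord] = [
        EventRecord(0, EventCode.RHYTHM, patient.rhythm.value),
        EventRecord(0, EventCode.STATE, status.state.value),
    ]
    physio: list[PhysioSample] = []
    drugs: list[DrugRecord] = []

    # unified timeline: (time, priority, payload); degradation is checked
    # before every item, samples precede actions at the same second.
    items: list[tuple[int, int, object]] = [
        (t, 1, "sample") for t in range(0, horizon + 1, physio_sample_interval)
    ]
    items += [(a.time, 2, a) for a in actions]
    items.append((horizon, 3, "end"))
    items.sort(key=lambda item: (item[0], item[1]))

    def maybe_degrade(t_item: int) -> None:
        nonlocal patient
        if patient.rhythm in SHOCKABLE and not compressions:
            due = math.floor(last_cc_stop + cfg.asystole_degeneration_timeout) + 1
            if due <= t_item:
                patient = replace(patient, no_cc_elapsed=float(due - last_cc_stop))
                patient = degrade_to_asystole(patient, cfg)
                events.append(EventRecord(due, EventCode.RHYTHM, patient.rhythm.value))

    for t, _prio, payload in items:
        maybe_degrade(t)

        if payload == "sample":
            physio.append(_sample(t, patient, compressions, profile_cc_output))
            continue
        if payload == "end":
            events.append(EventRecord(t, EventCode.STATE, ScenarioState.EXIT.value))
            break

        action: ActionEvent = payload  # type: ignore[assignment]

        if action.kind is ActionKind.CC_START:
            if compressions:
                continue  # duplicate start: idempotent
            compressions = True
            patient = surrogate_hemodynamics(patient, True, profile_cc_output)
            patient = condition_on_compressions(patient, True)
            events.append(EventRecord(t, EventCode.CC_ON))
            status = _enter(events, status, _state_sequence(status, patient, action, cfg), t)

        elif action.kind is ActionKind.CC_STOP:
            if not compressions:
                continue
            compressions = False
            last_cc_stop = t
            patient = surrogate_hemodynamics(patient, False, profile_cc_output)
            events.append(EventRecord(t, EventCode.CC_OFF))
            status = _enter(events, status, _state_sequence(status, patient, action, cfg), t)

        elif action.kind is ActionKind.VENTILATION:
            events.append(EventRecord(t, EventCode.VENT))
            status = _enter(events, status, _state_sequence(status, patient, action, cfg), t)

        elif action.kind is ActionKind.MARKER:
            events.append(EventRecord(t, EventCode.MARKER, action.marker.value))
            patient = apply_marker(patient, action.marker)
            patient = condition_on_compressions(patient, compressions)
            if action.marker in _MARKER_DRUG:
                drug, dose = _MARKER_DRUG[action.marker]
                drugs.append(DrugRecord(t, drug, dose))
            status = _enter(events, status, _state_sequence(status, patient, action, cfg), t)
            # automatic pass-through: compressions still running re-enter CC
            if compressions and patient.sbp > cfg.cc_sbp_threshold:
                status = _enter(events, status, [ScenarioState.CC], t)

        elif action.kind is ActionKind.DEFIBRILLATION:
            cls = classify_defibrillation(patient.rhythm, action.energy,
                                          cfg.shock_energy_floor)
            if cls is DefibClass.IGNORED:
                events.append(EventRecord(
                    t, EventCode.WARN,
                    f"shock {action.energy:g}J at or below {cfg.shock_energy_floor:g}J floor ignored"))
                continue
            if action.energy > cfg.shock_energy_cap:
                events.append(EventRecord(
                    t, EventCode.WARN,
                    f"shock {action.energy:g}J above advisory {cfg.shock_energy_cap:g}J cap"))
            events.append(EventRecord(t, EventCode.DEFIB,
                                      format_defib_detail(action.energy, cls.value)))
            before = patient.rhythm
            patient = defibrillation_outcome(patient, action.energy, cfg)
            seq = _state_sequence(status, replace(patient, rhythm=before), action, cfg)
            converted = patient.rhythm is Rhythm.SR and before in SHOCKABLE
            status = _enter(events, status, seq[:2], t)
            if converted:
                patient = surrogate_hemodynamics(patient, compressions, profile_cc_output)
                events.append(EventRecord(t, EventCode.RHYTHM, Rhythm.SR.value))
                events.append(EventRecord(t, EventCode.ROSC))
                status = _enter(events, status, [ScenarioState.EXIT], t)
                break
            status = _enter(events, status, seq[2:], t)

        else:  # pragma: no cover - ActionEvent validation forbids this
            raise ValueError(f"unknown action kind {action.kind!r}")

    return EventLog(events), PhysioLog(physio), DrugLog(drugs)


def _enter(events: list[EventRecord], status: ScenarioStatus,
           seq: Sequence[ScenarioState], t: int) -> ScenarioStatus:
    for state in seq:
        events.append(EventRecord(t, EventCode.STATE, state.value))
        status = ScenarioStatus(state, t)
    return status


def _sample(t: int, patient: PatientState, compressions: bool,
            cc_output: float) -> PhysioSample:
    if patient.rhythm is Rhythm.SR:
        return PhysioSample(t, _POST_ROSC_HR, POST_ROSC_SBP, _POST_ROSC_DBP,
                            POST_ROSC_CO, _POST_ROSC_SPO2)
    if compressions:
        return PhysioSample(t, 0.0, CPR_SBP, _CPR_DBP, cc_output, _CPR_SPO2)
    return PhysioSample(t, 0.0, 0.0, 0.0, 0.0, _ARREST_SPO2)


def _validate_actions(actions: Sequence[ActionEvent], horizon: int) -> None:
    prev = 0
    for a in actions:
        if not isinstance(a, ActionEvent):
            raise TypeError(f"expected ActionEvent, got {type(a).__name__}")
        if a.time < prev:
            raise ValueError(f"action stream not time-sorted at t={a.time}")
        if a.time > horizon:
            raise ValueError(f"action at t={a.time} beyond horizon {horizon}")
        prev = a.time
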