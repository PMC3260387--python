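"""Synthetic rescuer-team behaviour: parameterized action-stream generator.

A :class:`TeamProfile` abstracts how a three-person prehospital team works
an arrest: how soon they deliver the first shock and at what cycle length
thereafter, how long their compression segments and hands-off pauses are,
how long they clear the patient around each shock, their bag-mask
ventilation rate, and when they secure IV access, intubate and give drugs.
Durations and intervals are drawn from normal distributions truncated at
zero and rounded to whole seconds, so profiles with zero spread produce
exactly predictable schedules (the basis of the parameter-recovery tests).

The generator emulates behaviour only at the event level — no compression
depth/rate waveforms, no cognition; see ``docs/methods.md``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np

from ._flatfile import read_flat, write_flat
from .engine import (
    ActionEvent,
    ActionKind,
    GuidelineConfig,
    Marker,
    Rhythm,
    run_engine,
)
from .log_io import DrugLog, EventLog, PhysioLog
from .metrics import MetricsReport, compute_metrics

# processing order of simultaneous events (stable within one second)
_KIND_PRIORITY = {
    ActionKind.CC_STOP: 0,
    ActionKind.MARKER: 1,
    ActionKind.VENTILATION: 2,
    ActionKind.DEFIBRILLATION: 3,
    ActionKind.CC_START: 4,
}


@dataclass(frozen=True)
class TeamProfile:
    """Behaviour parameters of one synthetic rescuer team (times in s)."""

    t_first_defib_mean: float = 120.0
    t_first_defib_sd: float = 0.0
    shock_interval_mean: float = 150.0
    shock_interval_sd: float = 0.0
    peri_shock_pause: int = 10          # hands-off carve-out before each shock
    cc_segment_mean: float = 60.0
    cc_segment_sd: float = 0.0
    cc_pause_mean: float = 10.0
    cc_pause_sd: float = 0.0
    vent_rate: float = 1.0              # bag-mask ventilations per minute
    t_iv: float | None = 180.0
    t_intubation: float | None = 300.0
    t_epi1: float | None = 400.0
    t_epi2: float | None = 560.0
    t_amiodarone: float | None = None
    t_atropine: float | None = None
    cc_output: float = 1.5              # cardiac output during compressions, L/min
    shock_energy: float = 150.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("t_first_defib_sd", "shock_interval_sd", "cc_segment_sd",
                     "cc_pause_sd", "vent_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("t_first_defib_mean", "shock_interval_mean", "cc_segment_mean",
                     "cc_pause_mean", "peri_shock_pause", "shock_energy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("t_iv", "t_intubation", "t_epi1", "t_epi2",
                     "t_amiodarone", "t_atropine"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be >= 0 or None")
        if not 0 < self.cc_output <= 3:
            raise ValueError("cc_output must be in (0, 3] L/min")
        if (self.t_epi1 is not None and self.t_epi2 is not None
                and self.t_epi2 < self.t_epi1):
            warnings.warn("second adrenaline dose scheduled before the first",
                          stacklevel=2)


def _draw(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Truncated-normal draw (at 0), rounded to whole seconds; exact at sd=0."""
    x = mean if sd == 0 else max(0.0, float(rng.normal(mean, sd)))
    return int(round(x))


def generate_actions(profile: TeamProfile, horizon: int) -> list[ActionEvent]:
    """Reproducible, time-sorted action stream over ``[0, horizon)`` seconds."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    profile.validate()
    rng = np.random.default_rng(profile.seed)

    # compression timetable: alternating segments and pauses from t=0;
    # a zero-mean, zero-spread segment length means the team never compresses
    comp = np.zeros(horizon, dtype=bool)
    no_compressions = profile.cc_segment_mean == 0 and profile.cc_segment_sd == 0
    t, on = 0, True
    while t < horizon and not no_compressions:
        if on:
            dur = max(1, _draw(rng, profile.cc_segment_mean, profile.cc_segment_sd))
        else:
            dur = _draw(rng, profile.cc_pause_mean, profile.cc_pause_sd)
        comp[t:t + dur] = on
        t += dur
        on = not on

    # shock schedule; rescuers clear the patient for peri_shock_pause seconds
    shocks: list[int] = []
    s = _draw(rng, profile.t_first_defib_mean, profile.t_first_defib_sd)
    while s < horizon:
        shocks.append(s)
        s += max(1, _draw(rng, profile.shock_interval_mean, profile.shock_interval_sd))
    for s in shocks:
        comp[max(0, s - profile.peri_shock_pause):s] = False

    actions: list[ActionEvent] = []
    prev = False
    for tt in range(horizon):
        if comp[tt] and not prev:
            actions.append(ActionEvent(tt, ActionKind.CC_START))
        elif prev and not comp[tt]:
            actions.append(ActionEvent(tt, ActionKind.CC_STOP))
        prev = bool(comp[tt])

    for s in shocks:
        actions.append(ActionEvent(s, ActionKind.DEFIBRILLATION,
                                   energy=profile.shock_energy))

    # bag-mask ventilations at the profile rate until intubation
    if profile.vent_rate > 0:
        cutoff = horizon if profile.t_intubation is None else min(
            horizon, profile.t_intubation)
        period = 60.0 / profile.vent_rate
        k = 0
        while round(k * period) < cutoff:
            actions.append(ActionEvent(int(round(k * period)), ActionKind.VENTILATION))
            k += 1

    for when, marker in ((profile.t_iv, Marker.IV_LINE),
                         (profile.t_intubation, Marker.INTUBATION),
                         (profile.t_epi1, Marker.EPI_1),
                         (profile.t_epi2, Marker.EPI_2),
                         (profile.t_amiodarone, Marker.AMIODARONE),
                         (profile.t_atropine, Marker.ATROPINE)):
        if when is not None and when < horizon:
            actions.append(ActionEvent(int(round(when)), ActionKind.MARKER,
                                       marker=marker))

    actions.sort(key=lambda a: (a.time, _KIND_PRIORITY[a.kind]))
    return actions


def run_scenario(profile: TeamProfile, initial_rhythm: Rhythm = Rhythm.CVF,
                 cfg: GuidelineConfig | None = None, horizon: int = 1200,
                 physio_sample_interval: int = 5,
                 ) -> tuple[EventLog, PhysioLog, DrugLog, MetricsReport]:
    """End-to-end: generate behaviour, replay it, extract the metrics."""
    actions = generate_actions(profile, horizon)
    event_log, physio_log, drug_log = run_engine(
        actions, initial_rhythm, cfg,
        profile_cc_output=profile.cc_output,
        physio_sample_interval=physio_sample_interval,
        horizon=horizon)
    report = compute_metrics(event_log, physio_log, drug_log, cfg)
    return event_log, physio_log, drug_log, report


# ---------------------------------------------------------------------------
# profile files

_NONE_FIELDS = {"t_iv", "t_intubation", "t_epi1", "t_epi2",
                "t_amiodarone", "t_atropine"}
_INT_FIELDS = {"peri_shock_pause", "seed"}


def load_profile(path: str | Path) -> TeamProfile:
    raw = read_flat(path)
    kwargs: dict[str, object] = {}
    for key, value in raw.items():
        if key in _NONE_FIELDS and value.lower() in ("none", "na", ""):
            kwargs[key] = None
        elif key in _INT_FIELDS:
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    profile = TeamProfile(**kwargs)  # raises on unknown keys
    profile.validate()
    return profile


def save_profile(profile: TeamProfile, path: str | Path) -> None:
    write_flat(path, {
        name: getattr(profile, name)
        for name in TeamProfile.__dataclass_fields__})


def fixture_profiles() -> dict[str, TeamProfile]:
    """Five shipped example team profiles, tuned to the order of magnitude
    of a real professional cohort (not fitted to any particular team)."""
    base = resources.files("cprsim") / "fixtures" / "profiles"
    profiles = {}
    for entry in sorted(base.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".cfg"):
            with resources.as_file(entry) as path:
                profiles[entry.name[:-4]] = load_profile(path)
    return profiles
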