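"""Unit tests for the scenario state machine and its elementary operations."""

import dataclasses

import pytest

from cprsim.engine import (
    ActionEvent,
    ActionKind,
    DefibClass,
    GuidelineConfig,
    Marker,
    Rhythm,
    ScenarioState,
    ScenarioStatus,
    apply_marker,
    classify_defibrillation,
    condition_on_compressions,
    defibrillation_outcome,
    degrade_to_asystole,
    initialize_patient,
    run_engine,
    surrogate_hemodynamics,
    transition,
)
from cprsim.log_io import EventCode


def _cc(t):
    return ActionEvent(t, ActionKind.CC_START)


def _stop(t):
    return ActionEvent(t, ActionKind.CC_STOP)


def _shock(t, e=150.0):
    return ActionEvent(t, ActionKind.DEFIBRILLATION, energy=e)


def _mark(t, m):
    return ActionEvent(t, ActionKind.MARKER, marker=m)


class TestInitializePatient:
    @pytest.mark.parametrize("rhythm", [Rhythm.ASY, Rhythm.CVF, Rhythm.PVT])
    def test_baseline_values(self, rhythm):
        p = initialize_patient(rhythm)
        assert p.rhythm is rhythm
        assert p.cardiac_output == 0
        assert p.sbp == 0
        assert p.nmb == 100
        assert p.fio2 == 0.80
        assert p.iia == 0.99
        assert p.iis == 0.5
        assert p.cf_lv == 0.5 and p.cf_rv == 0.5
        assert not p.drug_conditioning_armed

    def test_patients_differ_only_in_rhythm(self):
        a = initialize_patient(Rhythm.CVF)
        b = initialize_patient(Rhythm.ASY)
        assert dataclasses.replace(a, rhythm=Rhythm.ASY) == b

    def test_sinus_start_rejected(self):
        with pytest.raises(ValueError):
            initialize_patient(Rhythm.SR)


class TestClassifyDefibrillation:
    @pytest.mark.parametrize("rhythm,energy,expected", [
        (Rhythm.CVF, 150, DefibClass.INDICATED),
        (Rhythm.PVT, 11, DefibClass.INDICATED),
        (Rhythm.SR, 150, DefibClass.NON_INDICATED),
        (Rhythm.ASY, 200, DefibClass.NON_INDICATED),
        (Rhythm.CVF, 10, DefibClass.IGNORED),    # "more than 10 J" is strict
        (Rhythm.ASY, 5, DefibClass.IGNORED),
    ])
    def test_classification(self, rhythm, energy, expected):
        assert classify_defibrillation(rhythm, energy, floor=10) is expected

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            classify_defibrillation(Rhythm.CVF, -1)


class TestMarkersAndConditioning:
    @pytest.mark.parametrize("marker", [Marker.EPI_2, Marker.AMIODARONE])
    def test_arming_markers(self, marker):
        p = apply_marker(initialize_patient(Rhythm.CVF), marker)
        assert p.iis == 0.5
        assert p.drug_conditioning_armed

    def test_atropine_raises_right_ventricular_contractility(self):
        p = apply_marker(initialize_patient(Rhythm.CVF), Marker.ATROPINE)
        assert p.cf_rv == 0.8
        assert not p.drug_conditioning_armed

    @pytest.mark.parametrize("marker", [Marker.IV_LINE, Marker.INTUBATION, Marker.EPI_1])
    def test_timestamp_only_markers(self, marker):
        base = initialize_patient(Rhythm.CVF)
        assert apply_marker(base, marker) == base

    def test_repeated_clicks_idempotent(self):
        once = apply_marker(initialize_patient(Rhythm.CVF), Marker.EPI_2)
        assert apply_marker(once, Marker.EPI_2) == once

    def test_compressions_after_arming_raise_cf_lv(self):
        armed = apply_marker(initialize_patient(Rhythm.CVF), Marker.EPI_2)
        assert condition_on_compressions(armed, True).cf_lv == 0.8
        assert condition_on_compressions(armed, False).cf_lv == 0.5

    def test_compressions_without_arming_do_nothing(self):
        base = initialize_patient(Rhythm.CVF)
        assert condition_on_compressions(base, True).cf_lv == 0.5


class TestShockOutcome:
    @pytest.mark.parametrize("rhythm", list(Rhythm))
    @pytest.mark.parametrize("cf_lv", [0.5, 0.8])
    @pytest.mark.parametrize("energy", [5.0, 10.0, 11.0, 150.0, 250.0])
    def test_conversion_gate_exhaustive(self, rhythm, cf_lv, energy, cfg):
        """Shock converts iff rhythm is shockable AND cf_lv=0.8 AND E>10 J."""
        state = dataclasses.replace(
            initialize_patient(Rhythm.CVF), rhythm=rhythm, cf_lv=cf_lv)
        out = defibrillation_outcome(state, energy, cfg)
        should_convert = (rhythm in (Rhythm.CVF, Rhythm.PVT)
                          and cf_lv == 0.8 and energy > 10)
        assert (out.rhythm is Rhythm.SR) == (should_convert or rhythm is Rhythm.SR)
        if not should_convert:
            assert out.rhythm is state.rhythm


class TestDegeneration:
    @pytest.mark.parametrize("rhythm,elapsed,expect_asy", [
        (Rhythm.PVT, 61, True),
        (Rhythm.CVF, 61, True),
        (Rhythm.CVF, 60, False),   # strictly more than 60 s
        (Rhythm.CVF, 59, False),
        (Rhythm.SR, 300, False),
        (Rhythm.ASY, 300, False),
    ])
    def test_timeout_boundary(self, rhythm, elapsed, expect_asy, cfg):
        state = dataclasses.replace(
            initialize_patient(Rhythm.CVF), rhythm=rhythm, no_cc_elapsed=elapsed)
        out = degrade_to_asystole(state, cfg)
        if expect_asy:
            assert out.rhythm is Rhythm.ASY
        else:
            assert out.rhythm is rhythm


class TestSurrogateKernel:
    def test_three_regimes(self):
        arrest = initialize_patient(Rhythm.CVF)
        cpr = surrogate_hemodynamics(arrest, True, 1.5)
        assert (cpr.sbp, cpr.cardiac_output) == (60.0, 1.5)
        noflow = surrogate_hemodynamics(arrest, False, 1.5)
        assert (noflow.sbp, noflow.cardiac_output) == (0.0, 0.0)
        sinus = surrogate_hemodynamics(
            dataclasses.replace(arrest, rhythm=Rhythm.SR), False, 1.5)
        assert (sinus.sbp, sinus.cardiac_output) == (120.0, 5.0)
        assert sinus.cardiac_output > 0  # SR implies perfusion


class TestTransition:
    def test_cc_start_enters_cc_when_pressure_clears_gate(self, cfg):
        status = ScenarioStatus(ScenarioState.NO_CC, 0)
        out = transition(status, initialize_patient(Rhythm.CVF), _cc(10), cfg)
        assert out.state is ScenarioState.CC and out.entered_at == 10

    def test_cc_start_ineffective_below_gate(self):
        # raise the gate above the CPR kernel pressure of 60 mmHg
        cfg = GuidelineConfig(cc_sbp_threshold=60.0)
        status = ScenarioStatus(ScenarioState.NO_CC, 0)
        out = transition(status, initialize_patient(Rhythm.CVF), _cc(10), cfg)
        assert out.state is ScenarioState.INEFFECTIVE_RESUSCITATION

    def test_marker_returns_to_no_cc(self, cfg):
        status = ScenarioStatus(ScenarioState.CC, 5)
        out = transition(status, initialize_patient(Rhythm.CVF),
                         _mark(20, Marker.EPI_1), cfg)
        assert out.state is ScenarioState.NO_CC

    def test_ventilation_returns_to_prior_compression_state(self, cfg):
        patient = initialize_patient(Rhythm.CVF)
        vent = ActionEvent(30, ActionKind.VENTILATION)
        assert transition(ScenarioStatus(ScenarioState.CC, 5), patient,
                          vent, cfg).state is ScenarioState.CC
        assert transition(ScenarioStatus(ScenarioState.NO_CC, 5), patient,
                          vent, cfg).state is ScenarioState.NO_CC

    def test_out_of_order_event_rejected(self, cfg):
        with pytest.raises(ValueError, match="out-of-order"):
            transition(ScenarioStatus(ScenarioState.CC, 50),
                       initialize_patient(Rhythm.CVF), _cc(10), cfg)


class TestRunEngine:
    def test_empty_stream_degenerates_and_exits(self, cfg):
        ev, ph, dr = run_engine([], Rhythm.CVF, cfg, horizon=600)
        codes = [(r.time, r.code, r.detail) for r in ev]
        assert codes[0] == (0, EventCode.RHYTHM, "cVF")
        assert codes[1] == (0, EventCode.STATE, "NO_CC")
        assert (61, EventCode.RHYTHM, "ASY") in codes
        assert codes[-1] == (600, EventCode.STATE, "EXIT")
        assert all(s.cardiac_output == 0 for s in ph)
        assert dr.records == []

    def test_single_cc_start_flows_from_then_on(self, cfg):
        ev, ph, dr = run_engine([_cc(10)], Rhythm.CVF, cfg,
                                profile_cc_output=1.5, horizon=600)
        codes = [(r.time, r.code) for r in ev]
        assert (10, EventCode.CC_ON) in codes
        assert (10, EventCode.STATE) in codes
        assert not any(r.code is EventCode.RHYTHM and r.detail == "ASY" for r in ev)
        # samples strictly after the start carry the CPR flow
        assert all(s.cardiac_output == 1.5 for s in ph if s.time > 10)
        assert all(s.cardiac_output == 0.0 for s in ph if s.time <= 10)

    def test_deterministic_replay(self, cfg):
        actions = [_cc(5), _stop(65), _mark(70, Marker.EPI_2), _cc(80), _shock(100)]
        out1 = run_engine(actions, Rhythm.CVF, cfg, horizon=300)
        out2 = run_engine(actions, Rhythm.CVF, cfg, horizon=300)
        assert out1 == out2

    def test_unsorted_actions_rejected(self, cfg):
        with pytest.raises(ValueError, match="not time-sorted"):
            run_engine([_cc(50), _stop(10)], Rhythm.CVF, cfg)

    def test_effective_shock_chain_reaches_rosc(self, cfg):
        """Drugs -> compressions -> shock converts; the scenario ends there."""
        actions = [_cc(0), _mark(30, Marker.EPI_2), _shock(50)]
        ev, ph, dr = run_engine(actions, Rhythm.CVF, cfg, horizon=600)
        assert any(r.code is EventCode.ROSC and r.time == 50 for r in ev)
        last = ev.records[-1]
        assert (last.time, last.code, last.detail) == (50, EventCode.STATE, "EXIT")
        assert max(s.time for s in ph) <= 50
        assert any(d.drug.value == "adrenaline" for d in dr)

    def test_shock_without_arming_never_converts(self, cfg):
        actions = [_cc(0), _shock(50), _shock(170), _shock(290)]
        ev, _, _ = run_engine(actions, Rhythm.CVF, cfg, horizon=400)
        assert not any(r.code is EventCode.ROSC for r in ev)

    def test_defib_state_entries_match_recorded_shocks(self, cfg):
        """DEFIB_INDICATED + DEFIB_NON_INDICATED entries == shocks above floor."""
        actions = [_shock(20, 5.0), _shock(30, 150.0), _shock(40, 250.0),
                   _shock(100, 150.0)]
        ev, _, _ = run_engine(actions, Rhythm.CVF, cfg, horizon=300)
        n_defib_states = sum(1 for r in ev if r.code is EventCode.STATE
                             and r.detail in ("DEFIB_INDICATED", "DEFIB_NON_INDICATED"))
        n_recorded = sum(1 for r in ev if r.code is EventCode.DEFIB)
        assert n_defib_states == n_recorded == 3
        # the 5 J shock is ignored with a warning; the 250 J one flagged
        warns = [r.detail for r in ev if r.code is EventCode.WARN]
        assert any("ignored" in w for w in warns)
        assert any("cap" in w for w in warns)
        # rhythm degenerated at 61 s without compressions: last shock non-indicated
        details = [r.detail for r in ev if r.code is EventCode.DEFIB]
        assert details == ["150J indicated", "250J indicated", "150J non_indicated"]

    def test_degenerated_arrest_is_absorbing(self, cfg):
        """No compressions: asystole by timeout, and no later shock converts."""
        actions = [_mark(30, Marker.EPI_2), _shock(100), _shock(220), _shock(340)]
        ev, _, _ = run_engine(actions, Rhythm.PVT, cfg, horizon=600)
        assert any(r.code is EventCode.RHYTHM and r.detail == "ASY" and r.time == 61
                   for r in ev)
        assert not any(r.code is EventCode.ROSC for r in ev)
        details = [r.detail for r in ev if r.code is EventCode.DEFIB]
        assert all(d.endswith("non_indicated") for d in details)

    def test_marker_states_return_to_no_cc_and_do_not_touch_physiology(self, cfg):
        actions = [_cc(0), _mark(40, Marker.IV_LINE)]
        ev, ph, _ = run_engine(actions, Rhythm.CVF, cfg, horizon=120)
        states = [(r.time, r.detail) for r in ev if r.code is EventCode.STATE]
        i = states.index((40, "MARKER_IV_LINE"))
        assert states[i + 1] == (40, "NO_CC")
        assert states[i + 2] == (40, "CC")  # compressions ongoing: automatic re-entry
        assert all(s.cardiac_output == 1.5 for s in ph if s.time > 0)
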