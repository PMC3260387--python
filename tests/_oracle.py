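"""Independent brute-force oracle: a per-second scan of a raw action stream.

Recomputes the scenario outcome and performance metrics directly from the
action list with a flat second-by-second loop, touching neither the engine's
state machine nor the metrics extractor.  Used to cross-check the full
pipeline (actions -> engine -> logs -> metrics) on random streams.
"""

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from cprsim.engine import ActionKind, Marker, Rhythm


@dataclass
class OracleResult:
    window_end: int
    no_flow_time: float
    no_flow_fraction: float
    time_to_rosc: int | None
    t_first_defib: int | None
    n_indicated: int
    n_non_indicated: int
    mean_interval: float | None
    mean_abs_dev: float | None
    median_co: float | None
    t_first_epi: int | None
    n_vents: int
    vent_frequency: float | None


def brute_force_metrics(actions, initial_rhythm: Rhythm, cc_output: float,
                        horizon: int, interval: int = 5, floor: float = 10.0,
                        timeout: float = 60.0, target: float = 120.0) -> OracleResult:
    by_time = defaultdict(list)
    for a in actions:
        by_time[a.time].append(a)

    shockable = {Rhythm.CVF, Rhythm.PVT}
    rhythm = initial_rhythm
    comp = False
    last_stop = 0
    armed = False
    cf_lv = 0.5
    shock_times: list[int] = []
    shock_classes: list[str] = []
    vent_times: list[int] = []
    epi1_time = None
    any_epi_time = None
    intubation_time = None
    rosc = None
    co_samples: list[float] = []
    flow = np.zeros(horizon, dtype=bool)

    for t in range(horizon + 1):
        # degeneration: strictly more than `timeout` s without compressions
        if rhythm in shockable and not comp and t - last_stop > timeout:
            rhythm = Rhythm.ASY
        # physio sampling at the start of the second, before actions
        if t % interval == 0:
            co_samples.append((t, cc_output if comp else 0.0))
        for a in by_time.get(t, ()):
            if a.kind is ActionKind.CC_START:
                comp = True
                if armed:
                    cf_lv = 0.8
            elif a.kind is ActionKind.CC_STOP:
                comp = False
                last_stop = t
            elif a.kind is ActionKind.VENTILATION:
                vent_times.append(t)
            elif a.kind is ActionKind.MARKER:
                if a.marker in (Marker.EPI_2, Marker.AMIODARONE):
                    armed = True
                    if comp:
                        cf_lv = 0.8
                if a.marker is Marker.EPI_1 and epi1_time is None:
                    epi1_time = t
                if a.marker in (Marker.EPI_1, Marker.EPI_2) and any_epi_time is None:
                    any_epi_time = t
                if a.marker is Marker.INTUBATION and intubation_time is None:
                    intubation_time = t
            elif a.kind is ActionKind.DEFIBRILLATION:
                if a.energy > floor:
                    shock_times.append(t)
                    shock_classes.append(
                        "indicated" if rhythm in shockable else "non_indicated")
                    if rhythm in shockable and cf_lv == 0.8:
                        rosc = t
            if rosc is not None:
                break
        if rosc is not None:
            break
        if t < horizon:
            flow[t] = comp

    end = rosc if rosc is not None else horizon
    nft = float(end - int(flow[:end].sum()))

    n_ind = shock_classes.count("indicated")
    n_non = len(shock_classes) - n_ind
    if len(shock_times) >= 2:
        diffs = np.diff(shock_times)
        mean_interval = (shock_times[-1] - shock_times[0]) / (len(shock_times) - 1)
        mad = float(np.mean(np.abs(diffs - target)))
    else:
        mean_interval = mad = None

    co_in_window = [v for (ts, v) in co_samples if ts <= end]
    median_co = float(np.median(co_in_window)) if co_in_window else None

    t_epi = epi1_time if epi1_time is not None else any_epi_time
    cutoff = intubation_time if intubation_time is not None else end
    n_vents = sum(1 for v in vent_times if v < cutoff)
    vent_freq = n_vents / (cutoff / 60.0) if cutoff > 0 else None

    return OracleResult(
        window_end=end,
        no_flow_time=nft,
        no_flow_fraction=nft / end if end > 0 else 1.0,
        time_to_rosc=rosc,
        t_first_defib=shock_times[0] if shock_times else None,
        n_indicated=n_ind,
        n_non_indicated=n_non,
        mean_interval=mean_interval,
        mean_abs_dev=mad,
        median_co=median_co,
        t_first_epi=t_epi,
        n_vents=n_vents,
        vent_frequency=vent_freq,
    )
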