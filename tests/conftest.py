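from __future__ import annotations

import numpy as np
import pytest

from reacharc import (
    Crossing,
    ProtocolConfig,
    ReachSurface,
    SessionLog,
    TargetSpec,
    TrialRecord,
    Vec3,
    default_surface,
)


@pytest.fixture
def surface() -> ReachSurface:
    return default_surface(0.6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_log(
    errors_by_condition: dict[str, list[float]],
    times_by_condition: dict[str, list[float]] | None = None,
    experiment: str = "visible_invisible",
    participant_id: str = "T01",
    n_practice: int = 0,
) -> SessionLog:
    """Hand-built session with prescribed error/time sequences per condition.

    Trials are interleaved round-robin across conditions in presentation
    order; geometry fields are placeholders (errors are set directly), which
    is all metrics/stats need.
    """
    surface = default_surface(0.6)
    conditions = list(errors_by_condition)
    n_per = {c: len(v) for c, v in errors_by_condition.items()}
    protocol = ProtocolConfig(
        experiment=experiment,
        n_trials_per_condition=max(n_per.values()),
        n_practice=max(n_practice, 0),
    )
    target = TargetSpec(azimuth=0.0, elevation=0.0, cartesian=surface.surface_point(0, 0))
    trials: list[TrialRecord] = []
    idx = 0
    remaining = {c: 0 for c in conditions}
    total = sum(n_per.values())
    while idx < total:
        for c in conditions:
            i = remaining[c]
            if i >= n_per[c]:
                continue
            err = float(errors_by_condition[c][i])
            t_ms = (
                float(times_by_condition[c][i])
                if times_by_condition is not None
                else 600.0 + i
            )
            trials.append(
                TrialRecord(
                    trial_index=idx,
                    phase="experimental",
                    condition=c,
                    target=target,
                    crossing=Crossing(point=surface.surface_point(err, 0.0), time_ms=t_ms),
                    error_deg=err,
                    error_azimuth_deg=err,
                    error_elevation_deg=0.0,
                    reach_time_ms=t_ms,
                    valid=True,
                )
            )
            remaining[c] += 1
            idx += 1
    return SessionLog(
        participant_id=participant_id,
        protocol=protocol,
        surface=surface,
        trials=trials,
    )
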