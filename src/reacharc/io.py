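"""File formats: trial-log CSV, trajectory JSON Lines, run configuration.

Trial logs are long-format CSV with a fixed, ordered header (one row per
trial); angles are stored in degrees, positions in metres, times in
milliseconds, all numerics at 12 significant digits so logs round-trip with
in-memory sessions to 1e-9.  Files written by this package may start with a
single ``#`` comment line embedding the config hash and seed of the run
that produced them; readers skip it.

Deposited logs from other acquisition software can be ingested through a
``column_mapping`` that renames their columns onto this schema; error
columns absent from the source are recomputed from the target and endpoint
angles and the session is flagged accordingly.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import OrderingError, SchemaError
from .geometry import Crossing, ReachSurface, TargetSpec, Trajectory, Vec3
from .simulate import (
    DurationModel,
    EndpointModel,
    EndpointPopulation,
    PopulationParams,
    ProtocolConfig,
    ReacherParams,
    SessionLog,
    TrialRecord,
    conditions_for,
    exp1_population,
    exp2_population,
    null_population,
    patient_reacher,
)

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "write_trial_log",
    "read_trial_log",
    "write_trajectories",
    "read_trajectories",
    "RunConfig",
    "load_config",
    "config_hash",
]

TRIAL_LOG_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "experiment",
    "phase",
    "trial_index",
    "condition",
    "target_azimuth_deg",
    "target_elevation_deg",
    "radius_m",
    "endpoint_azimuth_deg",
    "endpoint_elevation_deg",
    "error_deg",
    "error_azimuth_deg",
    "error_elevation_deg",
    "reach_time_ms",
    "valid",
)

_REQUIRED_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "experiment",
    "phase",
    "trial_index",
    "condition",
    "target_azimuth_deg",
    "target_elevation_deg",
    "radius_m",
    "endpoint_azimuth_deg",
    "endpoint_elevation_deg",
    "reach_time_ms",
)

_FMT = "%.12g"


def _fmt(v: float) -> str:
    return _FMT % v


def write_trial_log(
    logs: SessionLog | Sequence[SessionLog],
    path: str | Path,
    header_comment: str | None = None,
) -> Path:
    """Write one or more sessions to a trial-log CSV.

    Rows are ordered by (participant, phase, trial index) — deterministic,
    so two writes of the same sessions are byte-identical.  An optional
    ``header_comment`` (e.g. config hash and seed) is written as a single
    leading ``#`` line.
    """
    if isinstance(logs, SessionLog):
        logs = [logs]
    path = Path(path)
    lines: list[str] = []
    if header_comment is not None:
        lines.append("# " + header_comment.replace("\n", " "))
    lines.append(",".join(TRIAL_LOG_COLUMNS))
    for log in sorted(logs, key=lambda s: s.participant_id):
        surface = log.surface
        for phase in ("experimental", "practice"):
            recs = [t for t in log.trials if t.phase == phase]
            for t in sorted(recs, key=lambda r: r.trial_index):
                if t.crossing is not None:
                    e_az, e_el = surface.angles_of(t.crossing.point)
                else:
                    e_az, e_el = math.nan, math.nan
                lines.append(
                    ",".join(
                        [
                            log.participant_id,
                            log.protocol.experiment,
                            phase,
                            str(t.trial_index),
                            t.condition,
                            _fmt(t.target.azimuth),
                            _fmt(t.target.elevation),
                            _fmt(surface.radius),
                            _fmt(e_az),
                            _fmt(e_el),
                            _fmt(t.error_deg),
                            _fmt(t.error_azimuth_deg),
                            _fmt(t.error_elevation_deg),
                            _fmt(t.reach_time_ms),
                            "1" if t.valid else "0",
                        ]
                    )
                )
    path.write_text("\n".join(lines) + "\n")
    return path


def _check_monotone(group: pd.DataFrame, pid: str, phase: str) -> None:
    idx = group["trial_index"].to_numpy()
    if idx.size and not np.all(np.diff(idx) > 0):
        raise OrderingError(
            f"participant {pid!r}, phase {phase!r}: trial_index not strictly "
            "increasing"
        )


def read_trial_log(
    path: str | Path,
    column_mapping: Mapping[str, str] | None = None,
) -> list[SessionLog]:
    """Read a trial-log CSV into SessionLog objects (one per participant).

    ``column_mapping`` renames source columns onto the canonical schema
    (``{"their_name": "canonical_name"}``) before validation, so externally
    deposited logs can be ingested without code changes.  Missing error
    columns are recomputed from target and endpoint angles via the surface
    geometry and noted on the session.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty trial log") from None
    if column_mapping:
        df = df.rename(columns=dict(column_mapping))
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no trial rows")

    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.phase not in ("practice", "experimental"):
            problems.append(f"line {i}: unknown phase {row.phase!r}")
        if not math.isfinite(row.radius_m) or row.radius_m <= 0:
            problems.append(f"line {i}: bad radius_m {row.radius_m!r}")
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems[:10]))

    derived = "error_deg" not in df.columns
    logs: list[SessionLog] = []
    for pid, g in df.groupby("participant_id", sort=True):
        experiments = g["experiment"].unique()
        if len(experiments) != 1:
            raise SchemaError(
                f"{path}: participant {pid!r} spans experiments {list(experiments)}"
            )
        experiment = str(experiments[0])
        conditions = conditions_for(experiment)
        radius = float(g["radius_m"].iloc[0])
        if not np.allclose(g["radius_m"], radius):
            raise SchemaError(f"{path}: participant {pid!r} has varying radius_m")
        surface = ReachSurface(origin=Vec3(0.0, 0.0, 0.0), radius=radius)

        trials: list[TrialRecord] = []
        counts = {c: 0 for c in conditions}
        for phase in ("practice", "experimental"):
            sub = g[g["phase"] == phase]  # file order within phase
            _check_monotone(sub, str(pid), phase)
            for row in sub.itertuples(index=False):
                if row.condition not in conditions:
                    raise SchemaError(
                        f"{path}: condition {row.condition!r} not valid for "
                        f"experiment {experiment!r}"
                    )
                target = TargetSpec(
                    azimuth=float(row.target_azimuth_deg),
                    elevation=float(row.target_elevation_deg),
                    cartesian=surface.surface_point(
                        float(row.target_azimuth_deg),
                        float(row.target_elevation_deg),
                    ),
                )
                valid = bool(int(getattr(row, "valid", 1)))
                e_az = float(row.endpoint_azimuth_deg)
                e_el = float(row.endpoint_elevation_deg)
                if valid and math.isfinite(e_az) and math.isfinite(e_el):
                    point = surface.surface_point(e_az, e_el)
                    crossing = Crossing(
                        point=point, time_ms=max(float(row.reach_time_ms), 0.0)
                    )
                else:
                    crossing = None
                if derived:
                    if crossing is not None:
                        from .geometry import angular_error

                        err = angular_error(surface, target, crossing)
                        error_deg = err.total_deg
                        error_az = err.azimuth_deg
                        error_el = err.elevation_deg
                    else:
                        error_deg = error_az = error_el = math.nan
                else:
                    error_deg = float(row.error_deg)
                    error_az = float(getattr(row, "error_azimuth_deg", math.nan))
                    error_el = float(getattr(row, "error_elevation_deg", math.nan))
                trials.append(
                    TrialRecord(
                        trial_index=int(row.trial_index),
                        phase=phase,
                        condition=str(row.condition),
                        target=target,
                        crossing=crossing,
                        error_deg=error_deg,
                        error_azimuth_deg=error_az,
                        error_elevation_deg=error_el,
                        reach_time_ms=float(row.reach_time_ms),
                        valid=valid,
                    )
                )
                if phase == "experimental":
                    counts[str(row.condition)] += 1
        n_per = max(counts.values())
        n_practice = sum(1 for t in trials if t.phase == "practice")
        protocol = ProtocolConfig(
            experiment=experiment,
            n_trials_per_condition=n_per,
            n_practice=n_practice,
        )
        log = SessionLog(
            participant_id=str(pid),
            protocol=protocol,
            surface=surface,
            trials=trials,
            notes=["error_deg derived from target/endpoint angles"]
            if derived
            else [],
        )
        logs.append(log)
    return logs


# ---------------------------------------------------------------------------
# trajectory streams
# ---------------------------------------------------------------------------


def write_trajectories(log: SessionLog, path: str | Path) -> Path:
    """JSON Lines fingertip streams: one line per sample."""
    path = Path(path)
    if not log.trajectories:
        raise ValueError("session has no trajectories to write")
    with path.open("w") as fh:
        for trial_pos in sorted(log.trajectories):
            traj = log.trajectories[trial_pos]
            rec = log.trials[trial_pos]
            for t, p in zip(traj.t_ms, traj.xyz):
                fh.write(
                    json.dumps(
                        {
                            "participant_id": log.participant_id,
                            "trial_index": rec.trial_index,
                            "t_ms": round(float(t), 6),
                            "x_m": round(float(p[0]), 9),
                            "y_m": round(float(p[1]), 9),
                            "z_m": round(float(p[2]), 9),
                        },
                        separators=(",", ":"),
                    )
                    + "\n"
                )
    return path


def read_trajectories(path: str | Path) -> dict[tuple[str, int], Trajectory]:
    """Read a JSON Lines trajectory stream, keyed by (participant, trial)."""
    path = Path(path)
    buf: dict[tuple[str, int], list[tuple[float, float, float, float]]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                key = (str(obj["participant_id"]), int(obj["trial_index"]))
                sample = (
                    float(obj["t_ms"]),
                    float(obj["x_m"]),
                    float(obj["y_m"]),
                    float(obj["z_m"]),
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError):
                raise SchemaError(f"{path}: malformed line {lineno}") from None
            buf.setdefault(key, []).append(sample)
    out: dict[tuple[str, int], Trajectory] = {}
    for key, samples in buf.items():
        arr = np.array(samples)
        if not np.all(np.diff(arr[:, 0]) > 0):
            raise OrderingError(
                f"{path}: non-increasing t_ms in trial {key[1]} of {key[0]!r}"
            )
        out[key] = Trajectory(t_ms=arr[:, 0], xyz=arr[:, 1:])
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolSection(_Strict):
    n_trials_per_condition: int = 100
    n_practice: int = 10
    reset_delay_ms: float = 500.0
    tone_delay_ms: float = 1200.0
    target_flash_ms: float = 200.0
    target_elevation: float | tuple[float, float] = 0.0


class EndpointPopulationSection(_Strict):
    azimuth_sd_mean: float
    azimuth_sd_sd: float = 0.0
    elevation_sd_mean: float
    elevation_sd_sd: float = 0.0
    azimuth_bias_mean: float = 0.0
    azimuth_bias_sd: float = 0.0
    elevation_bias_mean: float = 0.0
    elevation_bias_sd: float = 0.0


class PopulationSection(_Strict):
    conditions: dict[str, EndpointPopulationSection]
    noise_correlation: float = 0.5
    duration_median_mean_ms: float = 618.0
    duration_median_sd_ms: float = 100.0
    duration_sigma: float = 0.15
    lapse_rate: float = 0.02
    radius_mean_m: float = 0.62
    radius_sd_m: float = 0.04

    def build(self) -> PopulationParams:
        return PopulationParams(
            conditions={
                c: EndpointPopulation(**s.model_dump())
                for c, s in self.conditions.items()
            },
            noise_correlation=self.noise_correlation,
            duration_median_mean_ms=self.duration_median_mean_ms,
            duration_median_sd_ms=self.duration_median_sd_ms,
            duration_sigma=self.duration_sigma,
            lapse_rate=self.lapse_rate,
            radius_mean_m=self.radius_mean_m,
            radius_sd_m=self.radius_sd_m,
        )


class EndpointModelSection(_Strict):
    azimuth_bias: float = 0.0
    elevation_bias: float = 0.0
    azimuth_sd: float = 0.0
    elevation_sd: float = 0.0


class DurationModelSection(_Strict):
    median_ms: float = 618.0
    sigma: float = 0.15


class ReacherSection(_Strict):
    endpoint: dict[str, EndpointModelSection]
    duration: DurationModelSection | dict[str, DurationModelSection] = Field(
        default_factory=DurationModelSection
    )
    frame_rate: float = 72.0
    lapse_rate: float = 0.02

    def build(self) -> ReacherParams:
        duration: DurationModel | dict[str, DurationModel]
        if isinstance(self.duration, DurationModelSection):
            duration = DurationModel(**self.duration.model_dump())
        else:
            duration = {
                c: DurationModel(**d.model_dump()) for c, d in self.duration.items()
            }
        return ReacherParams(
            endpoint={
                c: EndpointModel(**e.model_dump()) for c, e in self.endpoint.items()
            },
            duration=duration,
            frame_rate=self.frame_rate,
            lapse_rate=self.lapse_rate,
        )


class AnalysisSection(_Strict):
    design: Literal["paired", "individual"] = "paired"
    first_n: int | None = None
    n_permutations: int = 10_000


_POPULATION_PRESETS = {
    "exp1": exp1_population,
    "exp2": exp2_population,
    "null": null_population,
}

_REACHER_PRESETS = {
    "patient1": lambda: patient_reacher(1),
    "patient2": lambda: patient_reacher(2),
}


class RunConfig(_Strict):
    """Declarative description of a simulate + analyze run.

    Either a cohort is drawn from a ``population`` (preset name ``exp1``,
    ``exp2``, ``null`` or an explicit section) or explicit ``reachers``
    (preset names ``patient1``/``patient2`` or sections, keyed by
    participant id) are simulated individually.
    """

    experiment: Literal["visible_invisible", "memory_delay"] = "visible_invisible"
    n_participants: int = 20
    population: str | PopulationSection | None = "exp1"
    reachers: dict[str, str | ReacherSection] | None = None
    protocol: ProtocolSection = Field(default_factory=ProtocolSection)
    analysis: AnalysisSection = Field(default_factory=AnalysisSection)
    seed: int | None = None

    @field_validator("population")
    @classmethod
    def _known_preset(cls, v):
        if isinstance(v, str) and v not in _POPULATION_PRESETS:
            raise ValueError(
                f"unknown population preset {v!r}; expected one of "
                f"{sorted(_POPULATION_PRESETS)}"
            )
        return v

    def build_protocol(self, seed: int | None = None) -> ProtocolConfig:
        return ProtocolConfig(
            experiment=self.experiment,
            rng_seed=seed if seed is not None else self.seed,
            **self.protocol.model_dump(),
        )

    def build_population(self) -> PopulationParams | None:
        if self.population is None:
            return None
        if isinstance(self.population, str):
            fn = _POPULATION_PRESETS[self.population]
            if self.population == "null":
                return fn(self.experiment)
            return fn()
        return self.population.build()

    def build_reachers(self) -> dict[str, ReacherParams] | None:
        if self.reachers is None:
            return None
        out: dict[str, ReacherParams] = {}
        for pid, spec in self.reachers.items():
            if isinstance(spec, str):
                if spec not in _REACHER_PRESETS:
                    raise ValueError(f"unknown reacher preset {spec!r}")
                out[pid] = _REACHER_PRESETS[spec]()
            else:
                out[pid] = spec.build()
        return out


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    try:
        raw = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise SchemaError(f"{path}: cannot parse config: {exc}") from None
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:  # pydantic.ValidationError
        raise SchemaError(f"{path}: invalid config: {exc}") from None


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the canonicalized configuration."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
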