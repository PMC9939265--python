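"""Configuration files, CSV schemas and run manifests.

CSV dialects (all comma-separated, header row, UTF-8):

- trajectories: ``tick,agent_id,role,state,x,y``
- departures:   ``agent_id,departure_tick,return_tick,n_neighbours_at_departure``
- chases:       ``resident_id,onset_tick,offset_tick,mode``
- territories:  ``territory_id,owner_id,cx,cy,radius``
- visits:       ``female_id,territory_id,entry_tick,exit_tick``
- matings:      ``female_id,male_id,tick`` (empty male_id = unmated)
- events:       ``tick,actor_id,behaviour_code,x,y``
- heatmaps:     a dense value matrix ``<name>.csv`` plus geometry in
  ``<name>.meta.json``

Configuration is YAML with three sections (``model``, ``intruder``,
``female``) mirroring the parameter dataclass fields exactly; unknown
keys are rejected by name.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import BehaviouralState, Role, Territory, TrajectorySet
from .errors import ConfigurationError, SchemaError
from .females import MatingRecord, Visit, VisitSequence
from .foraging import DepartureRecord
from .intruder import ChaseEvent, ChaseMode
from .metrics import EVENT_COLUMNS, GridSpec, HeatmapGrid, HeatmapKind, validate_events
from .params import FemaleParams, IntruderParams, ModelParams

PathLike = Union[str, Path]

_SECTIONS = {"model": ModelParams, "intruder": IntruderParams, "female": FemaleParams}


# ---------------------------------------------------------------------------
# configuration


def load_config(path: PathLike) -> Tuple[ModelParams, IntruderParams, FemaleParams]:
    """Load and validate a YAML configuration file.

    Any missing section or field falls back to its default; unknown
    sections or keys are rejected with an error naming them.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping of sections")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown section(s) {sorted(unknown)}; expected {sorted(_SECTIONS)}"
        )
    out = []
    for section, cls in _SECTIONS.items():
        body = raw.get(section, {}) or {}
        if not isinstance(body, dict):
            raise ConfigurationError(f"{path}: section '{section}' must be a mapping")
        names = {f.name for f in dataclasses.fields(cls)}
        bad = set(body) - names
        if bad:
            raise ConfigurationError(
                f"{path}: unknown key(s) {sorted(bad)} in section '{section}'"
            )
        kwargs = {}
        for key, value in body.items():
            if key in ("centre", "foraging_site"):
                value = tuple(value)
            kwargs[key] = value
        try:
            out.append(cls(**kwargs))
        except ConfigurationError as exc:
            raise ConfigurationError(f"{path}: section '{section}': {exc}") from None
    return tuple(out)


def write_config(
    path: PathLike,
    model: ModelParams,
    intruder: Optional[IntruderParams] = None,
    female: Optional[FemaleParams] = None,
) -> None:
    doc = {
        "model": _as_plain(dataclasses.asdict(model)),
        "intruder": _as_plain(dataclasses.asdict(intruder or IntruderParams())),
        "female": _as_plain(dataclasses.asdict(female or FemaleParams())),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _as_plain(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, tuple):
            v = list(v)
        out[k] = v
    return out


# ---------------------------------------------------------------------------
# table helpers


def _read_csv(path: PathLike, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed CSV structure
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from None
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    extra = [c for c in frame.columns if c not in columns]
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {extra}")
    return frame


def _to_int(frame: pd.DataFrame, col: str, path: PathLike, allow_empty: bool = False):
    vals = []
    for i, raw in enumerate(frame[col]):
        if raw == "" and allow_empty:
            vals.append(None)
            continue
        try:
            vals.append(int(raw))
        except ValueError:
            raise SchemaError(
                f"{path}: row {i + 2}: column '{col}': not an integer: {raw!r}"
            ) from None
    return vals


def _to_float(frame: pd.DataFrame, col: str, path: PathLike):
    vals = []
    for i, raw in enumerate(frame[col]):
        try:
            vals.append(float(raw))
        except ValueError:
            raise SchemaError(
                f"{path}: row {i + 2}: column '{col}': not a number: {raw!r}"
            ) from None
    return vals


def _check_tokens(frame: pd.DataFrame, col: str, allowed: Sequence[str], path: PathLike):
    allowed_set = set(allowed)
    for i, raw in enumerate(frame[col]):
        if raw not in allowed_set:
            raise SchemaError(
                f"{path}: row {i + 2}: column '{col}': unknown token {raw!r} "
                f"(expected one of {sorted(allowed_set)})"
            )


# ---------------------------------------------------------------------------
# trajectories


def write_trajectories(traj: TrajectorySet, path: PathLike) -> None:
    frame = traj.frame[list(TrajectorySet.COLUMNS)]
    frame.to_csv(path, index=False)


def read_trajectories(path: PathLike) -> TrajectorySet:
    frame = _read_csv(path, TrajectorySet.COLUMNS)
    _check_tokens(frame, "role", [r.name for r in Role], path)
    _check_tokens(frame, "state", [s.name for s in BehaviouralState], path)
    out = pd.DataFrame(
        {
            "tick": _to_int(frame, "tick", path),
            "agent_id": _to_int(frame, "agent_id", path),
            "role": pd.Categorical(frame["role"], categories=[r.name for r in Role]),
            "state": pd.Categorical(
                frame["state"], categories=[s.name for s in BehaviouralState]
            ),
            "x": _to_float(frame, "x", path),
            "y": _to_float(frame, "y", path),
        }
    )
    return TrajectorySet(frame=out)


# ---------------------------------------------------------------------------
# departures


DEPARTURE_COLUMNS = ("agent_id", "departure_tick", "return_tick", "n_neighbours_at_departure")


def write_departures(records: Sequence[DepartureRecord], path: PathLike) -> None:
    frame = pd.DataFrame(
        {
            "agent_id": [r.agent_id for r in records],
            "departure_tick": [r.departure_tick for r in records],
            "return_tick": ["" if r.return_tick is None else r.return_tick for r in records],
            "n_neighbours_at_departure": [r.n_neighbours for r in records],
        }
    )
    frame.to_csv(path, index=False)


def read_departures(path: PathLike) -> List[DepartureRecord]:
    frame = _read_csv(path, DEPARTURE_COLUMNS)
    ids = _to_int(frame, "agent_id", path)
    dep = _to_int(frame, "departure_tick", path)
    ret = _to_int(frame, "return_tick", path, allow_empty=True)
    nnb = _to_int(frame, "n_neighbours_at_departure", path)
    return [
        DepartureRecord(
            agent_id=a, departure_tick=d, return_tick=r, n_neighbours=m
        )
        for a, d, r, m in zip(ids, dep, ret, nnb)
    ]


# ---------------------------------------------------------------------------
# chases


CHASE_COLUMNS = ("resident_id", "onset_tick", "offset_tick", "mode")


def write_chases(events: Sequence[ChaseEvent], path: PathLike) -> None:
    frame = pd.DataFrame(
        {
            "resident_id": [e.resident_id for e in events],
            "onset_tick": [e.onset_tick for e in events],
            "offset_tick": [e.offset_tick for e in events],
            "mode": [ChaseMode(e.mode).value for e in events],
        }
    )
    frame.to_csv(path, index=False)


def read_chases(path: PathLike) -> List[ChaseEvent]:
    frame = _read_csv(path, CHASE_COLUMNS)
    _check_tokens(frame, "mode", [m.value for m in ChaseMode], path)
    rid = _to_int(frame, "resident_id", path)
    on = _to_int(frame, "onset_tick", path)
    off = _to_int(frame, "offset_tick", path)
    return [
        ChaseEvent(resident_id=r, onset_tick=a, offset_tick=b, mode=ChaseMode(m))
        for r, a, b, m in zip(rid, on, off, frame["mode"])
    ]


# ---------------------------------------------------------------------------
# territories, visits, matings


TERRITORY_COLUMNS = ("territory_id", "owner_id", "cx", "cy", "radius")


def write_territories(territories: Sequence[Territory], path: PathLike) -> None:
    frame = pd.DataFrame(
        {
            "territory_id": [t.id for t in territories],
            "owner_id": [t.owner_id for t in territories],
            "cx": [float(t.centre[0]) for t in territories],
            "cy": [float(t.centre[1]) for t in territories],
            "radius": [t.radius for t in territories],
        }
    )
    frame.to_csv(path, index=False)


def read_territories(path: PathLike) -> List[Territory]:
    frame = _read_csv(path, TERRITORY_COLUMNS)
    tid = _to_int(frame, "territory_id", path)
    oid = _to_int(frame, "owner_id", path)
    cx = _to_float(frame, "cx", path)
    cy = _to_float(frame, "cy", path)
    rad = _to_float(frame, "radius", path)
    return [
        Territory(id=t, owner_id=o, centre=np.array([x, y]), radius=r)
        for t, o, x, y, r in zip(tid, oid, cx, cy, rad)
    ]


VISIT_COLUMNS = ("female_id", "territory_id", "entry_tick", "exit_tick")


def write_visits(sequences: Sequence[VisitSequence], path: PathLike) -> None:
    rows = [
        (s.female_id, v.territory_id, v.entry_tick, v.exit_tick)
        for s in sequences
        for v in s.visits
    ]
    pd.DataFrame(rows, columns=list(VISIT_COLUMNS)).to_csv(path, index=False)


def read_visits(path: PathLike) -> List[VisitSequence]:
    frame = _read_csv(path, VISIT_COLUMNS)
    fid = _to_int(frame, "female_id", path)
    tid = _to_int(frame, "territory_id", path)
    ent = _to_int(frame, "entry_tick", path)
    ext = _to_int(frame, "exit_tick", path)
    by_female: Dict[int, VisitSequence] = {}
    for f, t, a, b in zip(fid, tid, ent, ext):
        by_female.setdefault(f, VisitSequence(female_id=f)).visits.append(
            Visit(territory_id=t, entry_tick=a, exit_tick=b)
        )
    return [by_female[f] for f in sorted(by_female)]


MATING_COLUMNS = ("female_id", "male_id", "tick")


def write_matings(matings: Sequence[MatingRecord], path: PathLike) -> None:
    frame = pd.DataFrame(
        {
            "female_id": [m.female_id for m in matings],
            "male_id": ["" if m.male_id is None else m.male_id for m in matings],
            "tick": [m.tick for m in matings],
        }
    )
    frame.to_csv(path, index=False)


def read_matings(path: PathLike) -> List[MatingRecord]:
    frame = _read_csv(path, MATING_COLUMNS)
    fid = _to_int(frame, "female_id", path)
    mid = _to_int(frame, "male_id", path, allow_empty=True)
    tick = _to_int(frame, "tick", path)
    return [MatingRecord(f, m, t) for f, m, t in zip(fid, mid, tick)]


# ---------------------------------------------------------------------------
# events


def write_events(events: pd.DataFrame, path: PathLike) -> None:
    validate_events(events)
    events[list(EVENT_COLUMNS)].to_csv(path, index=False)


def read_events(path: PathLike) -> pd.DataFrame:
    from .metrics import ETHOGRAM_CODES

    frame = _read_csv(path, EVENT_COLUMNS)
    _check_tokens(frame, "behaviour_code", ETHOGRAM_CODES, path)
    return pd.DataFrame(
        {
            "tick": _to_int(frame, "tick", path),
            "actor_id": _to_int(frame, "actor_id", path),
            "behaviour_code": frame["behaviour_code"].to_numpy(),
            "x": _to_float(frame, "x", path),
            "y": _to_float(frame, "y", path),
        }
    )


# ---------------------------------------------------------------------------
# heatmaps


def write_heatmap(grid: HeatmapGrid, basepath: PathLike) -> Tuple[Path, Path]:
    """Write ``<basepath>.csv`` (dense matrix, row = y index) and
    ``<basepath>.meta.json`` (geometry, kind, overflow)."""
    basepath = Path(basepath)
    values_path = basepath.with_suffix(".csv")
    meta_path = basepath.with_suffix(".meta.json")
    np.savetxt(values_path, grid.values, delimiter=",", fmt="%.17g")
    meta = {
        "x_min": grid.spec.x_min,
        "y_min": grid.spec.y_min,
        "cell_size": grid.spec.cell_size,
        "n_x": grid.spec.n_x,
        "n_y": grid.spec.n_y,
        "kind": grid.kind.value,
        "overflow": grid.overflow,
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return values_path, meta_path


def read_heatmap(basepath: PathLike) -> HeatmapGrid:
    basepath = Path(basepath)
    values = np.loadtxt(basepath.with_suffix(".csv"), delimiter=",", ndmin=2)
    with open(basepath.with_suffix(".meta.json")) as fh:
        meta = json.load(fh)
    spec = GridSpec(
        x_min=meta["x_min"],
        y_min=meta["y_min"],
        cell_size=meta["cell_size"],
        n_x=meta["n_x"],
        n_y=meta["n_y"],
    )
    return HeatmapGrid(
        spec=spec,
        values=values,
        kind=HeatmapKind(meta["kind"]),
        overflow=float(meta["overflow"]),
    )


# ---------------------------------------------------------------------------
# run manifest


@dataclass
class RunManifest:
    """Reproducibility record for one orchestrated run."""

    command: str
    seed: int
    version: str = __version__
    config: dict = field(default_factory=dict)
    outputs: List[str] = field(default_factory=list)
    started: float = field(default_factory=time.time)
    finished: Optional[float] = None

    def write(self, path: PathLike) -> None:
        self.finished = time.time()
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
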