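"""Fixed-epoch scored hypnograms: reading, writing, stage lumping, phase labels.

A hypnogram is a sequence of sleep/wake states scored in fixed-length epochs
(2.5 s in the mouse recordings this package targets). All NREM sub-stages are
lumped into a single NREM state; each epoch additionally carries a LIGHT/DARK
label derived from the recording's wall-clock start time and the vivarium's
light schedule (12:12 by default, lights on 07:00).
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, replace
from enum import IntEnum
from pathlib import Path
from typing import Mapping, Union

import numpy as np

__all__ = [
    "State",
    "Phase",
    "Hypnogram",
    "StageMapError",
    "DEFAULT_STAGE_MAP",
    "DEFAULT_LIGHT_ON",
    "DEFAULT_LIGHT_OFF",
    "read_hypnogram",
    "write_hypnogram",
    "label_phase",
]


class State(IntEnum):
    """Lumped sleep/wake state of one epoch."""

    WAKE = 0
    NREM = 1
    REM = 2


class Phase(IntEnum):
    """Light/dark phase of the environment during one epoch."""

    LIGHT = 0
    DARK = 1


#: Raw score labels commonly found in scored mouse sleep data, lumped to the
#: three analysis states. Sub-stages of NREM all map to NREM; microarousal
#: ("MA") scores map to WAKE.
DEFAULT_STAGE_MAP: Mapping[str, State] = {
    "W": State.WAKE,
    "WAKE": State.WAKE,
    "MA": State.WAKE,
    "N": State.NREM,
    "NREM": State.NREM,
    "N1": State.NREM,
    "N2": State.NREM,
    "N3": State.NREM,
    "SWS": State.NREM,
    "R": State.REM,
    "REM": State.REM,
}

DEFAULT_LIGHT_ON = _dt.time(7, 0, 0)
DEFAULT_LIGHT_OFF = _dt.time(19, 0, 0)

DEFAULT_EPOCH_S = 2.5


class StageMapError(ValueError):
    """A raw score label has no entry in the stage map."""


def _coerce_time(t: Union[str, _dt.time]) -> _dt.time:
    if isinstance(t, _dt.time):
        return t
    return _dt.time.fromisoformat(t)


@dataclass(frozen=True)
class Hypnogram:
    """A validated fixed-epoch state sequence with optional phase labels.

    Parameters
    ----------
    states
        Integer-coded states (one of :class:`State`) in temporal order.
    epoch_s
        Epoch duration in seconds (all epochs identical).
    start_clock
        Wall-clock time of the start of epoch 0.
    phase
        Per-epoch LIGHT/DARK labels, or ``None`` before :func:`label_phase`.
    recording_id
        Opaque identifier used to keep cycles within one recording.
    """

    states: np.ndarray
    epoch_s: float = DEFAULT_EPOCH_S
    start_clock: _dt.time = _dt.time(7, 0, 0)
    phase: np.ndarray | None = None
    recording_id: str = "recording"

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int8)
        object.__setattr__(self, "states", states)
        if states.ndim != 1 or states.size == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        if not np.isin(states, [s.value for s in State]).all():
            raise ValueError("states must be WAKE, NREM or REM codes")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        if self.phase is not None:
            ph = np.asarray(self.phase, dtype=np.int8)
            if ph.shape != states.shape:
                raise ValueError("phase vector must match states in length")
            object.__setattr__(self, "phase", ph)
        object.__setattr__(self, "start_clock", _coerce_time(self.start_clock))

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        same_phase = (
            (self.phase is None and other.phase is None)
            or (
                self.phase is not None
                and other.phase is not None
                and np.array_equal(self.phase, other.phase)
            )
        )
        return (
            np.array_equal(self.states, other.states)
            and self.epoch_s == other.epoch_s
            and self.start_clock == other.start_clock
            and same_phase
            and self.recording_id == other.recording_id
        )


def _normalise_stage_map(stage_map: Mapping) -> dict[str, State]:
    out = {}
    for key, val in stage_map.items():
        out[str(key).strip().upper()] = State(val)
    return out


def read_hypnogram(
    path: Union[str, Path],
    stage_map: Mapping = DEFAULT_STAGE_MAP,
    epoch_s: float = DEFAULT_EPOCH_S,
    start_clock: Union[str, _dt.time] = _dt.time(7, 0, 0),
    recording_id: str | None = None,
) -> Hypnogram:
    """Read a canonical hypnogram TSV and lump raw labels into three states.

    The canonical format is tab-separated with a header; required columns are
    ``epoch_index`` (0-based, contiguous) and ``state`` (a raw score label
    resolved through *stage_map*, case-insensitively). Unknown labels raise
    :class:`StageMapError` naming the label and the offending row.
    """
    path = Path(path)
    smap = _normalise_stage_map(stage_map)
    states: list[int] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "state" not in reader.fieldnames:
            raise ValueError(f"{path}: missing header with a 'state' column")
        for i, row in enumerate(reader):
            raw = (row["state"] or "").strip().upper()
            if raw not in smap:
                raise StageMapError(
                    f"{path}: unmapped stage label {raw!r} at data row {i}"
                )
            states.append(int(smap[raw]))
    if not states:
        raise ValueError(f"{path}: empty hypnogram file")
    return Hypnogram(
        states=np.asarray(states, dtype=np.int8),
        epoch_s=epoch_s,
        start_clock=_coerce_time(start_clock),
        recording_id=recording_id if recording_id is not None else path.stem,
    )


def write_hypnogram(h: Hypnogram, path: Union[str, Path]) -> None:
    """Write *h* in the canonical TSV format (round-trips with the reader)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["epoch_index", "state"])
        for i, s in enumerate(h.states):
            writer.writerow([i, State(int(s)).name])


def _seconds_of_day(t: _dt.time) -> float:
    return t.hour * 3600 + t.minute * 60 + t.second + t.microsecond / 1e6


def label_phase(
    h: Hypnogram,
    light_on: Union[str, _dt.time] = DEFAULT_LIGHT_ON,
    light_off: Union[str, _dt.time] = DEFAULT_LIGHT_OFF,
) -> Hypnogram:
    """Attach LIGHT/DARK labels from the clock schedule.

    An epoch is LIGHT iff its midpoint clock time falls in the half-open
    interval ``[light_on, light_off)``; schedules wrapping midnight are
    supported. Idempotent: labels depend only on ``start_clock``, ``epoch_s``
    and the schedule.
    """
    on = _seconds_of_day(_coerce_time(light_on))
    off = _seconds_of_day(_coerce_time(light_off))
    if on == off:
        raise ValueError("light_on and light_off must differ")
    start = _seconds_of_day(h.start_clock)
    idx = np.arange(h.n_epochs, dtype=np.float64)
    mid = np.mod(start + (idx + 0.5) * h.epoch_s, 86400.0)
    if on < off:
        is_light = (mid >= on) & (mid < off)
    else:  # schedule wraps midnight
        is_light = (mid >= on) | (mid < off)
    phase = np.where(is_light, Phase.LIGHT.value, Phase.DARK.value).astype(np.int8)
    return replace(h, phase=phase)
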