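"""REM-cycle extraction from hypnograms.

A REM cycle runs from the start of one REM bout to the start of the next.
For each cycle we record the opening REM bout duration |REMpre|, the
cumulative NREM in the inter-REM interval |N| (wake, including
microarousals, excluded), the wake content and the longest single wake bout,
and the duration |REMpost| of the closing REM bout. Cycles containing an
extended wake period (a single bout longer than 5 min by default) are
discarded, and cycles are binned by |REMpre| duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram, Phase, State

__all__ = [
    "RemBout",
    "RemCycle",
    "BinSpec",
    "DEFAULT_BINS",
    "DEFAULT_MAX_WAKE_BOUT_S",
    "find_rem_bouts",
    "build_cycles",
    "filter_extended_wake",
    "assign_bin",
    "cycles_to_frame",
]

#: |REMpre| bin edges in seconds; the last bin is open-ended (>180 s).
DEFAULT_BIN_EDGES_S = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0)

DEFAULT_MAX_WAKE_BOUT_S = 300.0


@dataclass(frozen=True)
class RemBout:
    """A maximal run of consecutive REM epochs."""

    start_epoch: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("REM bout duration must be positive")


@dataclass(frozen=True)
class RemCycle:
    """One REM cycle: an opening REM bout plus its inter-REM interval."""

    rempre_s: float
    n_s: float
    wake_s: float
    max_wake_bout_s: float
    rempost_s: float
    phase: int
    bin_index: int
    onset_epoch: int
    recording_id: str = "recording"
    order: int = 0  # temporal rank of the cycle within its recording

    def __post_init__(self) -> None:
        if self.rempre_s <= 0 or self.n_s <= 0 or self.rempost_s <= 0:
            raise ValueError("rempre_s, n_s and rempost_s must be positive")
        if self.wake_s < 0 or self.max_wake_bout_s < 0:
            raise ValueError("wake durations cannot be negative")
        if self.max_wake_bout_s > self.wake_s:
            raise ValueError("max wake bout cannot exceed total wake")


@dataclass(frozen=True)
class BinSpec:
    """Half-open |REMpre| bins partitioning (0, inf)."""

    edges_s: Sequence[float] = DEFAULT_BIN_EDGES_S

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges_s)
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
        object.__setattr__(self, "edges_s", edges)

    @property
    def n_bins(self) -> int:
        return len(self.edges_s)

    def label(self, index: int) -> str:
        edges = self.edges_s
        if index < 0 or index >= self.n_bins:
            raise IndexError(f"bin index {index} out of range")
        if index == self.n_bins - 1:
            return f">{edges[-1]:g}s"
        return f"[{edges[index]:g},{edges[index + 1]:g})s"


DEFAULT_BINS = BinSpec()


def assign_bin(rempre_s: float, spec: BinSpec = DEFAULT_BINS) -> int:
    """Index of the half-open bin containing *rempre_s* (last bin open-ended)."""
    if rempre_s <= 0:
        raise ValueError("rempre_s must be positive")
    edges = spec.edges_s
    # np.searchsorted with side='right' gives the half-open [a, b) rule.
    idx = int(np.searchsorted(edges, rempre_s, side="right")) - 1
    return min(max(idx, 0), spec.n_bins - 1)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of maximal True runs in a boolean vector."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def find_rem_bouts(h: Hypnogram) -> list[RemBout]:
    """Maximal consecutive-REM runs, in temporal order."""
    mask = h.states == State.REM.value
    return [
        RemBout(start_epoch=s, duration_s=n * h.epoch_s) for s, n in _runs(mask)
    ]


def build_cycles(
    h: Hypnogram,
    bouts: Sequence[RemBout] | None = None,
    spec: BinSpec = DEFAULT_BINS,
) -> list[RemCycle]:
    """One :class:`RemCycle` per consecutive pair of REM bouts.

    |N| counts only NREM epochs strictly between the two bouts; wake epochs
    (microarousals included) are excluded from |N| and tallied separately.
    A cycle's phase is the phase at its REMpre onset epoch. The rare pair of
    REM bouts separated by wake only (|N| = 0) produces no cycle.

    Requires phase labels (run :func:`rempropensity.hypnogram.label_phase`
    first).
    """
    if h.phase is None:
        raise ValueError("hypnogram must be phase-labelled before cycle extraction")
    if bouts is None:
        bouts = find_rem_bouts(h)
    cycles: list[RemCycle] = []
    order = 0
    for prev, nxt in zip(bouts, bouts[1:]):
        lo = prev.start_epoch + round(prev.duration_s / h.epoch_s)
        hi = nxt.start_epoch
        between = h.states[lo:hi]
        n_epochs = int(np.count_nonzero(between == State.NREM.value))
        wake_mask = between == State.WAKE.value
        wake_epochs = int(np.count_nonzero(wake_mask))
        wake_runs = _runs(wake_mask)
        max_wake = max((n for _, n in wake_runs), default=0)
        if n_epochs == 0:
            continue
        rempre_s = prev.duration_s
        cycles.append(
            RemCycle(
                rempre_s=rempre_s,
                n_s=n_epochs * h.epoch_s,
                wake_s=wake_epochs * h.epoch_s,
                max_wake_bout_s=max_wake * h.epoch_s,
                rempost_s=nxt.duration_s,
                phase=int(h.phase[prev.start_epoch]),
                bin_index=assign_bin(rempre_s, spec),
                onset_epoch=prev.start_epoch,
                recording_id=h.recording_id,
                order=order,
            )
        )
        order += 1
    return cycles


def filter_extended_wake(
    cycles: Iterable[RemCycle],
    max_wake_bout_s: float = DEFAULT_MAX_WAKE_BOUT_S,
    mode: str = "single",
) -> list[RemCycle]:
    """Drop cycles whose wake content marks the animal as not primarily asleep.

    With ``mode="single"`` (default) a cycle is removed iff its longest
    single wake bout exceeds *max_wake_bout_s*; ``mode="cumulative"`` applies
    the threshold to total wake instead (sensitivity switch).
    """
    if mode not in ("single", "cumulative"):
        raise ValueError("mode must be 'single' or 'cumulative'")
    if mode == "single":
        return [c for c in cycles if c.max_wake_bout_s <= max_wake_bout_s]
    return [c for c in cycles if c.wake_s <= max_wake_bout_s]


def cycles_to_frame(
    cycles: Sequence[RemCycle], spec: BinSpec = DEFAULT_BINS
) -> pd.DataFrame:
    """Tabulate cycles for export (TSV-friendly)."""
    rows = [
        {
            "recording_id": c.recording_id,
            "order": c.order,
            "onset_epoch": c.onset_epoch,
            "phase": Phase(c.phase).name,
            "rempre_s": c.rempre_s,
            "n_s": c.n_s,
            "wake_s": c.wake_s,
            "max_wake_bout_s": c.max_wake_bout_s,
            "rempost_s": c.rempost_s,
            "bin_index": c.bin_index,
            "bin_label": spec.label(c.bin_index),
        }
        for c in cycles
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "recording_id",
            "order",
            "onset_epoch",
            "phase",
            "rempre_s",
            "n_s",
            "wake_s",
            "max_wake_bout_s",
            "rempost_s",
            "bin_index",
            "bin_label",
        ],
    )
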