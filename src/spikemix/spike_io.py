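"""Spike-train containers, table readers/writers, and window extraction.

Spike times live on the half-open analysis window ``(0, T]`` in
milliseconds, re-anchored so that time 0 is 200 ms after stimulus onset
(the transient onset burst is excluded from analysis).  Times are binned at
``dt = 1`` ms with at most one spike per bin; a spike exactly at a bin edge
belongs to the earlier (right-closed) bin.

The on-disk format is a plain CSV with one row per trial::

    neuron_id,condition,direction_index,trial_index,T_ms,spike_times_ms

where ``spike_times_ms`` is a semicolon-joined list of window-relative
times (e.g. ``"12.0;57.0;103.0"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .tuning import CONDITIONS, BIDIRECTIONAL

#: Analysis window relative to stimulus onset (ms): 200-700 ms, i.e. at
#: most 500 ms of data per trial, terminated early if the stimulus changed.
WINDOW_START_MS = 200.0
WINDOW_END_MS = 700.0


class SpikeTableError(ValueError):
    """Raised for malformed spike tables or invalid spike trains."""


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered sequence of spike times on the window ``(0, T]``.

    Parameters
    ----------
    times:
        Strictly increasing spike times in ms, each in ``(0, T]``.
    T:
        Window length in ms.
    dt:
        Bin width in ms (1 ms throughout the analysis).
    """

    times: np.ndarray
    T: float
    dt: float = 1.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.T <= 0:
            raise SpikeTableError(f"window length T must be > 0, got {self.T}")
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise SpikeTableError("spike times must be strictly increasing")
            if t[0] <= 0 or t[-1] > self.T + 1e-9:
                raise SpikeTableError(
                    f"spike times must lie in (0, T={self.T}]: got range "
                    f"[{t[0]}, {t[-1]}]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def n_bins(self) -> int:
        n = self.T / self.dt
        if abs(n - round(n)) > 1e-9:
            raise SpikeTableError(f"T={self.T} is not a multiple of dt={self.dt}")
        return int(round(n))

    def spike_bins(self) -> np.ndarray:
        """0-based bin index of each spike; bin ``i`` covers ``(i*dt, (i+1)*dt]``."""
        idx = np.ceil(self.times / self.dt - 1e-12).astype(np.int64) - 1
        if idx.size and (np.any(idx < 0) or np.any(idx >= self.n_bins)):
            raise SpikeTableError("spike bin index out of range")
        if idx.size and np.any(np.diff(idx) == 0):
            raise SpikeTableError("two spikes fall in the same 1 ms bin")
        return idx

    def isis(self) -> np.ndarray:
        """Interspike intervals (ms); empty for trains with < 2 spikes."""
        return np.diff(self.times)


@dataclass(frozen=True)
class TrialRecord:
    """One trial's spike train with its experimental metadata."""

    neuron_id: str
    condition: str
    direction_index: int
    trial_index: int
    train: SpikeTrain

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise SpikeTableError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if not 1 <= int(self.direction_index) <= 12:
            raise SpikeTableError(
                f"direction_index must be in 1..12, got {self.direction_index}"
            )

    @property
    def is_bidirectional(self) -> bool:
        return self.condition in BIDIRECTIONAL


def bin_train(train: SpikeTrain) -> np.ndarray:
    """Binary spike indicator per 1 ms bin; its sum equals the spike count."""
    seq = np.zeros(train.n_bins, dtype=np.int8)
    seq[train.spike_bins()] = 1
    return seq


def unbin(indicator: np.ndarray, dt: float = 1.0) -> SpikeTrain:
    """Inverse of :func:`bin_train`: spikes placed at the right edge of their bin."""
    idx = np.flatnonzero(indicator)
    return SpikeTrain(times=(idx + 1) * dt, T=len(indicator) * dt, dt=dt)


def extract_window(
    raw_times_ms: Sequence[float],
    change_time_ms: Optional[float] = None,
    dt: float = 1.0,
) -> SpikeTrain:
    """Cut the analysis window out of onset-anchored spike times.

    ``raw_times_ms`` are spike times measured from stimulus onset.  The
    analysed interval is ``[200, min(700, change_time))`` ms, shifted so the
    window start becomes time 0 (so ``T <= 500`` ms).  Spikes outside the
    window are dropped; a change before 200 ms leaves no analysable data.
    """
    raw = np.asarray(raw_times_ms, dtype=float)
    if raw.size and raw.min() < 0:
        raise SpikeTableError("raw spike times must be nonnegative")
    end = WINDOW_END_MS if change_time_ms is None else min(WINDOW_END_MS, change_time_ms)
    T = end - WINDOW_START_MS
    if T <= 0:
        raise SpikeTableError(
            f"stimulus change at {change_time_ms} ms leaves an empty analysis window"
        )
    shifted = raw - WINDOW_START_MS
    kept = shifted[(shifted > 0) & (shifted <= T)]
    return SpikeTrain(times=np.sort(kept), T=float(T), dt=dt)


def split_half(train: SpikeTrain) -> tuple[SpikeTrain, SpikeTrain]:
    """Split a train into first and second halves, each re-anchored to 0.

    Used for the stationarity check that re-runs the full analysis on the
    0-250 ms and 250-500 ms halves of the window.
    """
    half = train.T / 2.0
    first = train.times[train.times <= half]
    second = train.times[train.times > half] - half
    return (
        SpikeTrain(times=first, T=half, dt=train.dt),
        SpikeTrain(times=second, T=half, dt=train.dt),
    )


def split_half_records(records: Iterable[TrialRecord]) -> tuple[list, list]:
    """Apply :func:`split_half` to every trial, keeping metadata."""
    firsts, seconds = [], []
    for rec in records:
        a, b = split_half(rec.train)
        firsts.append(TrialRecord(rec.neuron_id, rec.condition, rec.direction_index, rec.trial_index, a))
        seconds.append(TrialRecord(rec.neuron_id, rec.condition, rec.direction_index, rec.trial_index, b))
    return firsts, seconds


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["neuron_id", "condition", "direction_index", "trial_index", "T_ms", "spike_times_ms"]


def write_spike_table(records: Iterable[TrialRecord], path) -> None:
    """Write trials to the delimited spike-table format (lossless to 0.1 ms)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "neuron_id": rec.neuron_id,
                "condition": rec.condition,
                "direction_index": rec.direction_index,
                "trial_index": rec.trial_index,
                "T_ms": rec.train.T,
                "spike_times_ms": ";".join(f"{t:.1f}" for t in rec.train.times),
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_spike_table(path, min_trials_per_condition: int = 2):
    """Read and validate a spike table.

    Returns ``(records, report)`` where ``report`` is a dict with the
    neurons excluded by the inclusion rule (at least
    ``min_trials_per_condition`` trials in every condition the neuron was
    recorded in) and any condition groups flagged as too small.  Records of
    excluded neurons are not returned.
    """
    df = pd.read_csv(path, dtype={"neuron_id": str, "condition": str})
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise SpikeTableError(f"spike table {path} is missing columns {sorted(missing)}")

    records: list[TrialRecord] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        raw = "" if pd.isna(row.spike_times_ms) else str(row.spike_times_ms)
        times = np.array([float(x) for x in raw.split(";") if x.strip() != ""])
        try:
            train = SpikeTrain(times=times, T=float(row.T_ms))
            train.spike_bins()  # validates the one-spike-per-bin assumption
            rec = TrialRecord(
                neuron_id=str(row.neuron_id),
                condition=str(row.condition),
                direction_index=int(row.direction_index),
                trial_index=int(row.trial_index),
                train=train,
            )
        except SpikeTableError as err:
            raise SpikeTableError(f"{path} row {row_number}: {err}") from err
        records.append(rec)

    counts: dict[tuple, int] = {}
    for rec in records:
        counts[(rec.neuron_id, rec.condition)] = counts.get((rec.neuron_id, rec.condition), 0) + 1
    excluded = sorted(
        {nid for (nid, _), n in counts.items() if n < min_trials_per_condition}
    )
    flagged = sorted(k for k, n in counts.items() if n < min_trials_per_condition)
    kept = [r for r in records if r.neuron_id not in excluded]
    report = {"excluded_neurons": excluded, "small_groups": flagged}
    return kept, report


def group_by_neuron(records: Iterable[TrialRecord]) -> dict:
    """Group trial records by neuron id, preserving order."""
    out: dict[str, list[TrialRecord]] = {}
    for rec in records:
        out.setdefault(rec.neuron_id, []).append(rec)
    return out
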