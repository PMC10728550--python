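"""Core domain types and session I/O.

A recording session couples spike trains from dorsal CA1 (dCA1) and medial
prefrontal cortex (mPFC) with the event table of a delayed non-match to
sample (DNMTS) task: cue light, sample lever press, a 4/8/16 s delay ended
by a 500 ms tone, nose-poke, and choice lever press.

All times are absolute seconds from session start.  Alignment to task events
is always done by subtraction; binned series use half-open bins
``[t, t + bin_width)`` timestamped by their left edge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AREAS = ("dCA1", "mPFC")

#: Common spellings accepted in input tables, normalized to canonical names.
AREA_ALIASES = {
    "dca1": "dCA1",
    "ca1": "dCA1",
    "hpc": "dCA1",
    "hippocampus": "dCA1",
    "mpfc": "mPFC",
    "pfc": "mPFC",
    "prelimbic": "mPFC",
    "prl": "mPFC",
}

DELAYS_S = (4.0, 8.0, 16.0)
BIN_S = 0.05

EVENT_COLUMNS = ("t_cue", "t_sample", "t_tone", "t_nosepoke", "t_choice", "t_reward")


class SessionFormatError(ValueError):
    """Raised when an input table is missing required columns."""


class SessionValidationError(ValueError):
    """Raised when trial events violate task ordering invariants."""


def normalize_area(area: str) -> str:
    a = str(area).strip()
    if a in AREAS:
        return a
    key = a.lower()
    if key in AREA_ALIASES:
        return AREA_ALIASES[key]
    raise SessionFormatError(f"unknown area label {area!r}")


@dataclass
class Unit:
    """A single unit: id, area, and its sorted spike times in seconds."""

    unit_id: str
    area: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.area = normalize_area(self.area)
        st = np.asarray(self.spike_times, dtype=float)
        if st.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if st.size and st.min() < 0:
            raise ValueError(f"unit {self.unit_id}: negative spike time")
        if np.any(np.diff(st) < 0):
            warnings.warn(f"unit {self.unit_id}: spike times unsorted; sorting")
            st = np.sort(st)
        self.spike_times = st

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def mean_rate(self, duration_s: float) -> float:
        return self.n_spikes / duration_s if duration_s > 0 else np.nan


@dataclass
class Trial:
    """One DNMTS trial: cue side, delay, outcome and event timestamps."""

    index: int
    cue_side: str  # "L" | "R"
    delay_s: float
    outcome: str  # "correct" | "error" | "miss"
    t_cue: float
    t_sample: float
    t_tone: float
    t_nosepoke: float | None = None
    t_choice: float | None = None
    t_reward: float | None = None

    def __post_init__(self) -> None:
        if self.cue_side not in ("L", "R"):
            raise ValueError(f"trial {self.index}: cue_side must be L or R")
        if self.outcome not in ("correct", "error", "miss"):
            raise ValueError(f"trial {self.index}: bad outcome {self.outcome!r}")

    @property
    def completed(self) -> bool:
        return self.outcome != "miss" and self.t_choice is not None

    def validate(self, tone_tol_s: float = 0.5) -> None:
        seq = [self.t_cue, self.t_sample, self.t_tone]
        if self.t_nosepoke is not None:
            seq.append(self.t_nosepoke)
        if self.t_choice is not None:
            seq.append(self.t_choice)
        if any(b < a for a, b in zip(seq, seq[1:])):
            raise SessionValidationError(
                f"trial {self.index}: event times out of order: {seq}"
            )
        if abs((self.t_tone - self.t_sample) - self.delay_s) > tone_tol_s:
            raise SessionValidationError(
                f"trial {self.index}: tone at {self.t_tone - self.t_sample:.2f} s "
                f"after sample, expected delay {self.delay_s} s"
            )


@dataclass
class Session:
    """Units plus trial table for one recording session."""

    units: list[Unit]
    trials: list[Trial]
    duration_s: float
    lfp: dict[str, tuple[np.ndarray, float]] | None = None  # area -> (signal, fs)

    def __post_init__(self) -> None:
        self.trials = sorted(self.trials, key=lambda t: t.index)

    def units_in(self, area: str) -> list[Unit]:
        area = normalize_area(area)
        return [u for u in self.units if u.area == area]

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def completed_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.completed]

    def completion_fraction(self) -> float:
        if not self.trials:
            return 0.0
        return len(self.completed_trials()) / len(self.trials)

    def validate(self) -> None:
        for t in self.trials:
            t.validate()
            for name in EVENT_COLUMNS:
                v = getattr(t, name)
                if v is not None and not (0 <= v <= self.duration_s):
                    raise SessionValidationError(
                        f"trial {t.index}: {name}={v} outside [0, {self.duration_s}]"
                    )
        if self.completion_fraction() < 0.67:
            warnings.warn(
                "session completed fewer than 67% of trials; real sessions at "
                "this completion level are normally excluded from analysis"
            )


@dataclass
class AlignedRateTensor:
    """Trials x units x 50-ms-bin instantaneous rates around one event.

    ``rates[k, i, b]`` is unit ``unit_ids[i]``'s KDE rate on trial
    ``trial_indices[k]`` in the half-open bin starting ``times[b]`` seconds
    relative to the alignment event (bin offset 0 starts at the event).
    """

    rates: np.ndarray  # (n_trials, n_units, n_bins), Hz
    times: np.ndarray  # bin left edges, s relative to event
    bin_s: float
    align_event: str
    unit_ids: list[str]
    trial_indices: list[int]
    areas: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rates.ndim != 3:
            raise ValueError("rates must be (trials, units, bins)")
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_units(self) -> int:
        return self.rates.shape[1]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[2]

    def subset_units(self, idx: Sequence[int]) -> "AlignedRateTensor":
        idx = list(idx)
        return AlignedRateTensor(
            rates=self.rates[:, idx, :],
            times=self.times,
            bin_s=self.bin_s,
            align_event=self.align_event,
            unit_ids=[self.unit_ids[i] for i in idx],
            trial_indices=list(self.trial_indices),
            areas=[self.areas[i] for i in idx] if self.areas else [],
        )

    def subset_trials(self, idx: Sequence[int]) -> "AlignedRateTensor":
        idx = list(idx)
        return AlignedRateTensor(
            rates=self.rates[idx, :, :],
            times=self.times,
            bin_s=self.bin_s,
            align_event=self.align_event,
            unit_ids=list(self.unit_ids),
            trial_indices=[self.trial_indices[k] for k in idx],
            areas=list(self.areas),
        )


# ---------------------------------------------------------------------------
# I/O


def _opt(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def read_session(spikes_path, events_path, duration_s: float | None = None) -> Session:
    """Read a session from a spikes CSV and an events CSV.

    The spikes file has columns ``unit_id,area,spike_time_s``; the events
    file ``trial,cue_side,delay_s,outcome,t_cue,t_sample,t_tone,t_nosepoke,
    t_choice,t_reward`` with empty cells for absent events.  Area labels are
    normalized through an alias table (``CA1`` -> ``dCA1`` etc.).
    """
    spikes = pd.read_csv(spikes_path)
    missing = {"unit_id", "area", "spike_time_s"} - set(spikes.columns)
    if missing:
        raise SessionFormatError(f"spikes file missing columns: {sorted(missing)}")
    events = pd.read_csv(events_path)
    req = {"trial", "cue_side", "delay_s", "outcome", "t_cue", "t_sample", "t_tone"}
    missing = req - set(events.columns)
    if missing:
        raise SessionFormatError(f"events file missing columns: {sorted(missing)}")

    units = []
    for uid, grp in spikes.groupby("unit_id", sort=True):
        area = normalize_area(grp["area"].iloc[0])
        units.append(Unit(str(uid), area, np.sort(grp["spike_time_s"].to_numpy(float))))

    trials = []
    for _, row in events.iterrows():
        trials.append(
            Trial(
                index=int(row["trial"]),
                cue_side=str(row["cue_side"]).strip(),
                delay_s=float(row["delay_s"]),
                outcome=str(row["outcome"]).strip(),
                t_cue=float(row["t_cue"]),
                t_sample=float(row["t_sample"]),
                t_tone=float(row["t_tone"]),
                t_nosepoke=_opt(row.get("t_nosepoke")),
                t_choice=_opt(row.get("t_choice")),
                t_reward=_opt(row.get("t_reward")),
            )
        )

    if duration_s is None:
        t_max = max(
            [u.spike_times[-1] for u in units if u.n_spikes]
            + [t.t_choice or t.t_tone for t in trials],
            default=0.0,
        )
        duration_s = float(t_max) + 1.0
    sess = Session(units=units, trials=trials, duration_s=duration_s)
    sess.validate()
    return sess


def write_session(session: Session, spikes_path, events_path) -> None:
    """Write a session back to the two-CSV on-disk form (see read_session)."""
    rows = []
    for u in session.units:
        for t in u.spike_times:
            rows.append((u.unit_id, u.area, t))
    pd.DataFrame(rows, columns=["unit_id", "area", "spike_time_s"]).to_csv(
        spikes_path, index=False, float_format="%.6f"
    )
    erows = []
    for t in session.trials:
        erows.append(
            {
                "trial": t.index,
                "cue_side": t.cue_side,
                "delay_s": t.delay_s,
                "outcome": t.outcome,
                "t_cue": t.t_cue,
                "t_sample": t.t_sample,
                "t_tone": t.t_tone,
                "t_nosepoke": t.t_nosepoke,
                "t_choice": t.t_choice,
                "t_reward": t.t_reward,
            }
        )
    pd.DataFrame(erows).to_csv(events_path, index=False, float_format="%.6f")


def read_lfp(path) -> dict[str, tuple[np.ndarray, float]]:
    """Read per-area LFP from a CSV with columns ``area,time_s,voltage``.

    Samples must be evenly spaced per area; returns {area: (signal, fs_hz)}.
    """
    df = pd.read_csv(path)
    missing = {"area", "time_s", "voltage"} - set(df.columns)
    if missing:
        raise SessionFormatError(f"LFP file missing columns: {sorted(missing)}")
    out = {}
    for area, grp in df.groupby("area"):
        grp = grp.sort_values("time_s")
        dt = np.diff(grp["time_s"].to_numpy())
        if dt.size and (dt.max() - dt.min()) > 1e-6:
            raise SessionFormatError(f"LFP for {area} is not evenly sampled")
        fs = 1.0 / dt[0] if dt.size else float("nan")
        out[normalize_area(area)] = (grp["voltage"].to_numpy(float), fs)
    return out


# ---------------------------------------------------------------------------
# Unit selection and task-epoch extraction


def select_units(session: Session, min_rate_hz: float = 0.5) -> Session:
    """Restrict a session to units firing at least ``min_rate_hz`` on average.

    The 0.5 Hz default is the standard inclusion threshold for putative
    principal cells in this kind of dataset.
    """
    if session.duration_s <= 0:
        raise ValueError("session duration must be positive")
    kept = [u for u in session.units if u.mean_rate(session.duration_s) >= min_rate_hz]
    if not kept:
        warnings.warn("no units pass the rate threshold")
    return replace(session, units=kept)


def excise_task_epochs(
    session: Session, pre_s: float = 5.0, post_s: float = 5.0, bin_s: float = BIN_S
) -> tuple[np.ndarray, np.ndarray]:
    """Task-epoch 50-ms bin indices, cue - ``pre_s`` to choice + ``post_s``.

    Returns ``(bin_indices, trial_of_bin)``: sorted global bin indices (bin b
    covers ``[b*bin_s, (b+1)*bin_s)`` in session time) concatenated over
    completed trials with overlapping windows merged, and the owning trial
    index per bin (earliest trial wins on overlap).
    """
    intervals = []
    for t in session.trials:
        if not t.completed:
            logger.info("trial %d skipped in epoch excision (no choice press)", t.index)
            continue
        b0 = int(np.floor((t.t_cue - pre_s) / bin_s))
        b1 = int(np.ceil((t.t_choice + post_s) / bin_s))
        intervals.append((max(b0, 0), b1, t.index))

    if not intervals:
        warnings.warn("no completed trials; empty epoch set")
        return np.empty(0, dtype=int), np.empty(0, dtype=int)

    intervals.sort()
    bins: list[int] = []
    owners: list[int] = []
    hi = -1
    for b0, b1, tix in intervals:
        start = max(b0, hi)
        if b1 > start:
            bins.extend(range(start, b1))
            owners.extend([tix] * (b1 - start))
            hi = max(hi, b1)
    order = np.argsort(bins, kind="stable")
    return np.asarray(bins, dtype=int)[order], np.asarray(owners, dtype=int)[order]
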