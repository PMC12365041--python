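"""Vigilance-state hypnograms and NREMS microarchitecture statistics.

A hypnogram is a sequence of per-epoch vigilance scores on a fixed grid
(4-s epochs by default).  The score alphabet is

* ``W`` — wakefulness
* ``N`` — non-REM sleep (NREMS)
* ``R`` — REM sleep (REMS)
* ``M`` — microarousal (MA), assigned by :func:`reclassify_microarousals`

This module implements the MA reclassification rule (brief wake
intrusions of at most 12 s flanked by NREMS), run-length bout detection
with optional MA merging, sleep-architecture statistics, NREMS->REMS
transition detection and the consolidated-bout segment recipes used by
the spectral analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STATES = ("W", "N", "R", "M")

#: Microarousal rule thresholds, in seconds: maximal MA duration, minimal
#: preceding NREMS, minimal following NREMS.
MA_MAX_S = 12.0
MA_PRE_S = 16.0
MA_POST_S = 4.0

__all__ = [
    "Hypnogram",
    "BoutStats",
    "reclassify_microarousals",
    "detect_bouts",
    "bout_statistics",
    "detect_transitions",
    "extract_segments",
]


@dataclass(frozen=True)
class Hypnogram:
    """Per-epoch vigilance scores on a uniform epoch grid.

    Epoch ``i`` spans the half-open interval
    ``[start_time + i*epoch_length, start_time + (i+1)*epoch_length)``.
    """

    scores: np.ndarray
    epoch_length: float = 4.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype="<U1")
        if scores.ndim != 1 or scores.size < 1:
            raise ValueError("hypnogram needs at least one epoch")
        bad = ~np.isin(scores, STATES)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"unknown score {scores[i]!r} at epoch {i}; expected one of {STATES}"
            )
        if not self.epoch_length > 0:
            raise ValueError("epoch_length must be positive")
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return int(self.scores.size)

    @property
    def duration(self) -> float:
        """Total recording duration in seconds."""
        return len(self) * self.epoch_length

    @property
    def times(self) -> np.ndarray:
        """Epoch start times in seconds."""
        return self.start_time + np.arange(len(self)) * self.epoch_length

    def epoch_at(self, t: float) -> int:
        """Index of the epoch containing time ``t`` (half-open intervals)."""
        i = int(math.floor((t - self.start_time) / self.epoch_length))
        if not 0 <= i < len(self):
            raise ValueError(f"time {t} s outside the recording")
        return i

    def with_scores(self, scores: np.ndarray) -> "Hypnogram":
        return replace(self, scores=scores)


def _runs(labels: np.ndarray):
    """Maximal runs of equal labels as (label, start, end) with end exclusive."""
    n = labels.size
    if n == 0:
        return
    boundaries = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    for s, e in zip(starts, ends):
        yield str(labels[s]), int(s), int(e)


def reclassify_microarousals(hyp: Hypnogram) -> Hypnogram:
    """Relabel brief NREMS-flanked wake intrusions as microarousals.

    A maximal wake run is relabeled ``M`` when its duration does not
    exceed 12 s, it is immediately preceded by at least 16 s of NREMS and
    immediately followed by at least 4 s of NREMS.  Every other epoch is
    left untouched, so the operation is idempotent; wake runs touching
    the recording edges can never qualify (their flanks are unverifiable).
    """
    el = hyp.epoch_length
    max_len = int(MA_MAX_S // el)  # MA run length in epochs
    n_pre = int(np.ceil(MA_PRE_S / el))
    n_post = int(np.ceil(MA_POST_S / el))
    scores = hyp.scores
    out = scores.copy()
    n = scores.size
    for label, s, e in _runs(scores):
        if label != "W" or (e - s) > max_len:
            continue
        if s - n_pre < 0 or e + n_post > n:
            continue  # edge runs are never MAs
        if not (scores[s - n_pre:s] == "N").all():
            continue
        if not (scores[e:e + n_post] == "N").all():
            continue
        out[s:e] = "M"
    return hyp.with_scores(out)


def detect_bouts(
    hyp: Hypnogram,
    state: str | None = None,
    min_duration: float = 4.0,
    merge_ma: bool = True,
) -> pd.DataFrame:
    """Run-length encode vigilance-state bouts.

    Parameters
    ----------
    state:
        Restrict to one state, or ``None`` for all states.
    min_duration:
        Drop bouts shorter than this (inclusive threshold, i.e. bouts of
        exactly ``min_duration`` are kept); must be a multiple of the
        epoch length.
    merge_ma:
        Treat MA epochs as NREMS so they do not break a NREMS run; merged
        epochs count toward the bout duration and are tallied in
        ``n_ma_epochs``.

    Returns
    -------
    pandas.DataFrame
        Columns ``state``, ``start`` / ``end`` (epoch indices, end
        exclusive), ``duration_s`` and ``n_ma_epochs``.
    """
    if state is not None and state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    el = hyp.epoch_length
    if abs(min_duration / el - round(min_duration / el)) > 1e-9:
        raise ValueError("min_duration must be a multiple of the epoch length")
    labels = hyp.scores
    if merge_ma:
        labels = np.where(labels == "M", "N", labels)
    rows = []
    for label, s, e in _runs(labels):
        if state is not None and label != state:
            continue
        dur = (e - s) * el
        if dur < min_duration:
            continue
        n_ma = int((hyp.scores[s:e] == "M").sum()) if label == "N" else 0
        rows.append((label, s, e, dur, n_ma))
    return pd.DataFrame(rows, columns=["state", "start", "end", "duration_s", "n_ma_epochs"])


@dataclass
class BoutStats:
    """Per-state sleep-architecture statistics for one recording."""

    avg_bout_length: dict = field(default_factory=dict)  # seconds
    percent_of_recording: dict = field(default_factory=dict)  # %
    bouts_per_hour: dict = field(default_factory=dict)  # 1/h
    mas_per_hour_nrems: float | None = None  # events / h of NREMS

    def to_dict(self) -> dict:
        return {
            "avg_bout_length_s": self.avg_bout_length,
            "percent_of_recording": self.percent_of_recording,
            "bouts_per_hour": self.bouts_per_hour,
            "mas_per_hour_nrems": self.mas_per_hour_nrems,
        }


def count_ma_events(hyp: Hypnogram) -> int:
    """Number of MA events, i.e. maximal runs of ``M`` epochs."""
    return sum(1 for label, _, _ in _runs(hyp.scores) if label == "M")


def bout_statistics(
    hyp: Hypnogram,
    bouts: pd.DataFrame,
    recording_duration: float | None = None,
    include_ma_in_nrems_time: bool = True,
) -> BoutStats:
    """Sleep-architecture statistics from a bout table.

    Per state: mean bout length, percentage of the recording covered and
    bout count per hour.  The MA rate is the number of maximal MA runs
    per hour of NREMS; the NREMS-time denominator includes MA epochs
    merged into NREMS bouts unless ``include_ma_in_nrems_time=False``.
    With zero NREMS time the MA rate is undefined and reported as
    ``None``, not zero.
    """
    if recording_duration is None:
        recording_duration = hyp.duration
    if recording_duration <= 0:
        raise ValueError("recording_duration must be positive")
    stats = BoutStats()
    hours = recording_duration / 3600.0
    for state, grp in bouts.groupby("state"):
        stats.avg_bout_length[state] = float(grp["duration_s"].mean())
        stats.percent_of_recording[state] = float(
            100.0 * grp["duration_s"].sum() / recording_duration
        )
        stats.bouts_per_hour[state] = float(len(grp) / hours)
    el = hyp.epoch_length
    nrems_s = float((hyp.scores == "N").sum()) * el
    if include_ma_in_nrems_time:
        nrems_s += float((hyp.scores == "M").sum()) * el
    if nrems_s > 0:
        stats.mas_per_hour_nrems = count_ma_events(hyp) * 3600.0 / nrems_s
    return stats


def detect_transitions(hyp: Hypnogram, min_epochs: int = 5) -> list[int]:
    """Indices of the first REMS epoch of each NREMS->REMS transition.

    A transition qualifies when at least ``min_epochs`` continuous NREMS
    epochs (MA epochs counting as NREMS) are followed by at least
    ``min_epochs`` continuous REMS epochs.
    """
    if min_epochs < 1:
        raise ValueError("min_epochs must be >= 1")
    labels = np.where(hyp.scores == "M", "N", hyp.scores)
    out = []
    runs = list(_runs(labels))
    for (la, sa, ea), (lb, sb, eb) in zip(runs[:-1], runs[1:]):
        if la == "N" and lb == "R" and (ea - sa) >= min_epochs and (eb - sb) >= min_epochs:
            out.append(sb)
    return out


def extract_segments(
    hyp: Hypnogram,
    min_len: float,
    trim_start: float = 0.0,
    trim_end: float = 0.0,
    cut_to: float | None = None,
    min_len_inclusive: bool = False,
) -> list[tuple[int, int]]:
    """Consolidated NREMS segments for the spectral analyses.

    MA-merged NREMS runs longer than ``min_len`` (``>=`` when
    ``min_len_inclusive``) are trimmed by ``trim_start`` / ``trim_end``
    seconds and optionally truncated to ``cut_to`` seconds from the
    trimmed start; runs whose trimmed length falls short of ``cut_to``
    are dropped, not padded.  Returns half-open epoch-index pairs.

    The canonical recipes: cross-correlation and PSD use runs > 300 s
    with the first 100 s deleted (PSD additionally cut to 200 s);
    peak-to-peak uses runs >= 150 s with the first 16 s and last 4 s
    deleted.
    """
    el = hyp.epoch_length
    for name, v in (("trim_start", trim_start), ("trim_end", trim_end)):
        if abs(v / el - round(v / el)) > 1e-9:
            raise ValueError(f"{name} must be a multiple of the epoch length")
    if cut_to is not None and abs(cut_to / el - round(cut_to / el)) > 1e-9:
        raise ValueError("cut_to must be a multiple of the epoch length")
    if not min_len > trim_start + trim_end:
        raise ValueError("min_len must exceed trim_start + trim_end")
    labels = np.where(hyp.scores == "M", "N", hyp.scores)
    segments: list[tuple[int, int]] = []
    for label, s, e in _runs(labels):
        if label != "N":
            continue
        dur = (e - s) * el
        if dur < min_len or (dur == min_len and not min_len_inclusive):
            continue
        a = s + int(round(trim_start / el))
        b = e - int(round(trim_end / el))
        if cut_to is not None:
            if (b - a) * el < cut_to:
                continue
            b = a + int(round(cut_to / el))
        if b > a:
            segments.append((a, b))
    return segments
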