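"""Readers and writers for the on-disk formats.

All files are UTF-8 CSV with a mandatory header row, comma separators
and ``.`` decimals; times are seconds from recording start.  Metadata
(seed, config hash) is carried in ``#``-prefixed comment lines above the
header.  Readers validate and reject malformed input with line numbers
rather than silently coercing.

Formats:

* hypnogram — ``time_s,score`` with scores ``W``/``N``/``R``/``M``
* band powers — ``time_s,slow,delta,sigma,full`` (non-negative, no gaps)
* photometry — ``time_s,F`` (strictly increasing time; empty F values
  permitted and flagged as gaps)
* dF/F — ``time_s,dff,z,nrem``
* stimulation log — ``onset_s,duration_s``
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bandpower import BANDS, EpochPowerSeries
from .closed_loop import StimulationLog
from .hypnogram import STATES, Hypnogram
from .photometry import DffSeries, PhotometryTrace

__all__ = [
    "read_hypnogram", "write_hypnogram",
    "read_band_powers", "write_band_powers",
    "read_photometry", "write_photometry",
    "write_dff", "write_stim_log", "write_json",
]


def _read_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def _write_csv(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    for k, v in (metadata or {}).items():
        buf.write(f"# {k}={v}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def _check_uniform_grid(time: np.ndarray, path) -> float:
    if time.size < 2:
        raise ValueError(f"{path}: need at least 2 rows to infer the epoch grid")
    deltas = np.diff(time)
    if not np.all(deltas > 0):
        i = int(np.flatnonzero(deltas <= 0)[0])
        raise ValueError(f"{path}: times not strictly increasing at data row {i + 2}")
    el = float(deltas[0])
    bad = np.abs(deltas - el) > 1e-6
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{path}: non-uniform epoch grid at data row {i + 2}")
    return el


def read_hypnogram(path) -> Hypnogram:
    df = _read_csv(path, dtype={"score": str})
    if list(df.columns) != ["time_s", "score"]:
        raise ValueError(f"{path}: expected header 'time_s,score', got {list(df.columns)}")
    time = df["time_s"].to_numpy(dtype=float)
    el = _check_uniform_grid(time, path)
    scores = df["score"].to_numpy()
    bad = ~np.isin(scores, STATES)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{path}: unknown score {scores[i]!r} at data row {i + 2}")
    return Hypnogram(scores, epoch_length=el, start_time=float(time[0]))


def write_hypnogram(hyp: Hypnogram, path, metadata: dict | None = None) -> None:
    _write_csv(pd.DataFrame({"time_s": hyp.times, "score": hyp.scores}), path, metadata)


def read_band_powers(path) -> EpochPowerSeries:
    df = _read_csv(path)
    expected = ["time_s", *BANDS]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header {','.join(expected)}")
    if df[list(BANDS)].isna().any().any():
        col = df[list(BANDS)].isna().any().idxmax()
        i = int(df[col].isna().idxmax())
        raise ValueError(f"{path}: missing {col} value at data row {i + 2}")
    neg = (df[list(BANDS)] < 0).any()
    if neg.any():
        col = neg.idxmax()
        i = int((df[col] < 0).idxmax())
        raise ValueError(f"{path}: negative {col} power at data row {i + 2}")
    time = df["time_s"].to_numpy(dtype=float)
    _check_uniform_grid(time, path)
    return EpochPowerSeries(time, df[list(BANDS)].reset_index(drop=True))


def write_band_powers(powers: EpochPowerSeries, path, metadata: dict | None = None) -> None:
    df = powers.powers.copy()
    df.insert(0, "time_s", powers.time)
    _write_csv(df, path, metadata)


def read_photometry(path) -> tuple[PhotometryTrace, np.ndarray]:
    """Read a photometry trace; returns (trace, gap mask over kept samples).

    Rows with missing F are dropped from the trace and flagged in the gap
    mask (True at samples adjacent to a dropped row).
    """
    df = _read_csv(path)
    if list(df.columns) != ["time_s", "F"]:
        raise ValueError(f"{path}: expected header 'time_s,F'")
    time = df["time_s"].to_numpy(dtype=float)
    if not np.all(np.diff(time) > 0):
        i = int(np.flatnonzero(np.diff(time) <= 0)[0])
        raise ValueError(f"{path}: non-monotone time at data row {i + 2}")
    f = df["F"].to_numpy(dtype=float)
    missing = ~np.isfinite(f)
    trace = PhotometryTrace(time[~missing], f[~missing])
    gap = np.zeros(trace.time.size, dtype=bool)
    if missing.any():
        kept = np.flatnonzero(~missing)
        pos = np.searchsorted(kept, np.flatnonzero(missing))
        gap[np.clip(pos - 1, 0, gap.size - 1)] = True
        gap[np.clip(pos, 0, gap.size - 1)] = True
    return trace, gap


def write_photometry(trace: PhotometryTrace, path, metadata: dict | None = None) -> None:
    _write_csv(pd.DataFrame({"time_s": trace.time, "F": trace.F}), path, metadata)


def write_dff(dff: DffSeries, path, metadata: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "time_s": dff.time,
            "dff": dff.dff,
            "z": dff.z if dff.z is not None else np.nan,
            "nrem": dff.nrem_mask.astype(int),
        }
    )
    _write_csv(df, path, metadata)


def write_stim_log(log: StimulationLog, path, metadata: dict | None = None) -> None:
    _write_csv(log.to_frame(), path, metadata)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return super().default(o)


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder, allow_nan=True) + "\n")
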