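"""Delimited-text file formats for recordings, metadata and results.

One subject is stored as two CSV files — ``<id>_nirs.csv`` (time plus the
four 20 Hz hemoglobin channels) and ``<id>_abp.csv`` (time plus the
1000 Hz pressure channel) — alongside a cohort-level ``metadata.csv``
(subject_id, group, moca, plus any ground-truth columns the generator
adds, prefixed ``true_``/``drawn_``). Times are in seconds from zero; the
sampling rate is inferred from the median time step and checked for
uniformity.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .timeseries import ALL_CHANNELS, NIRS_CHANNELS, Recording, TimeSeries

__all__ = ["read_recording", "write_recording", "read_cohort", "write_cohort"]

_UNITS = {c: "umol/L" for c in NIRS_CHANNELS} | {"ABP": "mmHg"}


def _read_signal_file(path) -> dict[str, TimeSeries]:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as CSV ({exc})") from exc
    if df.shape[1] < 2 or df.columns[0] != "time":
        raise FormatError(f"{path}: first column must be 'time'")
    t = df["time"].to_numpy(dtype=float)
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise FormatError(
            f"{path}: non-monotone time at line {bad[0] + 2}"
        )
    med = float(np.median(dt))
    jitter = np.abs(dt - med) / med
    bad = np.flatnonzero(jitter > 0.01)
    if bad.size:
        raise FormatError(
            f"{path}: sampling jitter > 1% at line {bad[0] + 2}"
        )
    rate = 1.0 / med
    if abs(rate - round(rate)) < 1e-4 * rate:  # snap float-precision residue
        rate = float(round(rate))
    out = {}
    for col in df.columns[1:]:
        if col not in ALL_CHANNELS:
            raise FormatError(
                f"{path}: unknown channel {col!r}; expected one of {ALL_CHANNELS}"
            )
        out[col] = TimeSeries(df[col].to_numpy(dtype=float), rate,
                              label=col, units=_UNITS[col])
    return out


def read_recording(signal_paths, subject_id: str = "") -> Recording:
    """Read one subject's Recording from one or more delimited signal files."""
    channels: dict[str, TimeSeries] = {}
    for p in signal_paths:
        channels.update(_read_signal_file(p))
    missing = [c for c in ALL_CHANNELS if c not in channels]
    if missing:
        raise FormatError(f"missing channels across files: {missing}")
    return Recording(channels, subject_id=subject_id)


def write_recording(rec: Recording, out_dir) -> list[Path]:
    """Write one Recording as ``<id>_nirs.csv`` + ``<id>_abp.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = rec.subject_id or "S000"

    nirs = {c: rec.channels[c] for c in NIRS_CHANNELS}
    rate = next(iter(nirs.values())).sampling_rate
    n = min(ts.n_samples for ts in nirs.values())
    df = pd.DataFrame({"time": np.arange(n) / rate}
                      | {c: ts.values[:n] for c, ts in nirs.items()})
    p_nirs = out_dir / f"{sid}_nirs.csv"
    df.to_csv(p_nirs, index=False, float_format="%.6f")

    abp = rec.channels["ABP"]
    p_abp = out_dir / f"{sid}_abp.csv"
    pd.DataFrame({"time": abp.times, "ABP": abp.values}).to_csv(
        p_abp, index=False, float_format="%.6f")
    return [p_nirs, p_abp]


def write_cohort(cohort, out_dir) -> Path:
    """Write every subject's signal files plus the cohort metadata table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in cohort.recordings:
        write_recording(rec, out_dir)
    meta_path = out_dir / "metadata.csv"
    cohort.metadata.to_csv(meta_path, index=False)
    return meta_path


def read_cohort(in_dir):
    """Read a cohort directory written by :func:`write_cohort`."""
    from .synthetic import Cohort

    in_dir = Path(in_dir)
    meta_path = in_dir / "metadata.csv"
    if not meta_path.exists():
        raise FormatError(f"{meta_path}: metadata table not found")
    metadata = pd.read_csv(meta_path)
    recs = []
    for sid in metadata["subject_id"]:
        paths = [in_dir / f"{sid}_nirs.csv", in_dir / f"{sid}_abp.csv"]
        for p in paths:
            if not p.exists():
                raise FormatError(f"{p}: signal file not found")
        recs.append(read_recording(paths, subject_id=str(sid)))
    return Cohort(recs, metadata)
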