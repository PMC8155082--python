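"""Signal and report I/O.

CSV is the canonical on-disk signal format: UTF-8, header ``time_s,uv``,
'.' decimal, full-precision floats (the default float repr round-trips
exactly).  The sampling rate is inferred from the time column when it is
uniform; a bare ``uv`` column needs an explicit rate — never a silent
default.  EDF recordings are read through :mod:`mne` (amplitudes are
converted to microvolts); EDF writing is not offered.

Synthetic epochs are written as a file family
``<stem>_x.csv`` / ``<stem>_clean.csv`` / ``<stem>_artifact.csv`` plus a
``<stem>_truth.json`` sidecar carrying the ground truth (onsets, durations,
mixing constant, seed).  :class:`RunReport` serialises a whole run —
config echo, per-epoch metric blocks, tool version, seed — to JSON and
back, losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChannelNotFoundError, MissingSamplingRateError
from .ssa import Signal1D
from .synth import SyntheticEpoch

__all__ = [
    "read_signal",
    "write_signal",
    "write_epoch",
    "read_epoch_truth",
    "RunReport",
]

#: relative tolerance for declaring the CSV time column uniform
_UNIFORM_RTOL = 1e-6


def write_signal(signal: Signal1D, path) -> Path:
    """Write a signal as a two-column ``time_s,uv`` CSV (full precision)."""
    path = Path(path)
    frame = pd.DataFrame({"time_s": signal.times, "uv": signal.samples})
    frame.to_csv(path, index=False)
    return path


def _read_csv(path: Path, fs_override: float | None, channel: str | None) -> Signal1D:
    frame = pd.read_csv(path, float_precision="round_trip")  # bitwise re-read
    if frame.shape[0] < 2:
        raise ValueError(f"{path}: fewer than 2 samples")
    if channel is not None:
        if channel not in frame.columns:
            raise ChannelNotFoundError(f"{path}: no column {channel!r}")
        value_col = channel
    elif "uv" in frame.columns:
        value_col = "uv"
    elif len([c for c in frame.columns if c != "time_s"]) == 1:
        value_col = [c for c in frame.columns if c != "time_s"][0]
    else:
        raise ChannelNotFoundError(
            f"{path}: ambiguous columns {list(frame.columns)}; pass channel="
        )
    values = pd.to_numeric(frame[value_col], errors="raise").to_numpy(float)

    fs = fs_override
    if fs is None and "time_s" in frame.columns:
        t = pd.to_numeric(frame["time_s"], errors="raise").to_numpy(float)
        dt = np.diff(t)
        if dt.size and np.all(dt > 0) and np.allclose(dt, dt[0], rtol=_UNIFORM_RTOL):
            fs = 1.0 / float(np.mean(dt))
    if fs is None:
        raise MissingSamplingRateError(
            f"{path}: no uniform time column and no sampling-rate override"
        )
    return Signal1D(values, fs)


def _read_edf(path: Path, channel: str | None, fs_override: float | None) -> Signal1D:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = raw.ch_names
    if channel is None:
        if len(names) != 1:
            raise ChannelNotFoundError(
                f"{path}: {len(names)} channels {names}; pass channel="
            )
        channel = names[0]
    if channel not in names:
        raise ChannelNotFoundError(f"{path}: channel {channel!r} not in {names}")
    data = raw.get_data(picks=[channel])[0] * 1e6  # mne returns volts
    fs = fs_override if fs_override is not None else float(raw.info["sfreq"])
    return Signal1D(data, fs)


def read_signal(
    path,
    fmt: str | None = None,
    channel: str | None = None,
    fs_override: float | None = None,
) -> Signal1D:
    """Load a single-channel signal from CSV or EDF.

    ``fmt`` is inferred from the suffix when omitted.  For CSV the value
    column is ``channel``, else ``uv``, else the only non-time column; for
    EDF the named channel (required when the file has several).  The
    sampling rate comes from the EDF header or the CSV time column, with
    ``fs_override`` taking precedence; a CSV without either raises
    :class:`MissingSamplingRateError` explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return _read_csv(path, fs_override, channel)
    if fmt == "edf":
        return _read_edf(path, channel, fs_override)
    raise ValueError(f"unsupported format {fmt!r} (csv or edf)")


def write_epoch(epoch: SyntheticEpoch, outdir, stem: str) -> dict[str, Path]:
    """Write one synthetic epoch as the CSV family + truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "x": write_signal(epoch.contaminated, outdir / f"{stem}_x.csv"),
        "clean": write_signal(epoch.clean, outdir / f"{stem}_clean.csv"),
        "artifact": write_signal(epoch.artifact, outdir / f"{stem}_artifact.csv"),
    }
    truth = {
        "p": epoch.p,
        "seed": epoch.seed,
        "fs": epoch.clean.fs,
        "blink_onsets": list(epoch.blink_onsets),
        "blink_durations_ms": list(epoch.blink_durations_ms),
    }
    sidecar = outdir / f"{stem}_truth.json"
    sidecar.write_text(json.dumps(truth, indent=1))
    paths["truth"] = sidecar
    return paths


def read_epoch_truth(path) -> dict:
    """Load a ground-truth sidecar written by :func:`write_epoch`."""
    return json.loads(Path(path).read_text())


@dataclass
class RunReport:
    """JSON-serialisable record of one tool run.

    ``epochs`` holds one metric block per processed epoch (rrmse, cc, band
    MAE, FPR where ground truth was available, FD values, bypass flag).
    """

    config: dict
    seed: int
    version: str
    epochs: list[dict] = field(default_factory=list)

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path
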