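"""Reading and writing multichannel time series.

Native format: a delimited numeric matrix (CSV/TSV) with a header row of
channel labels and one row per sample, plus the sampling rate supplied
either as an argument or via a JSON sidecar (``<stem>.json`` holding
``{"fs": ...}``).  A transposed layout (one row per channel, no header) is
auto-detected.  EDF files are read through :mod:`mne` when it is installed
(``pip install petd[edf]``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .ordinal import TimeSeries

__all__ = ["MultichannelSeries", "read_timeseries", "write_timeseries"]


@dataclass(frozen=True)
class MultichannelSeries:
    """Labelled channels sharing one sampling rate.

    ``data`` is ``(n_channels, n_samples)``; iterate to get
    ``(label, TimeSeries)`` pairs.
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=np.float64)
        if d.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(d)):
            raise ValueError("data must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        labels = tuple(str(l) for l in self.labels)
        if len(labels) != d.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for {d.shape[0]} channels"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(self, "labels", labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> TimeSeries:
        try:
            i = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None
        return TimeSeries(self.data[i], self.fs)

    def __iter__(self) -> Iterator[tuple[str, TimeSeries]]:
        for label, row in zip(self.labels, self.data):
            yield label, TimeSeries(row, self.fs)

    def __len__(self) -> int:
        return self.n_channels


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _resolve_fs(path: Path, fs: float | None) -> float:
    if fs is not None:
        return float(fs)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "fs" in meta:
            return float(meta["fs"])
    raise ValueError(
        f"sampling rate unknown for {path}: pass fs or provide a JSON sidecar "
        f"{sidecar.name} with an 'fs' field"
    )


def read_timeseries(
    path: str | Path,
    fs: float | None = None,
    orient: str = "auto",
) -> MultichannelSeries:
    """Read a CSV/TSV matrix (or EDF) into a :class:`MultichannelSeries`.

    Parameters
    ----------
    path : path-like
        ``.csv``/``.tsv`` matrix or ``.edf`` recording.
    fs : float, optional
        Sampling rate in Hz; for delimited files it may instead come from a
        ``<stem>.json`` sidecar.  Ignored for EDF (taken from the header).
    orient : {"auto", "samples", "channels"}
        What the rows of a delimited file are.  ``samples`` expects a header
        of channel labels; ``channels`` expects raw numeric rows.  ``auto``
        decides by whether the first row parses as numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    fs = _resolve_fs(path, fs)

    first = path.read_text().splitlines()[0] if path.stat().st_size else ""
    first_numeric = _row_is_numeric(first.split(sep))
    if orient == "auto":
        orient = "channels" if first_numeric else "samples"
    if orient == "channels":
        df = _read_matrix(path, sep, header=None)
        data = df.to_numpy(dtype=np.float64)
        labels = [f"ch{i}" for i in range(data.shape[0])]
    elif orient == "samples":
        if first_numeric:
            raise ValueError(
                f"{path}: orient='samples' requires a header row of channel labels"
            )
        df = _read_matrix(path, sep, header=0)
        labels = [str(c) for c in df.columns]
        data = df.to_numpy(dtype=np.float64).T
    else:
        raise ValueError(f"unknown orient {orient!r}")
    return MultichannelSeries(data, fs, labels)


def _row_is_numeric(cells) -> bool:
    try:
        [float(c) for c in cells]
        return True
    except ValueError:
        return False


def _read_matrix(path: Path, sep: str, header) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, header=header)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed matrix — {exc}") from exc


def write_timeseries(
    mc: MultichannelSeries,
    path: str | Path,
    sidecar: bool = True,
) -> Path:
    """Write channels as a CSV/TSV (header labels, one row per sample).

    With ``sidecar`` a ``<stem>.json`` holding the sampling rate is written
    next to the matrix, so ``read_timeseries`` can round-trip without flags.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.DataFrame(mc.data.T, columns=list(mc.labels))
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")
    if sidecar:
        _sidecar_path(path).write_text(json.dumps({"fs": mc.fs}))
    return path


def _read_edf(path: Path) -> MultichannelSeries:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - env dependent
        raise ImportError(
            "reading EDF requires the optional 'mne' dependency "
            "(pip install petd[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    extras = getattr(raw, "_raw_extras", None)
    if extras and "n_samps" in extras[0]:
        n_samps = np.asarray(extras[0]["n_samps"])
        if np.unique(n_samps[n_samps > 0]).size > 1:
            raise ValueError(
                f"{path}: channels have mixed sampling rates; a uniform fs is required"
            )
    return MultichannelSeries(raw.get_data(), float(raw.info["sfreq"]), tuple(raw.ch_names))
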