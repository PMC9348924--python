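"""Reading and writing heart-sound signals.

Two on-disk formats are supported: RIFF/WAV audio (the natural container for
digital-stethoscope recordings) and delimited-text amplitude logs of the kind
produced by serial data loggers, which carry no sampling rate of their own.

Amplitude convention
--------------------
Integer PCM is rescaled to float in [-1, 1] by dividing by the type's maximum
magnitude; float WAV data is used as-is.  No automatic gain normalisation is
ever applied: the downstream screening thresholds are absolute amplitudes, and
a gain step would invalidate them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = ["PcgSignal", "read_wav", "read_serial_csv", "write_wav"]


@dataclass
class PcgSignal:
    """A sampled heart-sound amplitude series.

    Parameters
    ----------
    samples : array-like of float
        Amplitude values, dimensionless, nominally in [-1, 1].
    fs : float
        Sampling rate in Hz; must be positive.
    source : str
        Free-text provenance tag (file path, simulator preset, ...).
    """

    samples: np.ndarray
    fs: float
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            self.samples = self.samples.reshape(-1)
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` if any invariant is violated."""
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples (NaN/Inf)")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Signal length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


# Full-scale divisors for integer PCM.
_PCM_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
}


def read_wav(path: str | os.PathLike) -> PcgSignal:
    """Read a mono PCG from a RIFF/WAV file.

    Integer PCM is rescaled to [-1, 1]; multi-channel audio is averaged to
    mono; the sampling rate is taken from the file header.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    try:
        fs, data = wavfile.read(os.fspath(path))
    except ValueError as exc:
        raise ValueError(f"malformed WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"WAV file {path} contains no audio samples")
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        x = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        x = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    else:
        x = data.astype(np.float64)
    if x.ndim > 1:
        x = x.mean(axis=1)
    return PcgSignal(x, float(fs), source=os.fspath(path))


def read_serial_csv(path: str | os.PathLike, fs: float) -> PcgSignal:
    """Read an amplitude series from a serial-logger text export.

    Accepts comma- or whitespace-delimited text with an optional single
    header row.  The amplitude is taken from the last fully numeric column
    (logger exports typically write ``time, amplitude``).  The sampling rate
    must be supplied by the caller: logger exports do not record one.
    """
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=r"[,;\t ]+", engine="python", header=None,
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: file contains no data rows") from exc
    # Drop a single leading header row if it is entirely non-numeric.
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().all():
        df = df.iloc[1:]
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows after header")
    # Amplitude = last column whose every entry parses as a number.
    for col in reversed(df.columns.tolist()):
        values = pd.to_numeric(df[col], errors="coerce")
        if values.notna().all():
            return PcgSignal(values.to_numpy(dtype=np.float64), float(fs),
                             source=os.fspath(path))
    raise ValueError(f"{path}: no numeric amplitude column found")


def write_wav(signal: PcgSignal, path: str | os.PathLike) -> None:
    """Write a PCG as 32-bit float mono WAV at ``signal.fs``.

    Round-trips through :func:`read_wav` reproduce the samples to within
    float32 precision (~1e-7) and the (integer) sampling rate exactly.
    """
    signal.validate()
    wavfile.write(os.fspath(path), int(round(signal.fs)),
                  signal.samples.astype(np.float32))
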