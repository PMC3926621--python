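"""Recording ingestion, epoching, demeaning, and performance metrics.

A recording is a samples x channels matrix, nominally sampled at 128 Hz with
12-bit integer amplitudes.  The codec operates on non-overlapping epochs of
``N`` samples (default 512); each channel of an epoch is demeaned before
sensing and the removed means travel in the compressed header so the server
can restore them.

Two figures of merit are used throughout:

* compression ratio  CR = b / b_hat  (original bits over compressed bits);
* normalized mean square error
  NMSE(x, y) = ||x - y||^2 / ||x - mean(x)||^2,
  so 0 is a perfect reconstruction and 1 is as bad as predicting the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np


@dataclass
class RawRecording:
    """A multichannel recording: ``samples`` is T x C, one column per channel."""

    samples: np.ndarray
    fs: float = 128.0
    labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a T x C matrix")
        if self.samples.shape[0] < 1 or self.samples.shape[1] < 1:
            raise ValueError("need at least one sample and one channel")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.samples.shape[1])]
        elif len(self.labels) != self.samples.shape[1]:
            raise ValueError("label count does not match channel count")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass
class Epoch:
    """One N x C window of a recording."""

    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2:
            raise ValueError("epoch must be an N x C matrix")

    @property
    def N(self) -> int:
        return self.F.shape[0]

    @property
    def C(self) -> int:
        return self.F.shape[1]


@dataclass
class DemeanedEpoch:
    """An epoch with per-channel means removed and stored separately."""

    Ftilde: np.ndarray
    means: np.ndarray

    @property
    def N(self) -> int:
        return self.Ftilde.shape[0]

    @property
    def C(self) -> int:
        return self.Ftilde.shape[1]


def remove_dead_channels(rec: RawRecording) -> RawRecording:
    """Drop channels that are identically zero (they carry no information)."""
    alive = ~np.all(rec.samples == 0.0, axis=0)
    if alive.all():
        return rec
    dropped = [lab for lab, ok in zip(rec.labels, alive) if not ok]
    warnings.warn(f"removed dead channels: {dropped}", stacklevel=2)
    if not alive.any():
        raise ValueError("all channels are dead")
    return RawRecording(
        rec.samples[:, alive],
        fs=rec.fs,
        labels=[lab for lab, ok in zip(rec.labels, alive) if ok],
    )


def resample_recording(rec: RawRecording, fs_target: float = 128.0) -> RawRecording:
    """Polyphase resampling to the telemonitoring rate (default 128 Hz)."""
    from fractions import Fraction

    from scipy.signal import resample_poly

    if rec.fs == fs_target:
        return rec
    frac = Fraction(fs_target / rec.fs).limit_denominator(1000)
    out = resample_poly(rec.samples, frac.numerator, frac.denominator, axis=0)
    return RawRecording(out, fs=fs_target, labels=list(rec.labels))


def epoch_stream(rec: RawRecording, N: int = 512) -> Iterator[Epoch]:
    """Yield non-overlapping N-sample epochs; a trailing partial window is dropped."""
    if N < 2:
        raise ValueError("epoch length must be at least 2")
    T = rec.n_samples
    if T < N:
        raise ValueError("recording shorter than one epoch")
    for k in range(T // N):
        yield Epoch(rec.samples[k * N : (k + 1) * N].copy())


def demean(e: Epoch) -> DemeanedEpoch:
    means = e.F.mean(axis=0)
    return DemeanedEpoch(e.F - means, means)


def add_means(d: DemeanedEpoch) -> Epoch:
    return Epoch(d.Ftilde + d.means)


def nmse(x: np.ndarray, y: np.ndarray) -> float:
    """Normalized mean square error ||x - y||^2 / ||x - mean(x)||^2."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    denom = float(np.sum((x - x.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("zero denominator: x is constant")
    return float(np.sum((x - y) ** 2)) / denom


def epoch_nmse(original: Epoch, reconstructed: Epoch) -> float:
    """Mean per-channel NMSE between two epochs."""
    if original.F.shape != reconstructed.F.shape:
        raise ValueError("epoch shapes differ")
    vals = [
        nmse(original.F[:, j], reconstructed.F[:, j]) for j in range(original.C)
    ]
    return float(np.mean(vals))


def compression_ratio(b: float, bhat: float) -> float:
    """Original bits over compressed bits; > 1 means the codec shrank the data."""
    if b <= 0 or bhat <= 0:
        raise ValueError("bit counts must be positive")
    return float(b) / float(bhat)


# ---------------------------------------------------------------------------
# Readers / writers


def read_matrix_csv(path) -> RawRecording:
    """Read a delimited-text samples x channels matrix with a header row."""
    import pandas as pd

    df = pd.read_csv(path)
    return RawRecording(df.to_numpy(dtype=float), labels=[str(c) for c in df.columns])


def write_matrix_csv(path, rec: RawRecording) -> None:
    import pandas as pd

    pd.DataFrame(rec.samples, columns=list(rec.labels)).to_csv(path, index=False)


def read_edf(path, fs_target: float | None = 128.0) -> RawRecording:
    """Read a European Data Format recording (delegates to mne, optional extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    rec = RawRecording(
        raw.get_data().T, fs=float(raw.info["sfreq"]), labels=list(raw.ch_names)
    )
    rec = remove_dead_channels(rec)
    if fs_target is not None:
        rec = resample_recording(rec, fs_target)
    return rec
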