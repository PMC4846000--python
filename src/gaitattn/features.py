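"""Per-task epoching, Burg (maximum-entropy) spectra, band-power features.

Breaks are removed first and epochs are cut inside single task segments
only, so no epoch mixes two tasks.  Epochs are one second long with a
half-second step; a 60 s task therefore yields 120 epochs, the last one
right-padded by reflection (see :func:`epoch_tasks`).  Each epoch/channel
is fitted with an autoregressive model via the Burg recursion — the
reflection coefficients minimize the summed forward and backward
prediction errors — and the AR transfer function is evaluated at integer
frequencies 1..100 Hz.  Six band features per channel are the sums of the
spectral bins falling in each band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import StandardizedSession
from .session import EEGSession, Segment, TASK_CODES, concat_segments
from .simulate import BAND_EDGES

BAND_NAMES = tuple(BAND_EDGES)
SPECTRUM_FREQS = np.arange(1, 101)  # Hz, 1 Hz resolution
DEFAULT_AR_ORDER = 16


@dataclass
class EpochSet:
    """Fixed-length overlapped epochs with their task and run labels."""

    epochs: np.ndarray  # (n_epochs, n_channels, epoch_len)
    labels: np.ndarray  # (n_epochs,) task codes
    runs: np.ndarray  # (n_epochs,) run indices
    step: int

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_len(self) -> int:
        return self.epochs.shape[2]


@dataclass
class Spectrum:
    """AR power spectra at 1..100 Hz for a batch of epochs."""

    power: np.ndarray  # (..., n_channels, 100), >= 0
    ar_order: int

    def __post_init__(self) -> None:
        if self.power.shape[-1] != SPECTRUM_FREQS.size:
            raise ValueError("spectrum must cover 1..100 Hz in 1 Hz bins")


@dataclass
class BandFeatures:
    """Per-epoch 32-dimensional band-power vectors for one band."""

    band: str
    values: np.ndarray  # (n_epochs, n_channels)
    labels: np.ndarray
    runs: np.ndarray

    def __post_init__(self) -> None:
        if self.band not in BAND_EDGES:
            raise ValueError(f"unknown band {self.band!r}")


def drop_breaks(session: EEGSession) -> EEGSession:
    """Remove break segments, concatenating the task segments in order."""
    tasks = session.task_segments()
    if len(tasks) == len(session.segments):
        return session.copy()
    pieces = [session.data[:, s.start:s.end] for s in tasks]
    out = session.copy(data=np.concatenate(pieces, axis=1))
    out.segments = concat_segments(tasks)
    out.meta["breaks_removed"] = True
    return out


def _segment_epochs(n: int, epoch_len: int, step: int) -> list[int]:
    """Epoch start offsets within one segment: every multiple of ``step``
    whose epoch covers at least ``step`` real samples.  For a segment of
    k*step samples this gives k-1 full epochs plus one final right-padded
    epoch, reproducing the 60 s / 0.5 s step -> 120 epochs arithmetic."""
    return list(range(0, n - step + 1, step))


def epoch_tasks(session: EEGSession, epoch_len: int | None = None,
                step: int | None = None) -> EpochSet:
    """Cut overlapped fixed-length epochs inside each task segment.

    ``epoch_len`` defaults to one second of samples and ``step`` to half
    that.  An epoch running past its segment's end is padded by reflecting
    the segment's own samples, never with data from a neighboring task.
    """
    if epoch_len is None:
        epoch_len = int(round(session.fs))
    if step is None:
        step = epoch_len // 2
    epochs: list[np.ndarray] = []
    labels: list[str] = []
    runs: list[int] = []
    for seg in session.task_segments():
        if seg.n_samples < epoch_len:
            raise ValueError(
                f"segment {seg} shorter than one epoch ({epoch_len})"
            )
        block = session.data[:, seg.start:seg.end]
        overhang = max(0, epoch_len - step)
        if overhang:
            # reflect the segment's own tail so the padded final epoch
            # never borrows samples from a neighboring task
            block = np.pad(block, ((0, 0), (0, overhang)), mode="reflect")
        for start in _segment_epochs(seg.n_samples, epoch_len, step):
            epochs.append(block[:, start:start + epoch_len])
            labels.append(seg.kind)
            runs.append(seg.run)
    return EpochSet(
        epochs=np.stack(epochs),
        labels=np.array(labels),
        runs=np.array(runs),
        step=step,
    )


def burg_ar(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Burg AR fit, vectorized over leading axes.

    ``x`` has shape (..., n).  Returns ``(a, e)`` where ``a`` (..., order)
    are the AR coefficients of ``x[t] + sum_k a[k] x[t-k] = eps[t]`` and
    ``e`` (...,) is the final prediction-error power.  Reflection
    coefficients are the classic Burg ratio minimizing the sum of squared
    forward and backward prediction errors.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    if n < 2 * order:
        raise ValueError(f"need >= {2 * order} samples for order {order}")
    f = x.copy()
    b = x.copy()
    a = np.zeros(x.shape[:-1] + (order,))
    e = np.mean(x ** 2, axis=-1)
    for m in range(order):
        ef = f[..., 1:]
        eb = b[..., :-1]
        num = -2.0 * np.sum(ef * eb, axis=-1)
        den = np.sum(ef ** 2, axis=-1) + np.sum(eb ** 2, axis=-1)
        k = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        km = k[..., None]
        f = ef + km * eb
        b = eb + km * ef
        if m > 0:
            a[..., :m] = a[..., :m] + km * a[..., m - 1::-1]
        a[..., m] = k
        e = e * (1.0 - k ** 2)
    return a, e


def ar_psd(a: np.ndarray, e: np.ndarray, fs: float,
           freqs: np.ndarray = SPECTRUM_FREQS) -> np.ndarray:
    """One-sided AR power spectral density at the given frequencies."""
    order = a.shape[-1]
    k = np.arange(1, order + 1)
    # (n_freqs, order) complex exponentials
    z = np.exp(-2j * np.pi * np.outer(freqs, k) / fs)
    denom = np.abs(1.0 + a @ z.T) ** 2
    psd = 2.0 * e[..., None] / fs / denom
    return np.where(e[..., None] > 0, psd, 0.0)


def burg_spectrum(epochs: np.ndarray, order: int = DEFAULT_AR_ORDER,
                  fs: float = 1200.0, chunk: int = 256) -> Spectrum:
    """Burg spectra at 1..100 Hz for (..., n_samples) epochs.

    All-zero epochs yield an all-zero spectrum.  Batches are processed in
    chunks along the first axis to bound memory.
    """
    x = np.asarray(epochs)
    if x.ndim == 1:
        a, e = burg_ar(x, order)
        return Spectrum(power=ar_psd(a, e, fs), ar_order=order)
    lead = x.shape[0]
    out = np.empty(x.shape[:-1] + (SPECTRUM_FREQS.size,))
    for i in range(0, lead, chunk):
        a, e = burg_ar(x[i:i + chunk], order)
        out[i:i + chunk] = ar_psd(a, e, fs)
    return Spectrum(power=out, ar_order=order)


def band_power(spectrum: Spectrum, band: str) -> np.ndarray:
    """Sum of spectral bins in [low, high) Hz, per channel."""
    if band not in BAND_EDGES:
        raise ValueError(f"unknown band {band!r}")
    low, high = BAND_EDGES[band]
    mask = (SPECTRUM_FREQS >= low) & (SPECTRUM_FREQS < high)
    return spectrum.power[..., mask].sum(axis=-1)


def extract_features(
    standardized: StandardizedSession | EEGSession,
    order: int = DEFAULT_AR_ORDER,
) -> dict[str, BandFeatures]:
    """Break removal, epoching, Burg spectra, six band-power feature sets."""
    session = (
        standardized.session
        if isinstance(standardized, StandardizedSession)
        else standardized
    )
    epoch_set = epoch_tasks(drop_breaks(session))
    spec = burg_spectrum(epoch_set.epochs, order=order, fs=session.fs)
    return {
        band: BandFeatures(
            band=band,
            values=band_power(spec, band),
            labels=epoch_set.labels.copy(),
            runs=epoch_set.runs.copy(),
        )
        for band in BAND_NAMES
    }


def average_feature_vectors(
    features: dict[str, BandFeatures]
) -> dict[tuple[str, str], np.ndarray]:
    """Mean feature vector per (band, task) cell — 24 vectors for a full
    session — the flat export standing in for scalp topography plots."""
    out: dict[tuple[str, str], np.ndarray] = {}
    for band, bf in features.items():
        for code in TASK_CODES:
            mask = bf.labels == code
            if mask.any():
                out[(band, code)] = bf.values[mask].mean(axis=0)
    return out
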