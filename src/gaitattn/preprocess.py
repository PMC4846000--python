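"""Time-domain processing: filtering, bad-channel repair, standardization.

Pipeline order is filter -> detect -> reconstruct -> thresholds ->
standardize.  The standardization statistic is the per-channel mean of
epoch maxima ("MV threshold"): the signal is windowed into consecutive
L-sample epochs and the epoch maxima are averaged.  Every channel is then
divided by the cross-channel mean of the 32 thresholds, making sessions
comparable across users while preserving between-channel power
differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .montage import Montage
from .session import EEGSession

DEFAULT_AMP_LIMIT_UV = 50.0
DEFAULT_BAD_FRACTION = 0.05


@dataclass(frozen=True)
class MVThresholds:
    """Per-channel standardization thresholds (uV) and how they were made."""

    values: np.ndarray  # (n_channels,)
    epoch_width_L: int
    n_epochs_N: int

    def __post_init__(self) -> None:
        if self.epoch_width_L < 1:
            raise ValueError("epoch width L must be >= 1")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass
class StandardizedSession:
    """Dimensionless session: every sample divided by the cross-channel
    mean MV threshold (the ``denominator``)."""

    session: EEGSession
    thresholds: MVThresholds
    denominator: float

    @property
    def data(self) -> np.ndarray:
        return self.session.data

    @property
    def fs(self) -> float:
        return self.session.fs


def bandpass_filter(
    session: EEGSession, low: float = 0.5, high: float = 100.0,
    order: int = 4,
) -> EEGSession:
    """Zero-phase Butterworth band-pass (forward-backward)."""
    if session.fs <= 2 * high:
        raise ValueError(
            f"fs={session.fs} too low for a {high} Hz band edge"
        )
    sos = signal.butter(order, [low, high], btype="bandpass",
                        fs=session.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, session.data, axis=1)
    out = session.copy(data=filtered.astype(session.data.dtype))
    out.meta["bandpass_hz"] = [low, high]
    return out


def notch_filter(session: EEGSession, f0: float = 50.0,
                 quality: float = 35.0) -> EEGSession:
    """Zero-phase IIR notch removing the power-line component."""
    if f0 >= session.fs / 2:
        raise ValueError(f"notch frequency {f0} not below Nyquist")
    b, a = signal.iirnotch(f0, quality, fs=session.fs)
    filtered = signal.filtfilt(b, a, session.data, axis=1)
    out = session.copy(data=filtered.astype(session.data.dtype))
    out.meta["notch_hz"] = f0
    return out


def exceed_fractions(session: EEGSession,
                     amp_limit: float = DEFAULT_AMP_LIMIT_UV) -> np.ndarray:
    """Per-channel fraction of samples with |x| > amp_limit."""
    return np.mean(np.abs(session.data) > amp_limit, axis=1)


def detect_bad_channels(
    session: EEGSession,
    amp_limit: float = DEFAULT_AMP_LIMIT_UV,
    frac: float = DEFAULT_BAD_FRACTION,
) -> set[str]:
    """Channels out of the typical EEG amplitude range: flagged when the
    fraction of samples beyond +/-amp_limit strictly exceeds ``frac``."""
    fractions = exceed_fractions(session, amp_limit)
    return {
        session.montage.names[i]
        for i in np.flatnonzero(fractions > frac)
    }


def reconstruct_channels(
    session: EEGSession, bad: set[str], montage: Montage | None = None
) -> EEGSession:
    """Replace each bad channel by the pointwise mean of its good
    (non-bad) surrounding channels; good channels are untouched."""
    montage = montage or session.montage
    unknown = bad - set(montage.names)
    if unknown:
        raise ValueError(f"unknown channel labels {sorted(unknown)}")
    out = session.copy()
    sources: dict[str, list[str]] = {}
    for label in sorted(bad):
        good = sorted(montage.neighbors[label] - bad)
        if not good:
            raise ValueError(
                f"channel {label} has no good neighbors to reconstruct from"
            )
        sources[label] = good
    # All replacements are computed from the *original* data so that one
    # bad channel never feeds another's reconstruction.
    for label, good in sources.items():
        idx = [montage.index(g) for g in good]
        mean = session.data[idx].astype(np.float64).mean(axis=0)
        out.data[montage.index(label)] = mean.astype(session.data.dtype)
    out.meta.setdefault("reconstructed", {}).update(sources)
    return out


def mv_threshold(channel_signal: np.ndarray, L: int,
                 absolute: bool = False) -> float:
    """Mean of per-epoch maxima over consecutive non-overlapping L-sample
    epochs starting at sample 0; trailing samples not filling an epoch are
    dropped.  With ``absolute`` the maxima are taken on |x|."""
    x = np.asarray(channel_signal)
    if x.ndim != 1:
        raise ValueError("expected a 1-D channel signal")
    if L < 1:
        raise ValueError("L must be >= 1")
    n_epochs = x.size // L
    if n_epochs == 0:
        raise ValueError(f"signal of length {x.size} shorter than L={L}")
    trimmed = x[: n_epochs * L].reshape(n_epochs, L)
    if absolute:
        trimmed = np.abs(trimmed)
    return float(trimmed.max(axis=1).mean())


def mv_threshold_curve(
    channel_signal: np.ndarray, L_values, absolute: bool = False
) -> list[tuple[int, float]]:
    """Threshold as a function of the epoch width L."""
    x = np.asarray(channel_signal)
    out = []
    for L in L_values:
        if L > x.size:
            raise ValueError(f"L={L} exceeds signal length {x.size}")
        out.append((int(L), mv_threshold(x, int(L), absolute=absolute)))
    return out


def mv_thresholds(session: EEGSession, L: int | None = None,
                  absolute: bool = False) -> MVThresholds:
    """One threshold per channel; L defaults to one second of samples."""
    if L is None:
        L = int(round(session.fs))
    values = np.array(
        [mv_threshold(session.data[c], L, absolute=absolute)
         for c in range(session.n_channels)]
    )
    return MVThresholds(values=values, epoch_width_L=int(L),
                        n_epochs_N=session.n_samples // int(L))


def standardize(session: EEGSession,
                thresholds: MVThresholds) -> StandardizedSession:
    """Divide every sample by the cross-channel mean threshold."""
    if thresholds.values.shape != (session.n_channels,):
        raise ValueError("one threshold per channel required")
    denominator = thresholds.mean
    if denominator == 0:
        raise ValueError("zero denominator: session has no signal")
    out = session.copy(data=session.data / np.float32(denominator))
    out.meta["standardized_by"] = denominator
    return StandardizedSession(session=out, thresholds=thresholds,
                               denominator=denominator)


def preprocess(
    session: EEGSession,
    low: float = 0.5,
    high: float = 100.0,
    notch_hz: float = 50.0,
    amp_limit: float = DEFAULT_AMP_LIMIT_UV,
    frac: float = DEFAULT_BAD_FRACTION,
    mv_L: int | None = None,
) -> tuple[StandardizedSession, dict]:
    """Full time-domain stage; returns the standardized session and a
    report (bad channels, exceed fractions, reconstruction sources)."""
    filtered = notch_filter(bandpass_filter(session, low, high), notch_hz)
    fractions = exceed_fractions(filtered, amp_limit)
    bad = detect_bad_channels(filtered, amp_limit, frac)
    repaired = reconstruct_channels(filtered, bad) if bad else filtered
    thresholds = mv_thresholds(repaired, mv_L)
    standardized = standardize(repaired, thresholds)
    report = {
        "bad_channels": sorted(bad),
        "exceed_fraction": {
            name: float(fractions[i])
            for i, name in enumerate(session.montage.names)
        },
        "reconstructed_from": repaired.meta.get("reconstructed", {}),
        "mv_threshold": {
            name: float(thresholds.values[i])
            for i, name in enumerate(session.montage.names)
        },
        "denominator": thresholds.mean,
    }
    return standardized, report
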