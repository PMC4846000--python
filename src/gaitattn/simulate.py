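"""Synthetic treadmill-walking EEG sessions.

The generator emits sessions with the statistical structure the analysis
pipeline assumes: spatially correlated 1/f background bounded within the
typical +/-50 uV EEG range, 50 Hz line interference, stride-locked
low-frequency motion artifacts strongest frontally, frontal blink
transients, a left/right alternating motor-cortex alpha rhythm, and a
band-limited oscillatory "class" process whose power is scaled per task by
configurable gains (the decodable signal).  Optionally some channels are
replaced by out-of-range garbage to exercise bad-channel handling.

Nothing here is a claim about real recordings: amplitudes are free
parameters of :class:`SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import scipy.fft as sfft

from .montage import REGIONS, region_indices, standard_montage
from .session import EEGSession, TASK_CODES, session_layout

#: band name -> (low, high) Hz, half-open [low, high)
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma_low": (30.0, 50.0),
    "gamma_high": (50.0, 90.0),
}

#: gain map type: task code -> {(band, region): multiplicative power gain}
GainMap = Mapping[str, Mapping[tuple[str, str], float]]


def _default_class_gain() -> dict[str, dict[tuple[str, str], float]]:
    # Occipito-parietal gamma power ordered B, C > A > D: the distractor
    # tasks push visual processing up, the high-gait-attention task down.
    gains = {"A": 1.4, "B": 2.0, "C": 1.9, "D": 1.0}
    return {
        code: {
            ("gamma_low", "occipito_parietal"): g,
            ("gamma_high", "occipito_parietal"): g,
        }
        for code, g in gains.items()
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic session generator (amplitudes in uV)."""

    fs: float = 1200.0
    n_runs: int = 8
    task_duration_s: float = 60.0
    break_duration_s: float = 60.0
    background_scale: float = 12.0  # std of the 1/f background
    line_noise_amp: float = 4.0  # 50 Hz amplitude
    alpha_motor_amp: float = 6.0  # 8-12 Hz over the motor strip
    gait_artifact_amp: float = 9.0  # stride-locked delta/theta components
    blink_rate: float = 4.0  # events per minute
    blink_amp: float = 22.0  # peak amplitude at FZ
    stride_hz: float = 0.8  # stride fundamental at 2 km/h
    n_stride_harmonics: int = 6
    class_base_amp: float = 2.5  # amplitude of the class process at gain 1
    class_gain: GainMap = field(default_factory=_default_class_gain)
    bad_channels: Sequence[tuple[str, float]] = ()
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "background_scale", "line_noise_amp", "alpha_motor_amp",
            "gait_artifact_amp", "blink_rate", "blink_amp", "class_base_amp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.stride_hz <= 0:
            raise ValueError("stride_hz must be > 0")
        if self.fs <= 0 or self.n_runs < 1:
            raise ValueError("invalid fs / n_runs")
        for code, gains in self.class_gain.items():
            if code not in TASK_CODES:
                raise ValueError(f"unknown task code {code!r} in class_gain")
            for (band, region), g in gains.items():
                if band not in BAND_EDGES:
                    raise ValueError(f"unknown band {band!r}")
                if region not in REGIONS:
                    raise ValueError(f"unknown region {region!r}")
                if g <= 0:
                    raise ValueError("class gains must be > 0")

    def null(self) -> "SimConfig":
        """Copy with every class gain forced to 1 (no task structure)."""
        flat = {
            code: {key: 1.0 for key in gains}
            for code, gains in self.class_gain.items()
        }
        return replace(self, class_gain=flat)


def _shaped_noise(rng: np.random.Generator, shape: tuple[int, int],
                  fs: float,
                  band: tuple[float, float] | None = None) -> np.ndarray:
    """Unit-std Gaussian noise rows, 1/f-shaped (band=None) or band-limited."""
    m, n = shape
    nfft = sfft.next_fast_len(n, real=True)
    white = rng.standard_normal((m, nfft), dtype=np.float32)
    spec = sfft.rfft(white, axis=-1)
    f = sfft.rfftfreq(nfft, d=1.0 / fs)
    if band is None:
        amp = 1.0 / np.sqrt(np.maximum(f, 1.0))  # flat below 1 Hz
        amp[0] = 0.0
    else:
        lo, hi = band
        amp = ((f >= lo) & (f < hi)).astype(float)
    spec *= amp[None, :].astype(np.float32)
    x = sfft.irfft(spec, nfft, axis=-1)[:, :n]
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _spatial_mixer(montage, length_scale: float = 0.35) -> np.ndarray:
    """Row-normalized square root of a distance-decay covariance, used to
    give the background noise volume-conduction-like channel correlation."""
    pos = montage.position_array()
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    cov = np.exp(-((d / length_scale) ** 2))
    w, v = np.linalg.eigh(cov)
    s = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    return s / np.linalg.norm(s, axis=1, keepdims=True)


def _anterior_weight(montage) -> np.ndarray:
    y = montage.position_array()[:, 1]
    return 0.35 + 0.65 * (y - y.min()) / (y.max() - y.min())


def generate_session(config: SimConfig) -> EEGSession:
    """Generate one full synthetic session laid out as 8 runs x (A,B,C,D)
    with breaks between runs.  Identical config (incl. seed) gives
    bit-identical samples."""
    config.validate()
    montage = standard_montage()
    segments = session_layout(
        config.fs, config.n_runs, config.task_duration_s,
        config.break_duration_s,
    )
    n = segments[-1].end
    n_ch = len(montage)
    fs = config.fs
    rng = np.random.default_rng(config.seed)
    t = np.arange(n) / fs
    data = np.zeros((n_ch, n), dtype=np.float32)

    # -- correlated 1/f cortical background -------------------------------
    if config.background_scale > 0:
        src = _shaped_noise(rng, (n_ch, n), fs)
        mixer = _spatial_mixer(montage).astype(np.float32)
        data += np.float32(config.background_scale) * (mixer @ src)
        del src

    # -- 50 Hz line interference ------------------------------------------
    if config.line_noise_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        line = np.sin(2 * np.pi * 50.0 * t).astype(np.float32)
        quad = np.cos(2 * np.pi * 50.0 * t).astype(np.float32)
        for c in range(n_ch):
            data[c] += np.float32(config.line_noise_amp) * (
                np.float32(np.cos(phases[c])) * line
                + np.float32(np.sin(phases[c])) * quad
            )

    # -- stride-locked motion artifact, strongest frontally ----------------
    if config.gait_artifact_amp > 0:
        k = np.arange(1, config.n_stride_harmonics + 1)
        weights = (1.0 / k) / np.sum(1.0 / k)
        phases = rng.uniform(0, 2 * np.pi, k.size)
        gait = np.zeros(n)
        for kk, w, ph in zip(k, weights, phases):
            gait += w * np.sin(2 * np.pi * kk * config.stride_hz * t + ph)
        gait32 = gait.astype(np.float32)
        w_ch = config.gait_artifact_amp * _anterior_weight(montage)
        for c in range(n_ch):
            data[c] += np.float32(w_ch[c]) * gait32

    # -- frontal blink transients -----------------------------------------
    n_blinks = rng.poisson(config.blink_rate * n / fs / 60.0) if config.blink_rate > 0 else 0
    blink_times = np.sort(rng.uniform(0, n / fs, n_blinks))
    if config.blink_amp > 0 and n_blinks:
        y = montage.position_array()[:, 1]
        w_blink = np.exp(-(y.max() - y) / 0.25)  # decays away from the front
        sigma = 0.09  # seconds
        half = int(4 * sigma * fs)
        kernel = np.exp(
            -0.5 * ((np.arange(-half, half + 1) / fs) / sigma) ** 2
        )
        pulse = np.zeros(n)
        for bt in blink_times:
            i = int(bt * fs)
            lo, hi = max(0, i - half), min(n, i + half + 1)
            pulse[lo:hi] += kernel[lo - (i - half): hi - (i - half)]
        data += (config.blink_amp * w_blink[:, None] * pulse[None, :]).astype(
            np.float32
        )

    # -- alternating left/right motor alpha rhythm ------------------------
    if config.alpha_motor_amp > 0:
        alpha = np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
        env = 0.5 + 0.5 * np.sin(2 * np.pi * (config.stride_hz / 2.0) * t)
        for region, e in (("motor_left", env), ("motor_right", 1.0 - env)):
            idx = region_indices(montage, region)
            data[idx] += (config.alpha_motor_amp * alpha * e).astype(
                np.float32
            )
        mid = montage.index("CZ")
        data[mid] += (0.5 * config.alpha_motor_amp * alpha).astype(np.float32)

    # -- task-dependent band-limited class process ------------------------
    keys = sorted({key for gains in config.class_gain.values()
                   for key in gains})
    if config.class_base_amp > 0:
        for band, region in keys:
            idx = region_indices(montage, region)
            proc = _shaped_noise(rng, (idx.size, n), fs,
                                 BAND_EDGES[band]).astype(np.float32)
            scale = np.ones(n, dtype=np.float32)
            for seg in segments:
                g = config.class_gain.get(seg.kind, {}).get((band, region),
                                                            1.0)
                if g != 1.0:
                    scale[seg.start:seg.end] = np.sqrt(g)
            data[idx] += config.class_base_amp * proc * scale[None, :]

    session = EEGSession(
        data=data,
        fs=fs,
        montage=montage,
        segments=segments,
        meta={
            "generator": "gaitattn.simulate",
            "seed": config.seed,
            "class_gain": {
                code: {f"{band}:{region}": g
                       for (band, region), g in gains.items()}
                for code, gains in config.class_gain.items()
            },
        },
    )
    if config.bad_channels:
        session = corrupt_channels(session, config.bad_channels)
    session.validate()
    return session


def generate_null_session(config: SimConfig) -> EEGSession:
    """Like :func:`generate_session` but with all class gains forced to 1,
    so band power carries no task information."""
    session = generate_session(config.null())
    session.meta["class_gain"] = "null"
    return session


def corrupt_channels(
    session: EEGSession, bad: Sequence[tuple[str, float]]
) -> EEGSession:
    """Replace the named channels with persistently out-of-range signals
    (slow drift plus a large oscillation); everything else is untouched."""
    for label, _ in bad:
        if label not in session.montage.names:
            raise ValueError(f"unknown channel label {label!r}")
    out = session.copy()
    t = np.arange(session.n_samples) / session.fs
    for label, amp in bad:
        i = session.montage.index(label)
        phase = 0.7 * (i + 1)
        garbage = amp * (
            0.7 * np.sin(2 * np.pi * 4.7 * t + phase)
            + 0.3 * np.sin(2 * np.pi * 0.6 * t + 2.0 * phase)
        )
        out.data[i] = garbage.astype(session.data.dtype)
    out.meta.setdefault("corrupted", []).extend(label for label, _ in bad)
    return out


def separability_demo_config(**overrides) -> SimConfig:
    """Config whose band-separability table mirrors the qualitative pattern
    of the study: task A broadband-offset from everything, B and C nearly
    identical (differing only in the high-gamma gain), D the no-gain
    reference.  Used by the pattern-recovery tests."""
    op = "occipito_parietal"
    bands = list(BAND_EDGES)
    gain: dict[str, dict[tuple[str, str], float]] = {
        "A": {(b, "all"): 4.0 for b in bands},
        "B": {(b, op): 1.7 for b in bands},
        "C": {(b, op): 1.7 for b in bands},
        "D": {(b, op): 1.0 for b in bands},
    }
    gain["B"][("gamma_low", op)] = 2.3
    gain["B"][("gamma_high", op)] = 3.2
    gain["C"][("gamma_low", op)] = 2.3
    gain["C"][("gamma_high", op)] = 2.4
    overrides.setdefault("class_base_amp", 4.0)
    return SimConfig(class_gain=gain, **overrides)
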