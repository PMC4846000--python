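"""Minimal EDF (European Data Format) import for real recordings.

Only what the pipeline needs: fixed-rate signals, physical scaling to
microvolts, and label matching against the 32-channel montage.  Annotations
channels and discontinuous files are not supported.  A small writer is
provided for interoperability tests; it is not part of the public pipeline.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .montage import ELECTRODES, standard_montage
from .session import EEGSession, Segment

_HDR = 256  # fixed part of the header, bytes


def _field(raw: bytes, start: int, length: int) -> str:
    return raw[start : start + length].decode("ascii").strip()


def _unit_to_uv(dim: str) -> float:
    dim = dim.replace("µ", "u").strip().lower()
    if dim in ("uv", ""):
        return 1.0
    if dim == "mv":
        return 1e3
    if dim == "v":
        return 1e6
    raise ValueError(f"unsupported physical dimension {dim!r}")


def _norm_label(label: str) -> str:
    label = label.strip()
    if label.upper().startswith("EEG "):
        label = label[4:]
    return label.strip().upper()


def read_edf(path: str | Path) -> EEGSession:
    """Read an EDF file into an :class:`EEGSession` (data in microvolts).

    The file must carry exactly the 32 montage channels (labels matched
    case-insensitively, an ``EEG `` prefix is ignored) at a single sampling
    rate.  The recording is annotated as one break segment; real task
    annotations, if any, must be attached afterwards.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HDR:
        raise ValueError("truncated EDF header")
    n_records = int(_field(raw, 236, 8))
    record_dur = float(_field(raw, 244, 8))
    ns = int(_field(raw, 252, 4))
    if ns != len(ELECTRODES):
        raise ValueError(f"expected {len(ELECTRODES)} channels, file has {ns}")
    hdr = raw[_HDR : _HDR + ns * 256]

    def per_sig(offset: int, width: int) -> list[str]:
        base = offset * ns
        return [
            _field(hdr, base + i * width, width) for i in range(ns)
        ]

    labels = [_norm_label(x) for x in per_sig(0, 16)]
    unknown = [x for x in labels if x not in ELECTRODES]
    if unknown:
        raise ValueError(f"unknown channel labels {unknown}")
    if len(set(labels)) != ns:
        raise ValueError("duplicate channel labels")
    # layout after labels: transducer(80), dim(8), phys_min(8), phys_max(8),
    # dig_min(8), dig_max(8), prefilter(80), samples_per_record(8), reserved(32)
    def block(start: int, width: int) -> list[str]:
        return [_field(hdr, start + i * width, width) for i in range(ns)]

    off_dim = ns * 16 + ns * 80
    dims = block(off_dim, 8)
    off_pmin = off_dim + ns * 8
    phys_min = np.array([float(x) for x in block(off_pmin, 8)])
    phys_max = np.array([float(x) for x in block(off_pmin + ns * 8, 8)])
    dig_min = np.array([float(x) for x in block(off_pmin + 2 * ns * 8, 8)])
    dig_max = np.array([float(x) for x in block(off_pmin + 3 * ns * 8, 8)])
    spr = [int(x) for x in block(off_pmin + 4 * ns * 8 + ns * 80, 8)]
    if len(set(spr)) != 1:
        raise ValueError("per-channel sampling rates differ")
    n_per = spr[0]
    fs = n_per / record_dur

    body = np.frombuffer(raw[_HDR + ns * 256 :], dtype="<i2")
    expected = n_records * ns * n_per
    if body.size < expected:
        raise ValueError("truncated EDF data section")
    body = body[:expected].reshape(n_records, ns, n_per).astype(np.float64)

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_min - gain * dig_min
    scaled = body * gain[None, :, None] + offset[None, :, None]
    units = np.array([_unit_to_uv(d) for d in dims])
    scaled *= units[None, :, None]

    montage = standard_montage()
    order = [labels.index(e) for e in montage.names]
    data = (
        scaled[:, order, :].transpose(1, 0, 2).reshape(ns, -1)
    ).astype(np.float32)
    n_samples = data.shape[1]
    session = EEGSession(
        data=data,
        fs=fs,
        montage=montage,
        segments=(Segment("break", 0, 0, n_samples),),
        meta={"source": str(path), "format": "edf"},
    )
    session.validate()
    return session


def write_edf(
    session: EEGSession, path: str | Path, record_duration_s: float = 1.0
) -> Path:
    """Write a bare-bones EDF file (testing / interop only).

    Samples are quantized to 16 bits over the session's amplitude range;
    the round trip is therefore approximate, unlike the internal format.
    """
    fs = session.fs
    n_per = int(round(fs * record_duration_s))
    ns = session.n_channels
    n_records = session.n_samples // n_per
    data = session.data[:, : n_records * n_per].astype(np.float64)
    pmin, pmax = float(data.min()) - 1.0, float(data.max()) + 1.0
    dmin, dmax = -32768, 32767
    gain = (pmax - pmin) / (dmax - dmin)
    digital = np.clip(np.round((data - pmin) / gain) + dmin, dmin, dmax)
    digital = digital.astype("<i2")

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")
        if len(b) > width:
            raise ValueError(f"field too long: {s!r}")
        return b.ljust(width)

    hdr = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("synthetic", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(_HDR + ns * 256), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad(f"{record_duration_s:g}", 8),
            pad(str(ns), 4),
        ]
    )
    sig = b"".join(pad(e, 16) for e in session.montage.names)
    sig += b"".join(pad("AgAgCl electrode", 80) for _ in range(ns))
    sig += b"".join(pad("uV", 8) for _ in range(ns))
    sig += b"".join(pad(f"{pmin:.2f}"[:8], 8) for _ in range(ns))
    sig += b"".join(pad(f"{pmax:.2f}"[:8], 8) for _ in range(ns))
    sig += b"".join(pad(str(dmin), 8) for _ in range(ns))
    sig += b"".join(pad(str(dmax), 8) for _ in range(ns))
    sig += b"".join(pad("BP 0.5-100Hz", 80) for _ in range(ns))
    sig += b"".join(pad(str(n_per), 8) for _ in range(ns))
    sig += b"".join(pad("", 32) for _ in range(ns))

    records = digital.reshape(ns, n_records, n_per).transpose(1, 0, 2)
    out = Path(path)
    out.write_bytes(hdr + sig + records.tobytes())
    return out
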