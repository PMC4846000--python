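"""Session data model and on-disk readers/writers.

An :class:`EEGSession` is a channels x samples array in microvolts plus a
sampling rate, the montage, and an ordered list of segments (task or break)
that tile the recording.  The internal on-disk format is a little-endian
float32 ``.npy`` array next to a JSON sidecar holding everything else;
both files are written deterministically so identical sessions produce
byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .montage import ELECTRODES, Montage, standard_montage

TASK_CODES = ("A", "B", "C", "D")

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TaskLabel:
    """One of the four attention tasks performed while walking."""

    code: str
    description: str
    attention_level: str


#: code -> label; A is the reference walking condition, B/C are distractor
#: tasks (low gait attention), D demands high gait attention.
TASK_LABELS: dict[str, TaskLabel] = {
    "A": TaskLabel("A", "normal walking", "standard"),
    "B": TaskLabel("B", "mathematical operations", "low"),
    "C": TaskLabel("C", "video", "low"),
    "D": TaskLabel("D", "following marks", "high"),
}


@dataclass(frozen=True)
class Segment:
    """Half-open sample interval [start, end) tagged with its kind and run."""

    kind: str  # "A" | "B" | "C" | "D" | "break"
    run: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in TASK_CODES and self.kind != "break":
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class EEGSession:
    """A full recording session: data in microvolts plus annotations."""

    data: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float
    montage: Montage
    segments: tuple[Segment, ...]
    subject_group: str = "healthy"  # "healthy" | "patient"
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def task_segments(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.kind != "break")

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.montage.index(label)]

    def validate(self) -> None:
        """Enforce the structural invariants; raise ValueError on violation."""
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"data has {self.data.shape[0]} rows for a "
                f"{len(self.montage)}-channel montage"
            )
        if self.subject_group not in ("healthy", "patient"):
            raise ValueError(f"unknown subject group {self.subject_group!r}")
        if not self.segments:
            raise ValueError("session has no segments")
        cursor = 0
        for seg in self.segments:
            if seg.start != cursor:
                raise ValueError(
                    f"segments must be ordered and tile the recording; "
                    f"expected start {cursor}, got {seg.start}"
                )
            cursor = seg.end
        if cursor != self.n_samples:
            raise ValueError(
                f"segments cover {cursor} samples but the recording has "
                f"{self.n_samples}"
            )
        by_run: dict[int, list[str]] = {}
        for seg in self.segments:
            if seg.kind != "break":
                by_run.setdefault(seg.run, []).append(seg.kind)
        for run, kinds in sorted(by_run.items()):
            if kinds != list(TASK_CODES):
                raise ValueError(
                    f"run {run} has task order {kinds}, expected "
                    f"{list(TASK_CODES)}"
                )

    def copy(self, data: np.ndarray | None = None, **changes) -> "EEGSession":
        new = replace(self, **changes)
        new.data = self.data.copy() if data is None else data
        new.meta = dict(new.meta)
        return new


def _paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix == ".json":
        p = p.with_suffix("")
    return p.with_suffix(".json"), p.with_suffix(".npy")


def write_session(session: EEGSession, path: str | Path) -> Path:
    """Write the internal format (JSON sidecar + float32 .npy array).

    The session is validated first; a session violating its invariants is
    refused.  Returns the sidecar path.
    """
    session.validate()
    sidecar, arr_path = _paths(path)
    sidecar.parent.mkdir(parents=True, exist_ok=True)
    np.save(arr_path, np.ascontiguousarray(session.data, dtype="<f4"))
    doc = {
        "format_version": _FORMAT_VERSION,
        "fs": session.fs,
        "channels": list(session.montage.names),
        "units": "uV",
        "subject_group": session.subject_group,
        "segments": [
            {"kind": s.kind, "run": s.run, "start": s.start, "end": s.end}
            for s in session.segments
        ],
        "meta": session.meta,
        "array_file": arr_path.name,
    }
    sidecar.write_text(json.dumps(doc, indent=2, sort_keys=True))
    return sidecar


def read_session(path: str | Path, format: str = "internal") -> EEGSession:
    """Read a session from disk (``internal`` or ``edf``)."""
    if format == "edf":
        from .edf import read_edf

        return read_edf(path)
    if format != "internal":
        raise ValueError(f"unknown format {format!r}")
    sidecar, arr_path = _paths(path)
    doc = json.loads(sidecar.read_text())
    channels = doc["channels"]
    montage = standard_montage()
    if list(channels) != list(ELECTRODES):
        unknown = [c for c in channels if c not in ELECTRODES]
        if unknown:
            raise ValueError(f"unknown channel labels {unknown}")
        raise ValueError("channel order does not match the montage")
    data = np.load(sidecar.parent / doc["array_file"]).astype(np.float32)
    if data.shape[0] != len(channels):
        raise ValueError(
            f"array has {data.shape[0]} channels, sidecar declares "
            f"{len(channels)}"
        )
    session = EEGSession(
        data=data,
        fs=float(doc["fs"]),
        montage=montage,
        segments=tuple(
            Segment(s["kind"], s["run"], s["start"], s["end"])
            for s in doc["segments"]
        ),
        subject_group=doc.get("subject_group", "healthy"),
        meta=dict(doc.get("meta", {})),
    )
    session.validate()
    return session


def session_layout(
    fs: float,
    n_runs: int = 8,
    task_duration_s: float = 60.0,
    break_duration_s: float = 60.0,
) -> tuple[Segment, ...]:
    """Segment layout of one session: per run the four tasks A-D back to
    back, with a break between consecutive runs (none after the last)."""
    task_n = int(round(task_duration_s * fs))
    break_n = int(round(break_duration_s * fs))
    segments: list[Segment] = []
    cursor = 0
    for run in range(1, n_runs + 1):
        for code in TASK_CODES:
            segments.append(Segment(code, run, cursor, cursor + task_n))
            cursor += task_n
        if run < n_runs:
            segments.append(Segment("break", run, cursor, cursor + break_n))
            cursor += break_n
    return tuple(segments)


def concat_segments(segments: Iterable[Segment]) -> tuple[Segment, ...]:
    """Re-index a sequence of segments so they tile a new recording."""
    out: list[Segment] = []
    cursor = 0
    for seg in segments:
        out.append(Segment(seg.kind, seg.run, cursor, cursor + seg.n_samples))
        cursor += seg.n_samples
    return tuple(out)
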