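"""32-electrode scalp montage (10/10 subset) with 2-D positions and adjacency.

Positions are unitless, expressed as a fraction of the head radius on a flat
projection (x: left negative / right positive, y: anterior positive).
Adjacency is derived from the positions: an electrode is linked to every
electrode lying within ``NEIGHBOR_FACTOR`` times its nearest-neighbor
distance, and the relation is then symmetrized by union.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: Electrode labels in acquisition order.
ELECTRODES: tuple[str, ...] = (
    "FZ",
    "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "CZ", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6",
    "P5", "P3", "PZ", "P4", "P6",
    "PO7", "PO3", "POZ", "PO4", "PO8",
)

# Flat-projection grid coordinates (arbitrary units, scaled below).  The
# lateral electrodes of a row sit at unit spacing; FZ and the parieto-occipital
# row are placed off-grid so that every border electrode keeps >= 2 neighbors
# under the distance rule.
_GRID: dict[str, tuple[float, float]] = {
    "FZ": (0.0, 5.25),
    "FC5": (-3.0, 4.0), "FC3": (-2.0, 4.0), "FC1": (-1.0, 4.0),
    "FCZ": (0.0, 4.0),
    "FC2": (1.0, 4.0), "FC4": (2.0, 4.0), "FC6": (3.0, 4.0),
    "C5": (-3.0, 3.0), "C3": (-2.0, 3.0), "C1": (-1.0, 3.0),
    "CZ": (0.0, 3.0),
    "C2": (1.0, 3.0), "C4": (2.0, 3.0), "C6": (3.0, 3.0),
    "CP5": (-3.0, 2.0), "CP3": (-2.0, 2.0), "CP1": (-1.0, 2.0),
    "CPZ": (0.0, 2.0),
    "CP2": (1.0, 2.0), "CP4": (2.0, 2.0), "CP6": (3.0, 2.0),
    "P5": (-3.0, 1.0), "P3": (-2.0, 1.0), "PZ": (0.0, 1.0),
    "P4": (2.0, 1.0), "P6": (3.0, 1.0),
    "PO7": (-2.6, 0.0), "PO3": (-1.1, 0.0), "POZ": (0.0, 0.0),
    "PO4": (1.1, 0.0), "PO8": (2.6, 0.0),
}

_SCALE = 1.0 / 6.0  # grid units -> head-radius fraction

#: Multiplier on each electrode's nearest-neighbor distance that defines
#: which electrodes count as "surrounding" it.
NEIGHBOR_FACTOR = 1.3

#: Named electrode regions used by the synthetic generator.
REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("FZ", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6"),
    "motor": ("C5", "C3", "C1", "CZ", "C2", "C4", "C6"),
    "motor_left": ("C5", "C3", "C1"),
    "motor_right": ("C2", "C4", "C6"),
    "parietal": ("CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6",
                 "P5", "P3", "PZ", "P4", "P6"),
    "occipital": ("PO7", "PO3", "POZ", "PO4", "PO8"),
    "occipito_parietal": ("P5", "P3", "PZ", "P4", "P6",
                          "PO7", "PO3", "POZ", "PO4", "PO8"),
    "all": ELECTRODES,
}


@dataclass(frozen=True)
class Montage:
    """Electrode labels, flat 2-D positions and the derived neighbor relation."""

    names: tuple[str, ...]
    positions: dict[str, tuple[float, float]]
    neighbors: dict[str, frozenset[str]] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("electrode labels must be unique")
        for e, nbrs in self.neighbors.items():
            if e in nbrs:
                raise ValueError(f"{e} listed as its own neighbor")
            for other in nbrs:
                if e not in self.neighbors[other]:
                    raise ValueError(f"asymmetric neighbor pair {e}/{other}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        return self.names.index(label)

    def position_array(self) -> np.ndarray:
        """(n, 2) array of positions in label order."""
        return np.array([self.positions[e] for e in self.names])

    def to_json(self) -> str:
        return json.dumps(
            {
                "names": list(self.names),
                "positions": {e: list(p) for e, p in self.positions.items()},
                "neighbors": {e: sorted(n) for e, n in self.neighbors.items()},
            },
            indent=2,
            sort_keys=True,
        )


def neighbors_from_positions(
    names: tuple[str, ...],
    positions: dict[str, tuple[float, float]],
    factor: float = NEIGHBOR_FACTOR,
) -> dict[str, frozenset[str]]:
    """Distance-rule adjacency: for each electrode take everything within
    ``factor`` x its nearest-neighbor distance, then symmetrize by union."""
    pos = np.array([positions[e] for e in names])
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    directed: dict[str, set[str]] = {}
    for i, e in enumerate(names):
        cutoff = factor * d[i].min()
        directed[e] = {names[j] for j in np.flatnonzero(d[i] <= cutoff)}
    out: dict[str, set[str]] = {e: set(v) for e, v in directed.items()}
    for e, nbrs in directed.items():
        for other in nbrs:
            out[other].add(e)
    return {e: frozenset(v) for e, v in out.items()}


def standard_montage() -> Montage:
    """The 32-electrode 10/10 montage used throughout the pipeline."""
    positions = {e: (x * _SCALE, y * _SCALE) for e, (x, y) in _GRID.items()}
    neighbors = neighbors_from_positions(ELECTRODES, positions)
    m = Montage(names=ELECTRODES, positions=positions, neighbors=neighbors)
    for e in m.names:
        assert len(m.neighbors[e]) >= 2, e
    return m


def region_indices(montage: Montage, region: str | tuple[str, ...]) -> np.ndarray:
    """Channel indices for a named region or an explicit label tuple."""
    labels = REGIONS[region] if isinstance(region, str) else region
    return np.array([montage.index(e) for e in labels])
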