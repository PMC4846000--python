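"""Band separability: pairwise Bhattacharyya distances and band selection.

The distance between two feature sets is the Gaussian Bhattacharyya
distance

    D = 1/8 (m1-m2)' S^-1 (m1-m2) + 1/2 ln( det S / sqrt(det S1 det S2) ),
    S = (S1+S2)/2,

computed on sample moments.  32-dimensional covariances estimated from
a few hundred epochs can be ill-conditioned, so each class covariance is
shrunk toward its diagonal before use; ``shrinkage=0`` recovers the raw
sample covariances and ``diagonal=True`` keeps only the variances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .features import BAND_NAMES, BandFeatures
from .session import TASK_CODES

#: the six unordered task pairs, in table order
TASK_PAIRS: tuple[str, ...] = tuple(
    a + b for a, b in combinations(TASK_CODES, 2)
)

DEFAULT_SHRINKAGE = 0.1
DEFAULT_THRESHOLD = 3.5


@dataclass
class BdistTable:
    """Bands x task-pairs separability table."""

    values: pd.DataFrame  # index: bands, columns: pairs

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("Bhattacharyya distances must be >= 0")

    def to_csv(self, path) -> None:
        self.values.to_csv(path, float_format="%.4f")


def _shrunk_cov(x: np.ndarray, shrinkage: float,
                diagonal: bool) -> np.ndarray:
    cov = np.cov(x, rowvar=False)
    cov = np.atleast_2d(cov)
    if diagonal:
        return np.diag(np.diag(cov))
    if shrinkage > 0:
        cov = (1 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
    return cov


def bhattacharyya(
    features1: np.ndarray,
    features2: np.ndarray,
    shrinkage: float = DEFAULT_SHRINKAGE,
    diagonal: bool = False,
) -> float:
    """Gaussian Bhattacharyya distance between two epoch x feature sets."""
    x1 = np.atleast_2d(np.asarray(features1, dtype=np.float64))
    x2 = np.atleast_2d(np.asarray(features2, dtype=np.float64))
    if x1.shape[0] < 2 or x2.shape[0] < 2:
        raise ValueError("need at least 2 epochs per class")
    if x1.shape[1] != x2.shape[1]:
        raise ValueError("feature dimensionality mismatch")
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    s1 = _shrunk_cov(x1, shrinkage, diagonal)
    s2 = _shrunk_cov(x2, shrinkage, diagonal)
    s = 0.5 * (s1 + s2)
    sign, logdet_s = np.linalg.slogdet(s)
    sign1, logdet1 = np.linalg.slogdet(s1)
    sign2, logdet2 = np.linalg.slogdet(s2)
    if sign <= 0 or sign1 <= 0 or sign2 <= 0:
        raise np.linalg.LinAlgError(
            "singular covariance after regularization"
        )
    diff = m1 - m2
    maha = diff @ np.linalg.solve(s, diff)
    d = 0.125 * maha + 0.5 * (logdet_s - 0.5 * (logdet1 + logdet2))
    return float(max(d, 0.0))


def bdist_table(
    features: dict[str, BandFeatures],
    shrinkage: float = DEFAULT_SHRINKAGE,
    diagonal: bool = False,
) -> BdistTable:
    """6 bands x 6 task pairs distance table (deterministic)."""
    rows = {}
    for band in BAND_NAMES:
        bf = features[band]
        present = set(np.unique(bf.labels))
        missing = set(TASK_CODES) - present
        if missing:
            raise ValueError(f"band {band}: missing tasks {sorted(missing)}")
        by_task = {c: bf.values[bf.labels == c] for c in TASK_CODES}
        rows[band] = {
            pair: bhattacharyya(by_task[pair[0]], by_task[pair[1]],
                                shrinkage=shrinkage, diagonal=diagonal)
            for pair in TASK_PAIRS
        }
    df = pd.DataFrame.from_dict(rows, orient="index").loc[
        list(BAND_NAMES), list(TASK_PAIRS)
    ]
    return BdistTable(values=df)


def select_bands(
    table: BdistTable,
    threshold: float = DEFAULT_THRESHOLD,
    pairs_of_interest: tuple[str, ...] | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Bands whose distance meets the inclusive >= threshold criterion on
    every designated pair; also returns the per-pair pass/fail table."""
    pairs = tuple(pairs_of_interest) if pairs_of_interest else TASK_PAIRS
    unknown = set(pairs) - set(TASK_PAIRS)
    if unknown:
        raise ValueError(f"unknown task pairs {sorted(unknown)}")
    passes = table.values.loc[:, list(pairs)] >= threshold
    selected = set(passes.index[passes.all(axis=1)])
    return selected, passes
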