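"""Finite-sample chance levels and significance testing of decoders.

A random classifier on n test epochs does not score exactly 100/k %: the
adjusted-Wald interval around the ideal rate gives the band of success
rates compatible with guessing,

    p~ = (n xbar + 2) / (n + 4),
    range = p~ +/- z_{1-alpha/2} sqrt( p~ (1-p~) / (n+4) ).

Observed fold-wise success rates are compared against values drawn
uniformly from that band with two-sided Wilcoxon rank-sum tests,
Bonferroni-corrected across the family of comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ChanceLevelParams:
    n: int  # number of test epochs
    xbar: float  # ideal random-classifier accuracy, in [0, 1]
    alpha: float  # confidence parameter
    z: float  # 1 - alpha/2 standard-normal quantile
    p_tilde: float  # adjusted estimator

    def __post_init__(self) -> None:
        if not 0 < self.xbar < 1:
            raise ValueError("xbar must lie in (0, 1)")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.n < 0:
            raise ValueError("n must be >= 0")


@dataclass(frozen=True)
class ChanceLevelRange:
    """Chance-level confidence bounds, in percent."""

    lower: float
    upper: float
    params: ChanceLevelParams

    def contains(self, rate_percent: float) -> bool:
        return self.lower <= rate_percent <= self.upper

    @property
    def midpoint(self) -> float:
        return 100.0 * self.params.p_tilde


def ideal_chance(n_classes: int) -> float:
    """Accuracy (%) of a random classifier on balanced classes."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    return 100.0 / n_classes


def p_tilde(n: int, xbar: float) -> float:
    """Adjusted (add-two-successes-and-two-failures) rate estimator."""
    return (n * xbar + 2.0) / (n + 4.0)


def chance_range(
    n: int, xbar: float = 0.25, alpha: float = DEFAULT_ALPHA
) -> ChanceLevelRange:
    """Adjusted-Wald confidence band around the chance level, in %."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < xbar < 1:
        raise ValueError("xbar must lie in (0, 1)")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    pt = p_tilde(n, xbar)
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    half = z * np.sqrt(pt * (1.0 - pt) / (n + 4.0))
    params = ChanceLevelParams(n=n, xbar=xbar, alpha=alpha, z=z, p_tilde=pt)
    # at very small n the Wald arm can cross 0/1; clip to valid rates
    return ChanceLevelRange(
        lower=float(np.clip(100.0 * (pt - half), 0.0, 100.0)),
        upper=float(np.clip(100.0 * (pt + half), 0.0, 100.0)),
        params=params,
    )


def chance_vector(
    rng: np.random.Generator, size: int, range_: ChanceLevelRange
) -> np.ndarray:
    """Random success-rate values (%) drawn uniformly from the chance band,
    the reference sample the observed fold rates are tested against."""
    return rng.uniform(range_.lower, range_.upper, size)


def _ranksum_p(sample1: np.ndarray, sample2: np.ndarray) -> float:
    if len(sample1) == 0 or len(sample2) == 0:
        raise ValueError("empty sample")
    return float(stats.ranksums(sample1, sample2).pvalue)


def compare_to_chance(
    fold_rates: dict[str, np.ndarray],
    range_: ChanceLevelRange,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-classifier rank-sum test of pooled fold rates against a
    matched-length chance vector; Bonferroni across the classifiers.

    ``fold_rates`` maps classifier name -> pooled fold success rates (%).
    """
    rng = np.random.default_rng(seed)
    family = len(fold_rates)
    rows = []
    for name, rates in fold_rates.items():
        rates = np.asarray(rates, dtype=float)
        reference = chance_vector(rng, rates.size, range_)
        p = _ranksum_p(rates, reference)
        p_adj = min(1.0, p * family)
        rows.append(
            {
                "classifier": name,
                "n_folds": rates.size,
                "mean_rate": rates.mean() if rates.size else np.nan,
                "p": p,
                "p_bonferroni": p_adj,
                "significant": p_adj < alpha,
                "above_chance": rates.mean() > range_.upper,
            }
        )
    return pd.DataFrame(rows).set_index("classifier")


def pairwise_comparisons(
    groups: dict[str, np.ndarray], alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Rank-sum p-values for every unordered pair of groups, Bonferroni
    corrected within the table; symmetric in pair order."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for name, values in groups.items():
        if len(np.asarray(values)) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    pairs = list(combinations(names, 2))
    family = len(pairs)
    rows = []
    for a, b in pairs:
        p = _ranksum_p(np.asarray(groups[a], float),
                       np.asarray(groups[b], float))
        p_adj = min(1.0, p * family)
        rows.append(
            {
                "group1": a,
                "group2": b,
                "p": p,
                "p_bonferroni": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)
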