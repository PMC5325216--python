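"""Statistical utilities for evaluating discrimination networks.

Covers three checks used when validating the semantic space and comparing
regression models fitted on network-derived predictors: category cohesion
(are within-category cosine similarities higher than similarities to words
outside the category?), the exact one-sided sign test, and AIC evidence
ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CategoryCohesionResult",
    "category_cohesion",
    "sign_test",
    "evidence_ratio",
]


@dataclass(frozen=True)
class CategoryCohesionResult:
    """Cohesion of one semantic category in a similarity matrix."""

    category: str
    within_mean: float
    outside_mean: float
    difference: float  # within - outside
    p_value: float
    size: int


def category_cohesion(
    S: pd.DataFrame, members: Iterable[str], category: str = ""
) -> CategoryCohesionResult:
    """Compare within-category and member-to-outside cosine similarities.

    ``within`` averages over unordered member pairs, ``outside`` over all
    (member, non-member) pairs; the p-value comes from a two-sample
    unequal-variance t-test over the two sets of pairwise similarities.
    Pairs sharing a word are treated as independent observations (no
    correction is attempted).  Members absent from ``S`` are dropped with
    a warning.
    """
    members = list(dict.fromkeys(members))
    known = [m for m in members if m in S.index]
    missing = sorted(set(members) - set(known))
    if missing:
        warnings.warn(f"dropping members absent from the similarity matrix: {missing}")
    if len(known) < 2:
        raise ValueError("category needs at least two members present in the matrix")
    outsiders = [w for w in S.index if w not in set(known)]
    if not outsiders:
        raise ValueError("category covers every lexome; no outside group exists")
    within = np.array([S.at[a, b] for a, b in combinations(known, 2)], dtype=float)
    outside = np.array(
        [S.at[m, o] for m in known for o in outsiders], dtype=float
    )
    if np.ptp(within) == 0 and np.ptp(outside) == 0:
        p = 1.0 if within.mean() == outside.mean() else 0.0
    else:
        p = float(stats.ttest_ind(within, outside, equal_var=False).pvalue)
    w_mean, o_mean = float(within.mean()), float(outside.mean())
    return CategoryCohesionResult(
        category=category,
        within_mean=w_mean,
        outside_mean=o_mean,
        difference=w_mean - o_mean,
        p_value=p,
        size=len(known),
    )


def sign_test(hits: int, n: int) -> float:
    """Exact one-sided upper-tail binomial p-value under chance (p = 0.5).

    P(X >= hits) for X ~ Binomial(n, 0.5), summed exactly.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= hits <= n:
        raise ValueError(f"hits must lie in [0, {n}], got {hits}")
    return float(stats.binomtest(hits, n, 0.5, alternative="greater").pvalue)


def evidence_ratio(aic_a: float, aic_b: float) -> float:
    """exp(|ΔAIC| / 2): how much more likely the lower-AIC model is to be
    the better approximation of the data.  Symmetric in its arguments;
    saturates to inf when the gap exceeds floating-point range."""
    try:
        return math.exp(abs(aic_b - aic_a) / 2.0)
    except OverflowError:
        return math.inf
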