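"""Pairwise set-overlap statistics for junction and event sets.

Two samples' unannotated-junction sets (or altered-event sets) are compared
by their shared proportion and by an exact upper-tail hypergeometric test:
with a universe of N eligible keys, drawing |A| and |B| of them, the
p-value is P(X >= k) for the observed intersection size k. The tail is
summed in log space so it stays exact-to-double for universes up to ~1e6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom


@dataclass
class JunctionSet:
    sample_id: str
    members: frozenset
    universe: frozenset

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        self.universe = frozenset(self.universe)
        if not self.members <= self.universe:
            raise ValueError(f"{self.sample_id}: members not a subset of the universe")


@dataclass
class OverlapResult:
    sample_a: str
    sample_b: str
    shared_count: int
    size_a: int
    size_b: int
    universe_size: int
    shared_proportion: float
    p_value: float

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p_value)) if self.p_value > 0 else np.inf


def shared_proportion(a: JunctionSet, b: JunctionSet, denominator: str = "union") -> float:
    """|A ∩ B| over |A ∪ B| (default) or over |A| + |B| (``'sum'``).

    The union convention keeps the statistic in [0, 1] with value 1 for
    identical sets; symmetric in its arguments under both conventions.
    """
    if not a.members and not b.members:
        raise ValueError("shared proportion undefined for two empty sets")
    k = len(a.members & b.members)
    if denominator == "union":
        return k / len(a.members | b.members)
    if denominator == "sum":
        return k / (len(a.members) + len(b.members))
    raise ValueError(f"unknown denominator convention {denominator!r}")


def hypergeom_sf_exact(k: int, N: int, K: int, n: int) -> float:
    """Exact upper tail P(X >= k), X ~ Hypergeometric(N, K, n).

    Computed as a log-space sum of pmf terms over the support, which keeps
    far-tail values accurate where a complemented CDF would cancel.
    """
    if K > N or n > N:
        raise ValueError("set sizes exceed the universe")
    lo = max(0, K + n - N)
    if k <= lo:
        return 1.0
    hi = min(K, n)
    if k > hi:
        return 0.0
    support = np.arange(k, hi + 1)
    return float(np.exp(logsumexp(hypergeom.logpmf(support, N, K, n))))


def hypergeometric_overlap_test(
    a: JunctionSet, b: JunctionSet, denominator: str = "union"
) -> OverlapResult:
    """Shared proportion plus the exact hypergeometric enrichment p-value."""
    if a.universe != b.universe:
        raise ValueError("mismatched universes; overlap test undefined")
    N = len(a.universe)
    k = len(a.members & b.members)
    return OverlapResult(
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        shared_count=k,
        size_a=len(a.members),
        size_b=len(b.members),
        universe_size=N,
        shared_proportion=shared_proportion(a, b, denominator=denominator),
        p_value=hypergeom_sf_exact(k, N, len(a.members), len(b.members)),
    )


def pairwise_matrix(
    sets: list[JunctionSet], denominator: str = "union"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Symmetric (proportion, p-value, -log10 p) matrices over all pairs.

    The diagonal carries proportion 1 and the self-overlap p-value.
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 sets for a pairwise matrix")
    ids = [s.sample_id for s in sets]
    n = len(sets)
    prop = pd.DataFrame(np.ones((n, n)), index=ids, columns=ids)
    pval = pd.DataFrame(np.ones((n, n)), index=ids, columns=ids)
    for i in range(n):
        for j in range(i, n):
            res = hypergeometric_overlap_test(sets[i], sets[j], denominator=denominator)
            prop.iloc[i, j] = prop.iloc[j, i] = res.shared_proportion
            pval.iloc[i, j] = pval.iloc[j, i] = res.p_value
    with np.errstate(divide="ignore"):
        neglog = -np.log10(pval)
    return prop, pval, neglog


def pairwise_long_format(
    sets: list[JunctionSet], denominator: str = "union"
) -> pd.DataFrame:
    """Long-format overlap table: one row per unordered sample pair."""
    rows = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            r = hypergeometric_overlap_test(sets[i], sets[j], denominator=denominator)
            rows.append(
                {
                    "sample_i": r.sample_a,
                    "sample_j": r.sample_b,
                    "shared": r.shared_count,
                    "size_i": r.size_a,
                    "size_j": r.size_b,
                    "universe": r.universe_size,
                    "proportion": r.shared_proportion,
                    "p_value": r.p_value,
                    "neg_log10_p": r.neg_log10_p,
                }
            )
    return pd.DataFrame(rows)


def junction_set_from_keys(
    sample_id: str, keys: set, universe: set
) -> JunctionSet:
    return JunctionSet(sample_id=sample_id, members=frozenset(keys), universe=frozenset(universe))
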