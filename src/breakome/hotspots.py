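"""Recurrent break positions across replicas and their Monte-Carlo null.

A hotspot is a single-nucleotide position observed in at least ``k >= 2``
independent biological replicas of a cell type.  Whether the observed shared
fraction exceeds chance is assessed against 100 simulations that redraw the
same numbers of samples and breaks per sample uniformly from the detectable
position space, with a two-sided one-sample Student t-test of the simulated
fractions against the observed value.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import BreakPosition, BreakSet

__all__ = ["SupportMap", "HotspotSet", "NullDistribution", "build_support",
           "call_hotspots", "hotspot_fraction", "simulate_null",
           "hotspot_significance", "overlap_odds_ratio", "overlap_odds_ratio_counts",
           "percentage", "summarize_hotspot_gene_counts"]


@dataclass(frozen=True)
class SupportMap:
    """Position -> number of replicas containing it, plus per-replica totals T_i."""

    counts: Mapping[BreakPosition, int]
    n_replicas: int
    replica_totals: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class HotspotSet:
    positions: frozenset[BreakPosition]
    support: Mapping[BreakPosition, int]
    min_support: int
    n_replicas: int

    def __len__(self) -> int:
        return len(self.positions)

    def __iter__(self):
        return iter(self.positions)


@dataclass(frozen=True)
class NullDistribution:
    fractions: np.ndarray
    n_simulations: int
    space_size: int
    seed: int | None


def build_support(replicas: Sequence[BreakSet]) -> SupportMap:
    """Exact multiplicity count of every position over the union of replicas."""
    if not replicas:
        raise ValueError("need at least one replica")
    counts: Counter[BreakPosition] = Counter()
    for rep in replicas:
        counts.update(rep.positions)
    return SupportMap(counts=dict(counts), n_replicas=len(replicas),
                      replica_totals=tuple(len(r) for r in replicas))


def call_hotspots(support: SupportMap, k: int = 2) -> HotspotSet:
    if k < 2:
        raise ValueError("hotspots require support in at least 2 replicas (k >= 2)")
    if k > support.n_replicas:
        raise ValueError(f"k={k} exceeds the {support.n_replicas} available replicas")
    hot = {p: c for p, c in support.counts.items() if c >= k}
    return HotspotSet(positions=frozenset(hot), support=hot, min_support=k,
                      n_replicas=support.n_replicas)


def hotspot_fraction(support: SupportMap, k: int = 2) -> float:
    """|positions with support >= k| / |positions found in at least one replica|."""
    total = len(support.counts)
    if total == 0:
        raise ValueError("empty support map")
    shared = sum(1 for c in support.counts.values() if c >= k)
    return shared / total


def _uniform_wo_replacement(rng: np.random.Generator, space: int, k: int) -> np.ndarray:
    """k distinct uniform draws from range(space): oversample + first-occurrence dedup."""
    if k > space:
        raise ValueError("cannot draw more positions than the space holds")
    if k == space:
        return np.arange(space, dtype=np.int64)
    out = np.zeros(0, dtype=np.int64)
    while len(out) < k:
        extra = rng.integers(0, space, size=max(2 * (k - len(out)), 64), dtype=np.int64)
        out = pd.unique(np.concatenate([out, extra]))
    return out[:k]


def simulate_null(n_replicas: int, breaks_per_replica: Sequence[int] | int,
                  space_size: int, n_sim: int = 100, seed: int | None = None,
                  k: int = 2) -> NullDistribution:
    """Shared-fraction null: redraw each replica uniformly without replacement.

    Each simulation draws the observed per-replica break counts from a space
    of ``space_size`` equally likely positions and records the fraction of
    union positions with support >= k.
    """
    if space_size <= 0:
        raise ValueError("space_size must be positive")
    if isinstance(breaks_per_replica, int):
        breaks_per_replica = [breaks_per_replica] * n_replicas
    if len(breaks_per_replica) != n_replicas:
        raise ValueError("breaks_per_replica length must equal n_replicas")
    if any(b > space_size for b in breaks_per_replica):
        raise ValueError("a replica cannot hold more positions than the space")
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_sim)
    for s in range(n_sim):
        draws = [_uniform_wo_replacement(rng, space_size, b) for b in breaks_per_replica]
        _, counts = np.unique(np.concatenate(draws), return_counts=True)
        fractions[s] = (counts >= k).sum() / len(counts)
    return NullDistribution(fractions=fractions, n_simulations=n_sim,
                            space_size=space_size, seed=seed)


def hotspot_significance(observed_fraction: float, null: NullDistribution):
    """Two-sided one-sample t-test of the simulated fractions vs the observation.

    Returns ``(t, p, degenerate)``; a zero-variance null falls back to exact
    comparison (p = 1 if the observation equals the constant, else p = 0
    reported at the machine floor) with ``degenerate=True``.
    """
    x = np.asarray(null.fractions, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 simulations")
    if np.ptp(x) == 0.0:
        if x[0] == observed_fraction:
            return 0.0, 1.0, True
        return np.inf, np.nextafter(0.0, 1.0), True
    res = stats.ttest_1samp(x, popmean=observed_fraction)
    return float(res.statistic), float(res.pvalue), False


def overlap_odds_ratio_counts(n_a: int, n_b: int, observed: int, universe_size: int):
    """OR = observed / (n_a * n_b / U) plus a two-sided binomial p-value."""
    if universe_size <= 0:
        raise ValueError("universe_size must be positive")
    if max(n_a, n_b) > universe_size:
        raise ValueError("set sizes cannot exceed the universe")
    expected = n_a * n_b / universe_size
    odds = observed / expected if expected > 0 else float("nan")
    prob = min(n_b / universe_size, 1.0)
    p = stats.binomtest(observed, n=n_a, p=prob).pvalue if n_a else float("nan")
    return observed, odds, p


def overlap_odds_ratio(set_a, set_b, universe_size: int):
    """Observed overlap vs expectation |A||B|/U, with a two-sided binomial test.

    ``set_a``/``set_b`` may be HotspotSets or any sized collections of
    positions; the overlap is computed from their intersection.
    """
    a = set_a.positions if isinstance(set_a, HotspotSet) else frozenset(set_a)
    b = set_b.positions if isinstance(set_b, HotspotSet) else frozenset(set_b)
    return overlap_odds_ratio_counts(len(a), len(b), len(a & b), universe_size)


def percentage(numer: int, denom: int) -> float:
    """Percentage rounded half-up to one decimal, matching the reporting style."""
    return float(Decimal(100.0 * numer / denom).quantize(Decimal("0.1"), ROUND_HALF_UP))


def summarize_hotspot_gene_counts(per_gene_counts: Mapping[str, int]) -> pd.DataFrame:
    """Distribution of hotspot-per-gene counts in classes {1, 2, 3-5, >5}."""
    if any(c < 1 for c in per_gene_counts.values()):
        raise ValueError("listed genes must have at least one hotspot")
    classes = {"1": 0, "2": 0, "3-5": 0, ">5": 0}
    for c in per_gene_counts.values():
        if c == 1:
            classes["1"] += 1
        elif c == 2:
            classes["2"] += 1
        elif c <= 5:
            classes["3-5"] += 1
        else:
            classes[">5"] += 1
    total = len(per_gene_counts)
    rows = [{"hotspot_count": k, "n_genes": v,
             "percentage": percentage(v, total) if total else float("nan")}
            for k, v in classes.items()]
    return pd.DataFrame(rows)
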