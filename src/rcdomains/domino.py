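"""Adjacent-height ordering ("domino") statistics over RCD groups.

Under the domino model the activation of one replicon cluster raises the
chance that its chromosomal neighbour activates next, so the replication
peak heights of neighbouring RCDs — a proxy for how early each activated —
should be more similar, and more often in monotone order, than random.

Two analyses quantify this on groups of RCDs lying < 1.6 Mbp apart within
one timing domain:

* the height-rank permutation class of each 3- or 4-member group,
  canonicalised under reversal since direction along the chromosome is
  arbitrary; and
* the adjacent-value-similarity metric
  ``1 − (ADFA − ADFSV)/(MADFAP − ADFSV)`` where ADFA is the mean absolute
  adjacent difference of the height array, ADFSV the same for the sorted
  array (= (max−min)/(n−1)), and MADFAP the mean absolute difference over
  all distinct unordered pairs, which equals the expectation of ADFA over
  random orderings.  The metric is 1 exactly for monotone arrays, averages
  0 over all orderings, and is negative for interleaved ("anti-similar")
  arrangements.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .detection import RCD

__all__ = [
    "RCDGroup",
    "AdjacencyMetricResult",
    "MAX_GROUP_GAP_BP",
    "form_groups",
    "classify_permutation",
    "permutation_frequencies",
    "adjacent_value_similarity",
    "weighted_similarity_report",
    "one_sample_t",
    "canonical_classes",
]

MAX_GROUP_GAP_BP = 1.6e6


@dataclass
class RCDGroup:
    members: list[RCD]                   # ordered along the chromosome
    timing_domain_id: int | None = None

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def heights(self) -> np.ndarray:
        return np.array([m.replication_peak_height for m in self.members])


@dataclass
class AdjacencyMetricResult:
    adfa: float
    adfsv: float
    madfap: float
    value: float
    defined: bool


def form_groups(rcds: list[RCD], max_gap: float = MAX_GROUP_GAP_BP,
                distance: str = "centre") -> list[RCDGroup]:
    """Maximal runs of RCDs < ``max_gap`` apart within one timing domain.

    ``distance`` is centre-to-centre by default; ``"edge"`` measures
    between facing extent edges instead.  Singleton groups are returned
    but excluded from all downstream statistics by the callers.
    """
    by_key: dict[tuple[str, int | None], list[RCD]] = {}
    for r in rcds:
        by_key.setdefault((r.chrom, r.timing_domain_id), []).append(r)
    groups: list[RCDGroup] = []
    for (chrom, dom), members in sorted(by_key.items(), key=lambda kv: str(kv[0])):
        members.sort(key=lambda r: r.position)
        run: list[RCD] = [members[0]]
        for prev, cur in zip(members, members[1:]):
            if distance == "edge":
                gap = cur.extent[0] - prev.extent[1]
            else:
                gap = cur.position - prev.position
            if gap < max_gap:
                run.append(cur)
            else:
                groups.append(RCDGroup(members=run, timing_domain_id=dom))
                run = [cur]
        groups.append(RCDGroup(members=run, timing_domain_id=dom))
    return groups


def _rank_sequence(heights: np.ndarray) -> tuple[int, ...]:
    """Ranks along the chromosome, 1 = highest; ties broken by position."""
    heights = np.asarray(heights, dtype=float)
    if np.unique(heights).size < heights.size:
        warnings.warn("tied heights; breaking ties by genomic position",
                      stacklevel=3)
    order = np.argsort(-heights, kind="stable")
    ranks = np.empty(heights.size, dtype=int)
    ranks[order] = np.arange(1, heights.size + 1)
    return tuple(int(r) for r in ranks)


def _canonical(seq: tuple[int, ...]) -> str:
    rev = seq[::-1]
    return "-".join(map(str, min(seq, rev)))


def classify_permutation(group: RCDGroup | np.ndarray) -> str:
    """Canonical height-order class of a 3- or 4-member group.

    The highest peak gets rank 1; the rank sequence along the chromosome
    and its reversal are equivalent (chromosome direction is arbitrary)
    and the lexicographically smaller one names the class.
    """
    heights = group.heights if isinstance(group, RCDGroup) else np.asarray(group)
    n = len(heights)
    if n not in (3, 4):
        raise ValueError(f"permutation classifier handles n in {{3, 4}}, got {n}")
    return _canonical(_rank_sequence(heights))


def canonical_classes(n: int) -> list[str]:
    """All reversal-canonical rank classes for group size n (3 for n=3,
    12 for n=4)."""
    seen: dict[str, None] = {}
    for perm in itertools.permutations(range(1, n + 1)):
        seen.setdefault(_canonical(perm))
    return sorted(seen)


def permutation_frequencies(groups_by_timepoint: list[list[RCDGroup]],
                            n: int) -> pd.DataFrame:
    """Percentage of size-n groups in each canonical class per timepoint.

    Returns a table with one row per class, one column per timepoint, and
    ``mean``/``sd`` columns across timepoints.  Percentages sum to 100 per
    timepoint.
    """
    classes = canonical_classes(n)
    cols = {}
    for tp, groups in enumerate(groups_by_timepoint):
        eligible = [g for g in groups if g.n == n]
        counts = {c: 0 for c in classes}
        for g in eligible:
            counts[classify_permutation(g)] += 1
        total = max(1, len(eligible))
        cols[f"tp{tp + 1}"] = [counts[c] / total * 100.0 for c in classes]
    df = pd.DataFrame(cols, index=classes)
    df["mean"] = df.mean(axis=1)
    df["sd"] = df[[c for c in df.columns if c.startswith("tp")]].std(axis=1, ddof=1) \
        if len(groups_by_timepoint) > 1 else 0.0
    return df


def adjacent_value_similarity(heights) -> AdjacencyMetricResult:
    """The adjacent-value-similarity metric and its components.

    ``value = 1 − (ADFA − ADFSV)/(MADFAP − ADFSV)``; undefined
    (``defined=False``) when MADFAP equals ADFSV, which happens for n = 2
    and for degenerate height multisets.
    """
    h = np.asarray(heights, dtype=float)
    n = h.size
    if n < 2:
        raise ValueError("need at least 2 values")
    adfa = float(np.abs(np.diff(h)).mean())
    hs = np.sort(h)
    adfsv = float((hs[-1] - hs[0]) / (n - 1))
    pair_diffs = np.abs(h[:, None] - h[None, :])[np.triu_indices(n, k=1)]
    madfap = float(pair_diffs.mean())
    denom = madfap - adfsv
    if abs(denom) < 1e-12:
        return AdjacencyMetricResult(adfa, adfsv, madfap, float("nan"), defined=False)
    return AdjacencyMetricResult(adfa, adfsv, madfap,
                                 1.0 - (adfa - adfsv) / denom, defined=True)


@dataclass
class OneSampleT:
    mean: float
    se: float
    ci95: tuple[float, float]
    t: float
    df: int
    p: float
    degenerate: bool = False


def one_sample_t(values) -> OneSampleT:
    """Two-sided one-sample t-test against zero with a 95% CI."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(v.mean())
    if np.allclose(v, v[0]):
        return OneSampleT(mean, 0.0, (mean, mean), float("nan"), v.size - 1, 1.0,
                          degenerate=True)
    se = float(v.std(ddof=1) / np.sqrt(v.size))
    t, p = stats.ttest_1samp(v, 0.0)
    half = stats.t.ppf(0.975, v.size - 1) * se
    return OneSampleT(mean, se, (mean - half, mean + half), float(t),
                      int(v.size - 1), float(p))


def weighted_similarity_report(groups: list[RCDGroup], min_n: int = 4) -> dict:
    """Similarity metric over groups of n ≥ 4, with n−1 replication weighting.

    Each group's metric value is recorded n−1 times in the weighted sample
    (larger groups carry proportionally more of the evidence, one unit per
    adjacency); the unweighted once-per-group ("no-rep") sample is reported
    alongside.  Groups of three are excluded: with only three members the
    metric cannot separate random from anti-ordered arrangements.
    """
    values, weighted = [], []
    for g in groups:
        if g.n < min_n:
            continue
        res = adjacent_value_similarity(g.heights)
        if not res.defined:
            continue
        values.append(res.value)
        weighted.extend([res.value] * (g.n - 1))
    if len(values) < 2:
        raise ValueError("no eligible groups (need >= 2 groups of size >= %d)" % min_n)
    return {
        "n_groups": len(values),
        "values": np.asarray(values),
        "weighted_values": np.asarray(weighted),
        "weighted": one_sample_t(weighted),
        "no_rep": one_sample_t(values),
    }
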