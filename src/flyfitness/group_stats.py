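"""Treatment-comparison statistics.

Nonparametric machinery shared by the fecundity, lifespan and fitness
analyses: Kruskal-Wallis, Dunn's post hoc z tests with Benjamini-Hochberg
adjustment, Bonferroni, the two-sample log-rank test on lifespan records,
a Wilcoxon rank-sum special case for two-group contrasts, and compact
letter displays summarising which treatments differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from lifelines.statistics import logrank_test as _ll_logrank

from .vial_data import SurvivalRecord

__all__ = [
    "GroupedValues",
    "PairwiseResult",
    "LetterDisplay",
    "kruskal_wallis",
    "dunn_test",
    "rank_sum_test",
    "bh_adjust",
    "bonferroni_adjust",
    "logrank_test",
    "pairwise_logrank",
    "compact_letter_display",
]


@dataclass
class GroupedValues:
    values: list[float]
    group_labels: list[str]

    def __post_init__(self):
        if len(self.values) != len(self.group_labels):
            raise ValueError("values and group_labels must be parallel")

    def groups(self) -> dict[str, np.ndarray]:
        out: dict[str, list[float]] = {}
        for v, g in zip(self.values, self.group_labels):
            out.setdefault(g, []).append(v)
        return {g: np.asarray(vs, dtype=float) for g, vs in out.items()}

    def n_groups(self) -> int:
        return len(set(self.group_labels))


@dataclass
class PairwiseResult:
    """Pairwise statistics: (group_a, group_b, statistic, p_raw, p_adjusted)."""

    pairs: list[tuple[str, str, float, float, float]]
    method: str


@dataclass
class LetterDisplay:
    letters: dict[str, str]


def kruskal_wallis(data: GroupedValues) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected mid-ranks) and its chi-square p."""
    groups = data.groups()
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    arrays = [groups[g] for g in sorted(groups)]
    if sum(a.size for a in arrays) < 3:
        raise ValueError("Kruskal-Wallis needs total n >= 3")
    if len({float(v) for v in data.values}) == 1:
        # every observation identical: all mean ranks equal, H = 0
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def dunn_test(data: GroupedValues, adjust: str = "bh") -> PairwiseResult:
    """Dunn's multiple-comparison z tests on mean ranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)) with
    tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p,
    adjusted across all pairs (B-H by default, "bonferroni" or "none"
    otherwise).
    """
    groups = data.groups()
    if any(a.size == 0 for a in groups.values()):
        raise ValueError("empty group in Dunn test")
    labels = sorted(groups)
    all_vals = np.concatenate([groups[g] for g in labels])
    n = all_vals.size
    ranks = stats.rankdata(all_vals)
    mean_rank = {}
    pos = 0
    for g in labels:
        size = groups[g].size
        mean_rank[g] = ranks[pos : pos + size].mean()
        pos += size
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term

    pairs = []
    raw_ps = []
    for a, b in combinations(labels, 2):
        var = base_var * (1.0 / groups[a].size + 1.0 / groups[b].size)
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / np.sqrt(var)
            p = 2.0 * stats.norm.sf(abs(z))
        pairs.append((a, b, float(z)))
        raw_ps.append(min(1.0, float(p)))
    if adjust == "bh":
        adj = bh_adjust(raw_ps)
    elif adjust == "bonferroni":
        adj = bonferroni_adjust(raw_ps)
    elif adjust == "none":
        adj = list(raw_ps)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return PairwiseResult(
        pairs=[(a, b, z, p, q) for (a, b, z), p, q in zip(pairs, raw_ps, adj)],
        method=f"dunn-{adjust}",
    )


def rank_sum_test(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) for a two-group contrast."""
    res = stats.mannwhitneyu(np.asarray(x, float), np.asarray(y, float), alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def _check_probs(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p values must lie in [0, 1]")
    return p


def bh_adjust(p) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = _check_probs(p)
    if p.size == 0:
        return []
    return [float(q) for q in multipletests(p, method="fdr_bh")[1]]


def bonferroni_adjust(p, m: int | None = None) -> list[float]:
    """Bonferroni: min(1, p * m); m defaults to the number of tests."""
    p = _check_probs(p)
    m = p.size if m is None else int(m)
    return [float(min(1.0, q * m)) for q in p]


def _split_records(records: list[SurvivalRecord], label: str):
    times = np.array([r.time_days for r in records if r.treatment == label], dtype=float)
    events = np.array([r.event for r in records if r.treatment == label], dtype=int)
    return times, events


def logrank_test(
    records: list[SurvivalRecord], group_a: str, group_b: str
) -> tuple[float, float]:
    """Two-sample log-rank chi-square (df=1) and p between two treatments."""
    ta, ea = _split_records(records, group_a)
    tb, eb = _split_records(records, group_b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups need at least one record")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank undefined with no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def pairwise_logrank(records: list[SurvivalRecord], adjust: str = "bh") -> PairwiseResult:
    """All-pairs log-rank with multiplicity adjustment, for letter displays."""
    labels = sorted({r.treatment for r in records})
    pairs = []
    raw = []
    for a, b in combinations(labels, 2):
        chi2, p = logrank_test(records, a, b)
        pairs.append((a, b, chi2))
        raw.append(p)
    adj = bh_adjust(raw) if adjust == "bh" else bonferroni_adjust(raw)
    return PairwiseResult(
        pairs=[(a, b, c, p, q) for (a, b, c), p, q in zip(pairs, raw, adj)],
        method=f"logrank-{adjust}",
    )


def compact_letter_display(pairwise: PairwiseResult, alpha: float = 0.05) -> LetterDisplay:
    """Insert-absorb letter assignment.

    Two groups share at least one letter iff their adjusted p >= alpha.
    Groups and letters are ordered lexicographically for deterministic
    output.  Raises if the pairwise set does not cover every group pair.
    """
    groups = sorted({g for a, b, *_ in pairwise.pairs for g in (a, b)})
    sig = set()
    seen = set()
    for a, b, _stat, _p, q in pairwise.pairs:
        key = tuple(sorted((a, b)))
        seen.add(key)
        if q < alpha:
            sig.add(key)
    expected = {tuple(sorted(p)) for p in combinations(groups, 2)}
    if expected - seen:
        raise ValueError(f"pairwise results missing pairs: {sorted(expected - seen)}")

    # columns: sets of mutually compatible groups
    columns: list[set[str]] = [set(groups)]
    for a, b in sorted(sig):
        new_cols = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop empty columns, duplicates, and proper subsets
        columns = []
        for col in new_cols:
            if col and col not in columns and not any(col < other for other in new_cols):
                columns.append(col)
    columns = [c for c in columns if c]
    # order columns by earliest member for stable letters
    columns.sort(key=lambda c: [groups.index(g) for g in sorted(c, key=groups.index)])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in groups}
    for i, col in enumerate(columns):
        letter = alphabet[i] if i < len(alphabet) else f"({i})"
        for g in col:
            letters[g].append(letter)
    return LetterDisplay(letters={g: "".join(sorted(ls)) for g, ls in letters.items()})
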