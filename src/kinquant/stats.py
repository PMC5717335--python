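"""Group statistics on per-cell summaries.

Two-group comparisons are routed by a Shapiro-Wilk normality gate: Gaussian
groups get the unpaired pooled-variance Student's t-test, anything else the
two-sided Mann-Whitney rank-sum test.  Three or more groups are compared by
Kruskal-Wallis ANOVA on ranks followed by Dunn's pairwise z-tests on mean
ranks.  Significance tiers: * p<0.05, ** p<0.01, *** p<0.001.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA_TIERS = (0.05, 0.01, 0.001)


def stars(p: float) -> str:
    """Map a p-value to the figure-legend star convention (strict inequalities)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class PairwiseDecision:
    pair: tuple[str, str]
    statistic: float
    p_value: float
    significant_at: dict[float, bool] = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return stars(self.p_value)


@dataclass
class ComparisonResult:
    groups: tuple[str, ...]
    test_name: str
    statistic: float
    p_value: float
    pairwise: list[PairwiseDecision] = field(default_factory=list)
    normality_p: dict[str, float] = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return stars(self.p_value)


def _degenerate(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.ptp(pooled) == 0


def route_two_group_test(
    a,
    b,
    alpha_normality: float = 0.05,
    labels: tuple[str, str] = ("a", "b"),
    force: str | None = None,
) -> ComparisonResult:
    """Normality-gated two-group test.

    Shapiro-Wilk is applied to each group at ``alpha_normality``; if both pass
    the unpaired two-tailed pooled-variance t-test runs, otherwise the
    two-sided Mann-Whitney test (exact null when both n ≤ 8 and tie-free,
    tie-corrected normal approximation otherwise).  ``force`` in
    {"t", "mannwhitney"} bypasses the gate (for calibration studies).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")

    if _degenerate(a, b):
        warnings.warn("degenerate comparison: all observations identical; p set to 1")
        return ComparisonResult(groups=labels, test_name="degenerate", statistic=0.0, p_value=1.0)

    normality_p = {}
    if force is None:
        for lab, x in zip(labels, (a, b)):
            if np.ptp(x) == 0:
                normality_p[lab] = 0.0  # constant group: treat as non-Gaussian
            else:
                normality_p[lab] = float(sps.shapiro(x).pvalue)
        use_t = all(p > alpha_normality for p in normality_p.values())
    else:
        use_t = force == "t"

    if use_t:
        res = sps.ttest_ind(a, b, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(stat):  # zero pooled variance, equal means excluded above
            stat, p = 0.0, 1.0
        name = "t-test"
    else:
        n1, n2 = len(a), len(b)
        tie_free = len(np.unique(np.concatenate([a, b]))) == n1 + n2
        method = "exact" if (n1 <= 8 and n2 <= 8 and tie_free) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
        name = "Mann-Whitney"
    logger.info("two-group routing: %s (normality p=%s)", name, normality_p)
    return ComparisonResult(
        groups=labels,
        test_name=name,
        statistic=stat,
        p_value=min(p, 1.0),
        normality_p=normality_p,
    )


def kruskal_dunn(
    groups: dict[str, np.ndarray],
    bonferroni: bool = False,
) -> ComparisonResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn's pairwise post hoc.

    Dunn's z for groups i, j compares mean ranks of the pooled sample:
    ``z = (R̄i − R̄j) / sqrt((N(N+1)/12 − T)(1/ni + 1/nj))`` with the tie term
    ``T = Σ(t³ − t) / (12(N − 1))``.  By default the unadjusted two-sided
    normal p is compared against the fixed α tiers; ``bonferroni=True``
    multiplies p by the number of pairs instead.
    """
    if len(groups) < 3:
        raise ValueError("kruskal_dunn needs >= 3 groups; use route_two_group_test")
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, x in zip(names, arrays):
        if len(x) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    h, p = sps.kruskal(*arrays)

    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g, x in zip(names, arrays):
        mean_ranks[g] = float(ranks[start : start + len(x)].mean())
        start += len(x)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    n_pairs = len(names) * (len(names) - 1) // 2
    pairwise = []
    for g1, g2 in itertools.combinations(names, 2):
        n1, n2 = len(groups[g1]), len(groups[g2])
        se = np.sqrt(var_base * (1.0 / n1 + 1.0 / n2))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p_pair = 2.0 * sps.norm.sf(abs(z))
        if bonferroni:
            p_pair = min(1.0, p_pair * n_pairs)
        pairwise.append(
            PairwiseDecision(
                pair=(g1, g2),
                statistic=float(z),
                p_value=float(p_pair),
                significant_at={alpha: p_pair < alpha for alpha in ALPHA_TIERS},
            )
        )
    return ComparisonResult(
        groups=tuple(names),
        test_name="Kruskal-Wallis+Dunn" + ("(bonferroni)" if bonferroni else ""),
        statistic=float(h),
        p_value=float(p),
        pairwise=pairwise,
    )


def comparison_report(result: ComparisonResult) -> str:
    """Human-readable text summary of one comparison."""
    lines = [
        f"test: {result.test_name}",
        f"groups: {', '.join(result.groups)}",
        f"statistic: {result.statistic:.4g}",
        f"p-value: {result.p_value:.4g} ({result.stars})",
    ]
    for d in result.pairwise:
        tiers = " ".join(f"p<{a}:{'yes' if ok else 'no'}" for a, ok in d.significant_at.items())
        lines.append(f"  {d.pair[0]} vs {d.pair[1]}: z={d.statistic:.3f} p={d.p_value:.4g} [{tiers}] {d.stars}")
    return "\n".join(lines)
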