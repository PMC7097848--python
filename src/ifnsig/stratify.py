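"""Control-calibrated stratification and clinical association statistics.

Patients are split into "high" and "low" signature-score strata using a
cutoff derived from healthy controls only: the control median plus twice the
control standard deviation. A score must strictly exceed the cutoff to be
called high — high means outside the control envelope. Binary clinical
outcomes (e.g. systemic flares, psoriatic arthritis) are then tested against
the strata with a two-sided Fisher exact test.

The module also provides the group-comparison and correlation tests used
around the scores: equal-variance t / one-way ANOVA with Dunnett's
many-to-one post test, Spearman correlation (exact permutation p at small n),
and paired non-parametrics (exact Wilcoxon signed rank, Friedman with Dunn
post test).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp, ndtr

from .containers import SampleTable, ValidationError
from .scoring import ScoreResult

__all__ = [
    "ContingencyTable2x2",
    "StratificationResult",
    "control_cutoff",
    "classify_high_low",
    "stratify",
    "fisher_exact_2x2",
    "associate",
    "compare_groups",
    "GroupComparison",
    "spearman",
    "paired_nonparametric",
    "PairedTestResult",
]

#: relative tolerance on the point-probability comparison in the two-sided
#: Fisher test, so float rounding never flips the inclusion of a table whose
#: probability ties the observed one.
FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for stratum (rows: high, low) x outcome (columns: yes, no)."""

    a: int  # high & yes
    b: int  # high & no
    c: int  # low & yes
    d: int  # low & no

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValidationError(f"table entries must be non-negative ints: {v}")
        if self.a + self.b + self.c + self.d < 1:
            raise ValidationError("contingency table is all zeros")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class StratificationResult:
    """High/low labels with the control-derived cutoff that produced them."""

    cutoff: float
    labels: dict[str, str]
    control_median: float
    control_sd: float

    def ids(self, label: str) -> list[str]:
        return [s for s, l in self.labels.items() if l == label]


def control_cutoff(
    control_scores: Sequence[float], robust: bool = False
) -> tuple[float, float, float]:
    """Median, spread and high/low cutoff from healthy-control scores.

    ``cutoff = median + 2 * sd`` with ``sd`` the sample standard deviation
    (n - 1 denominator); ``robust=True`` substitutes the scaled median
    absolute deviation (1.4826 * MAD) for the standard deviation.
    """
    x = np.asarray(list(control_scores), dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 control scores for a cutoff")
    med = float(np.median(x))
    if robust:
        sd = float(1.4826 * np.median(np.abs(x - med)))
    else:
        sd = float(np.std(x, ddof=1))
    return med, sd, med + 2.0 * sd


def classify_high_low(
    scores: ScoreResult | Mapping[str, float],
    cutoff: float,
    control_median: float = float("nan"),
    control_sd: float = float("nan"),
) -> StratificationResult:
    """Label each sample high (score strictly above cutoff) or low."""
    if not np.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    values = scores.scores if isinstance(scores, ScoreResult) else dict(scores)
    labels = {s: ("high" if v > cutoff else "low") for s, v in values.items()}
    return StratificationResult(
        cutoff=float(cutoff),
        labels=labels,
        control_median=control_median,
        control_sd=control_sd,
    )


def stratify(
    scores: ScoreResult | Mapping[str, float],
    control_ids: Sequence[str],
    robust: bool = False,
) -> StratificationResult:
    """Cutoff from the listed controls, then high/low labels for all samples."""
    values = scores.scores if isinstance(scores, ScoreResult) else dict(scores)
    missing = [s for s in control_ids if s not in values]
    if missing:
        raise ValidationError(f"control id {missing[0]!r} has no score")
    med, sd, cut = control_cutoff([values[s] for s in control_ids], robust=robust)
    return classify_high_low(values, cut, control_median=med, control_sd=sd)


# -- Fisher exact test ---------------------------------------------------------


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table, point-probability rule.

    Sums, over all tables with the observed margins, the hypergeometric point
    probabilities that are <= the observed table's probability (up to a
    relative tolerance of ``FISHER_REL_TOL``). Computed by enumeration in log
    space.
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        (a, b), (c, d) = np.asarray(table, dtype=int)
        ContingencyTable2x2(int(a), int(b), int(c), int(d))  # validate
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    log_p = _log_comb(r1, k) + _log_comb(r2, c1 - k) - _log_comb(n, c1)
    log_obs = float(log_p[k == a][0])
    include = log_p <= log_obs + np.log1p(FISHER_REL_TOL)
    return float(min(1.0, np.exp(logsumexp(log_p[include]))))


def associate(
    strat: StratificationResult, samples: SampleTable, flag: str
) -> tuple[ContingencyTable2x2, float]:
    """High/low stratum versus a binary clinical flag, Fisher exact p.

    Samples with a missing flag, and samples without a stratum label, are
    dropped (complete-case analysis). A zero margin after the drops yields a
    warning and p = 1.
    """
    flag_vals = samples.flag_values(flag)
    counts = {("high", True): 0, ("high", False): 0, ("low", True): 0, ("low", False): 0}
    n_used = 0
    for sample, value in flag_vals.items():
        label = strat.labels.get(sample)
        if label is None:
            continue
        counts[(label, value)] += 1
        n_used += 1
    if n_used == 0:
        warnings.warn(f"no sample has both a stratum and flag {flag!r}", stacklevel=2)
        return ContingencyTable2x2(0, 0, 0, 1), 1.0
    table = ContingencyTable2x2(
        counts[("high", True)],
        counts[("high", False)],
        counts[("low", True)],
        counts[("low", False)],
    )
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn(
            f"degenerate stratum/outcome margin for flag {flag!r}; p = 1",
            stacklevel=2,
        )
        return table, 1.0
    return table, fisher_exact_2x2(table)


# -- group comparisons ---------------------------------------------------------


@dataclass
class GroupComparison:
    """Result of a two-group t test or ANOVA + Dunnett many-to-one post test."""

    test: str  # "t" or "anova"
    p_value: float  # t p (2 groups) or ANOVA F p (>= 3 groups)
    statistic: float
    dunnett_p: dict[str, float] | None = None  # treatment label -> adjusted p


def compare_groups(
    values: Sequence[float],
    labels: Sequence[str],
    control_label: str | None = None,
    equal_var: bool = True,
    seed: int = 0,
) -> GroupComparison:
    """Compare score distributions between groups.

    Two groups: two-sided unpaired t test (classical equal-variance by
    default; ``equal_var=False`` for Welch). Three or more groups: one-way
    ANOVA, then Dunnett's test of every other group against
    ``control_label``, with the family-wise adjustment evaluated numerically
    from a seeded generator.
    """
    values = np.asarray(list(values), dtype=float)
    labels = [str(l) for l in labels]
    if len(values) != len(labels):
        raise ValidationError("values and labels differ in length")
    by_group: dict[str, list[float]] = {}
    for v, l in zip(values, labels):
        by_group.setdefault(l, []).append(v)
    if len(by_group) < 2:
        raise ValidationError("need at least 2 groups")
    small = [l for l, vs in by_group.items() if len(vs) < 2]
    if small:
        raise ValidationError(f"group {small[0]!r} has fewer than 2 samples")
    groups = {l: np.asarray(vs) for l, vs in by_group.items()}
    if len(groups) == 2:
        g1, g2 = groups.values()
        res = stats.ttest_ind(g1, g2, equal_var=equal_var)
        return GroupComparison(
            test="t", p_value=float(res.pvalue), statistic=float(res.statistic)
        )
    if control_label is None or control_label not in groups:
        raise ValidationError(
            f"control_label {control_label!r} needed for >= 3 groups"
        )
    f_res = stats.f_oneway(*groups.values())
    treatment_labels = [l for l in groups if l != control_label]
    dunnett = stats.dunnett(
        *[groups[l] for l in treatment_labels],
        control=groups[control_label],
        random_state=np.random.default_rng(seed),
    )
    return GroupComparison(
        test="anova",
        p_value=float(f_res.pvalue),
        statistic=float(f_res.statistic),
        dunnett_p={
            l: float(p) for l, p in zip(treatment_labels, np.atleast_1d(dunnett.pvalue))
        },
    )


# -- Spearman correlation ------------------------------------------------------

#: sample sizes up to this enumerate all rank permutations for an exact p
SPEARMAN_EXACT_N = 9


@lru_cache(maxsize=8)
def _perm_rho_values(ranks_x: tuple, ranks_y: tuple) -> np.ndarray:
    """|rho| over all permutations of ranks_y against fixed ranks_x."""
    rx = np.asarray(ranks_x, dtype=float)
    perms = np.array(list(itertools.permutations(ranks_y)), dtype=float)
    rx_c = rx - rx.mean()
    py_c = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (py_c**2).sum(axis=1))
    return np.abs(py_c @ rx_c) / denom


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    For n <= 9 the two-sided p is exact, from full enumeration of rank
    permutations; above that, the usual t approximation on rho is used.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("spearman needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("spearman is undefined for a constant vector")
    rho, p_approx = stats.spearmanr(x, y)
    rho = float(rho)
    n = x.size
    if n <= SPEARMAN_EXACT_N:
        # the permutation distribution is invariant to reordering the donors,
        # so canonicalize rank vectors for cache reuse across calls
        rx = tuple(sorted(stats.rankdata(x)))
        ry = tuple(sorted(stats.rankdata(y)))
        abs_rhos = _perm_rho_values(rx, ry)
        p = float(np.mean(abs_rhos >= abs(rho) - 1e-12))
        return rho, p
    return rho, float(p_approx)


# -- paired non-parametric tests ----------------------------------------------


@dataclass
class PairedTestResult:
    """Wilcoxon signed-rank (2 conditions) or Friedman + Dunn (>= 3)."""

    test: str  # "wilcoxon" or "friedman"
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None = None  # Dunn pairwise, Bonferroni-adjusted


def _dunn_posthoc(data: np.ndarray, condition_names: list[str]) -> pd.DataFrame:
    """Dunn pairwise z tests on within-donor rank sums, Bonferroni-adjusted."""
    n, k = data.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    pairs = list(itertools.combinations(range(k), 2))
    for i, j in pairs:
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * (1.0 - ndtr(abs(z)))
        rows.append(
            {
                "condition_a": condition_names[i],
                "condition_b": condition_names[j],
                "z": z,
                "p_value": min(1.0, p * len(pairs)),
            }
        )
    return pd.DataFrame(rows)


def paired_nonparametric(values, condition_names: list[str] | None = None) -> PairedTestResult:
    """Donor-paired comparison of 2+ conditions without normality assumptions.

    ``values`` is a donors x conditions grid with no missing cells (the tests
    are paired) and at least 3 donors. Two conditions: Wilcoxon signed rank,
    exact enumeration of sign assignments up to n = 25 and zero differences
    dropped. Three or more: Friedman chi-square on within-donor ranks,
    followed by Dunn pairwise z tests with Bonferroni adjustment.
    """
    if isinstance(values, pd.DataFrame):
        condition_names = condition_names or [str(c) for c in values.columns]
        data = values.to_numpy(dtype=float)
    else:
        data = np.asarray(values, dtype=float)
    if data.ndim != 2:
        raise ValidationError("paired data must be a donors x conditions grid")
    if np.any(~np.isfinite(data)):
        raise ValidationError("paired tests do not allow missing cells")
    n, k = data.shape
    if n < 3:
        raise ValidationError("need at least 3 donors")
    if k < 2:
        raise ValidationError("need at least 2 conditions")
    condition_names = condition_names or [f"condition_{i}" for i in range(k)]
    if k == 2:
        diffs = data[:, 0] - data[:, 1]
        if np.all(diffs == 0):
            return PairedTestResult(test="wilcoxon", statistic=0.0, p_value=1.0)
        method = "exact" if n <= 25 else "approx"
        res = stats.wilcoxon(
            data[:, 0], data[:, 1], zero_method="wilcox", method=method
        )
        return PairedTestResult(
            test="wilcoxon", statistic=float(res.statistic), p_value=float(res.pvalue)
        )
    if np.all(data == data[:, [0]]):
        # all conditions identical within each donor: statistic 0 by definition
        return PairedTestResult(
            test="friedman",
            statistic=0.0,
            p_value=1.0,
            posthoc=_dunn_posthoc(data, condition_names),
        )
    stat, p = stats.friedmanchisquare(*[data[:, j] for j in range(k)])
    return PairedTestResult(
        test="friedman",
        statistic=float(stat),
        p_value=float(p),
        posthoc=_dunn_posthoc(data, condition_names),
    )
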