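"""Group-comparison statistics for the permeability assay.

Implements the study's statistical battery: Student's t (paired and
pooled unpaired), exact-small-sample Wilcoxon signed-rank and
Mann-Whitney tests with full-enumeration null distributions, and
one-way ANOVA followed by the Newman-Keuls stepwise studentized-range
procedure. Test selection follows the assay's rule: matched samples are
compared with the Wilcoxon signed-rank test, all other comparisons with
Mann-Whitney. All tests are two-sided.

Exact modes enumerate every sign assignment (signed-rank, n <= 12) or
group labeling (Mann-Whitney, n1+n2 <= 14) with average-rank ties; above
those sizes a tie-corrected normal approximation with continuity
correction is used, and the mode is recorded on the result.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

__all__ = [
    "TestResult",
    "PosthocTable",
    "t_test",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "anova_newman_keuls",
    "compare_groups",
]

EXACT_MAX_SIGNED_RANK = 12
EXACT_MAX_MANN_WHITNEY = 14


@dataclass
class TestResult:
    """Outcome of one group comparison (two-sided unless stated)."""

    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    pairing: str  # "matched" | "independent"
    sided: str = "two-sided"
    method: str = "exact"  # "exact" | "asymptotic" | "analytic"
    df: float | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _two_sided_tail(null: np.ndarray, observed: float) -> float:
    """Doubled smaller tail of a discrete null, capped at 1."""
    lo = np.mean(null <= observed + 1e-12)
    hi = np.mean(null >= observed - 1e-12)
    return float(min(1.0, 2.0 * min(lo, hi)))


# ---------------------------------------------------------------------------
# t tests


def t_test(
    x,
    y,
    *,
    paired: bool = False,
    welch: bool = False,
    pair_ids_x=None,
    pair_ids_y=None,
) -> TestResult:
    """Student's two-tailed t test (classical pooled-variance unpaired by
    default; Welch behind a flag; paired on aligned pairs).

    Degenerate inputs follow the conventions: all-zero paired
    differences, or zero variance in both groups with equal means, give
    p = 1 (flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per group")
    if pair_ids_x is not None or pair_ids_y is not None:
        if not paired:
            raise ValueError("pair ids given for an unpaired test")
        if list(pair_ids_x) != list(pair_ids_y):
            raise ValueError("mismatched pair ids")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal n")
        d = x - y
        n = len(d)
        sd = d.std(ddof=1)
        if sd == 0.0:
            p = 1.0 if np.all(d == 0) else 0.0
            return TestResult(
                "paired t", 0.0 if np.all(d == 0) else np.inf, p, (n,), "matched",
                method="analytic", df=n - 1, notes=["zero-variance differences"],
            )
        t = d.mean() / (sd / np.sqrt(n))
        p = 2.0 * sps.t.sf(abs(t), n - 1)
        return TestResult("paired t", float(t), float(p), (n,), "matched", method="analytic", df=n - 1)

    n1, n2 = len(x), len(y)
    if welch:
        t, p = sps.ttest_ind(x, y, equal_var=False)
        df = sps.ttest_ind(x, y, equal_var=False).df
        return TestResult("Welch t", float(t), float(p), (n1, n2), "independent", method="analytic", df=float(df))
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0.0:
        equal = x.mean() == y.mean()
        return TestResult(
            "unpaired t (pooled)", 0.0 if equal else np.inf, 1.0 if equal else 0.0,
            (n1, n2), "independent", method="analytic", df=n1 + n2 - 2,
            notes=["zero variance in both groups"],
        )
    t = (x.mean() - y.mean()) / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult("unpaired t (pooled)", float(t), float(p), (n1, n2), "independent", method="analytic", df=df)


# ---------------------------------------------------------------------------
# rank tests


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on matched pairs.

    ``y=None`` treats ``x`` as precomputed differences. Zero differences
    are dropped (count reported). Exact p by enumeration of all 2^n sign
    assignments for n <= 12 (average-rank ties); tie-corrected normal
    approximation with continuity correction above. The statistic is W+,
    the sum of ranks of positive differences.
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValueError("matched pairs require equal n")
        d = x - y
    else:
        d = x
    n_total = len(d)
    nz = d[d != 0]
    n_zero = n_total - len(nz)
    notes = []
    if n_zero:
        notes.append(f"{n_zero} zero differences dropped")
    n = len(nz)
    if n == 0:
        return TestResult(
            "Wilcoxon signed-rank", 0.0, 1.0, (n_total,), "matched",
            method="exact", notes=notes + ["all differences zero"],
        )
    ranks = rankdata(np.abs(nz))
    w_pos = float(ranks[nz > 0].sum())

    if n <= EXACT_MAX_SIGNED_RANK:
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        null = signs @ ranks
        p = _two_sided_tail(null, w_pos)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
        z = (abs(w_pos - mu) - 0.5) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(z)))
        method = "asymptotic"
    return TestResult("Wilcoxon signed-rank", w_pos, p, (n_total,), "matched", method=method, notes=notes)


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test on independent samples.

    Exact p by enumeration over all C(n1+n2, n1) group labelings when
    n1+n2 <= 14 (average ranks for ties); tie-corrected normal
    approximation with continuity correction otherwise. The statistic is
    U1, counting (x > y) wins with half-credit for ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2

    if n <= EXACT_MAX_MANN_WHITNEY:
        null = np.array([
            sum(ranks[list(idx)]) - n1 * (n1 + 1) / 2.0
            for idx in itertools.combinations(range(n), n1)
        ])
        p = _two_sided_tail(null, u1)
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var == 0.0:
            return TestResult(
                "Mann-Whitney U", u1, 1.0, (n1, n2), "independent",
                method="asymptotic", notes=["all observations tied"],
            )
        z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(z)))
        method = "asymptotic"
    return TestResult("Mann-Whitney U", u1, p, (n1, n2), "independent", method=method)


# ---------------------------------------------------------------------------
# ANOVA + Newman-Keuls


@dataclass
class PosthocPair:
    group_a: str
    group_b: str
    mean_diff: float
    span: int
    q: float
    q_critical: float
    significant: bool
    tested: bool  # False when declared NS by stepwise closure


@dataclass
class PosthocTable:
    pairs: list[PosthocPair]
    mse: float
    df_error: int
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.pairs])

    def significant_pairs(self) -> set[frozenset]:
        return {frozenset((p.group_a, p.group_b)) for p in self.pairs if p.significant}


@lru_cache(maxsize=4096)
def _q_critical(alpha: float, span: int, df: int) -> float:
    return float(sps.studentized_range.ppf(1.0 - alpha, span, df))


def anova_newman_keuls(
    groups: dict[str, np.ndarray] | list,
    *,
    alpha: float = 0.05,
) -> tuple[TestResult, PosthocTable]:
    """One-way ANOVA followed by the Newman-Keuls stepwise procedure.

    Group means are ordered and pairs compared with the studentized
    range q at span-dependent critical values from the studentized-range
    distribution (unequal n handled with the harmonic standard error).
    Testing proceeds from the widest span inward and enforces stepwise
    closure: every pair inside a non-significant span is declared
    non-significant without testing.

    Identical groups (zero between- and within-variance) give F = 0,
    p = 1 by convention.
    """
    if not isinstance(groups, dict):
        groups = {f"g{i}": g for i, g in enumerate(groups)}
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    k = len(data)
    if k < 3:
        raise ValueError("need at least 3 groups")
    ns = [len(g) for g in data]
    if min(ns) < 2:
        raise ValueError("every group needs n >= 2")
    n_total = sum(ns)
    grand = np.concatenate(data).mean()
    ss_between = sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, data))
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in data)
    df_b, df_w = k - 1, n_total - k
    ms_between = ss_between / df_b
    mse = ss_within / df_w
    if mse == 0.0 and ms_between == 0.0:
        f_stat, p = 0.0, 1.0
        notes = ["all groups identical"]
    elif mse == 0.0:
        f_stat, p = np.inf, 0.0
        notes = ["zero within-group variance"]
    else:
        f_stat = ms_between / mse
        p = float(sps.f.sf(f_stat, df_b, df_w))
        notes = []
    anova = TestResult(
        "one-way ANOVA", float(f_stat), p, tuple(ns), "independent",
        method="analytic", df=float(df_w), notes=notes,
    )

    # Newman-Keuls on ordered means
    order = np.argsort([g.mean() for g in data])
    names_s = [names[i] for i in order]
    means_s = [data[i].mean() for i in order]
    ns_s = [ns[i] for i in order]

    decided: dict[tuple[int, int], PosthocPair] = {}

    def declare_ns(i: int, j: int) -> None:
        for a in range(i, j + 1):
            for b in range(a + 1, j + 1):
                if (a, b) not in decided:
                    decided[(a, b)] = PosthocPair(
                        names_s[a], names_s[b], means_s[b] - means_s[a],
                        b - a + 1, np.nan, np.nan, False, False,
                    )

    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if (i, j) in decided:
                continue
            diff = means_s[j] - means_s[i]
            se = np.sqrt(mse / 2.0 * (1.0 / ns_s[i] + 1.0 / ns_s[j]))
            if se == 0.0:
                q = np.inf if diff > 0 else 0.0
            else:
                q = diff / se
            q_crit = _q_critical(alpha, span, df_w)
            sig = q > q_crit
            decided[(i, j)] = PosthocPair(
                names_s[i], names_s[j], diff, span, float(q), q_crit, bool(sig), True
            )
            if not sig:
                declare_ns(i, j)

    pairs = [decided[key] for key in sorted(decided)]
    return anova, PosthocTable(pairs, float(mse), df_w, alpha)


# ---------------------------------------------------------------------------
# automatic test selection (assay rule)


def compare_groups(
    data: pd.DataFrame,
    *,
    value: str = "p_um_s",
    group: str = "condition",
    pair: str | None = "matched_pair_id",
    test: str = "auto",
) -> TestResult:
    """Compare two groups from an aggregated permeability table.

    With ``test='auto'`` the assay's rule applies: if every observation
    belongs to a complete matched pair, the Wilcoxon signed-rank test is
    used on the paired differences; otherwise Mann-Whitney. ``test='t'``
    uses the corresponding Student's t test instead.
    """
    levels = list(pd.unique(data[group]))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups in {group!r}, got {levels}")
    a = data[data[group] == levels[0]]
    b = data[data[group] == levels[1]]

    matched = False
    if pair is not None and pair in data.columns:
        pa = a[pair].dropna()
        pb = b[pair].dropna()
        matched = (
            len(pa) == len(a) == len(pb) == len(b)
            and sorted(pa) == sorted(pb)
            and pa.is_unique
        )
    if matched:
        a = a.sort_values(pair)
        b = b.sort_values(pair)
        if test == "t":
            result = t_test(a[value].to_numpy(), b[value].to_numpy(), paired=True)
        else:
            result = wilcoxon_signed_rank(a[value].to_numpy(), b[value].to_numpy())
        result.notes.append(f"matched pairs on {pair!r}: {levels[0]} vs {levels[1]}")
    else:
        if test == "t":
            result = t_test(a[value].to_numpy(), b[value].to_numpy())
        else:
            result = mann_whitney(a[value].to_numpy(), b[value].to_numpy())
        result.notes.append(f"independent groups: {levels[0]} vs {levels[1]}")
    return result
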