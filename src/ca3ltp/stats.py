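"""Cohort-level statistical battery.

Conventions chosen to match how slice-cohort results are customarily
reported:

* Fisher's exact test is two-sided by the probability-mass rule (sum the
  hypergeometric probabilities of all tables, with the observed margins,
  that are no more probable than the observed one).
* The 2x2 chi-square applies the Yates continuity correction by default.
* Rank tests use exact small-sample distributions where tie structure
  allows (Mann-Whitney n <= 10 per group, Wilcoxon n <= 25), otherwise
  the tie-corrected normal approximation.
* The one-way ANOVA posthoc is the Student-Newman-Keuls stepdown on the
  studentized range at fixed alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range

__all__ = [
    "ContingencyTable", "TestResult", "PosthocPair",
    "fisher_exact_two_sided", "chi_square_2x2",
    "mann_whitney_u", "wilcoxon_signed_rank", "kruskal_wallis",
    "anova_with_posthoc", "two_way_anova", "pearson_correlation_test",
    "build_contingency", "round_p",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 present/absent counts; rows are conditions."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("present", "absent")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TestResult:
    statistic: Optional[float]
    p_value: float
    method: str
    n: tuple = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class PosthocPair:
    groups: tuple[str, str]
    q: float
    critical: float
    span: int
    significant: bool


def round_p(p: float, digits: int = 3) -> float:
    """Half-even rounding used when comparing against printed p-values."""
    return float(np.round(p, digits))


def _as_table(table) -> ContingencyTable:
    if isinstance(table, ContingencyTable):
        return table
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    return ContingencyTable(*arr.ravel().tolist())


def fisher_exact_two_sided(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    A table with an empty margin carries no information: p = 1 with a
    degeneracy flag instead of an error.
    """
    t = _as_table(table)
    arr = t.to_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return TestResult(None, 1.0, "fisher-exact (degenerate margin)",
                          (int(arr[0].sum()), int(arr[1].sum())),
                          {"degenerate": True})
    res = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(None, float(res.pvalue), "fisher-exact two-sided",
                      (int(arr[0].sum()), int(arr[1].sum())),
                      {"odds_ratio": float(res.statistic)})


def chi_square_2x2(table, continuity_correction: bool = True) -> TestResult:
    """Pearson chi-square (df = 1) with Yates correction by default."""
    t = _as_table(table)
    arr = t.to_array()
    expected = sps.contingency.expected_freq(arr)
    if (expected == 0).any():
        raise ValueError("a zero expected cell makes the chi-square invalid; "
                         "use fisher_exact_two_sided instead")
    res = sps.chi2_contingency(arr, correction=continuity_correction)
    name = "chi-square (Yates)" if continuity_correction else "chi-square"
    return TestResult(float(res.statistic), float(res.pvalue), name,
                      (int(arr[0].sum()), int(arr[1].sum())),
                      {"dof": int(res.dof)})


def _has_ties(*samples) -> bool:
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact distribution when both groups have n <= 10 and there are no
    ties; tie-corrected normal approximation (midranks) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    exact = len(x) <= 10 and len(y) <= 10 and not _has_ties(x, y)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      f"mann-whitney-u ({method})", (len(x), len(y)))


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Two-sided Wilcoxon signed-rank for paired data (or differences).

    Exact for n <= 25 without zeros/ties; normal approximation otherwise.
    All-identical pairs make the test degenerate and are rejected.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if np.all(d == 0):
        raise ValueError("all paired differences are zero: the signed-rank "
                         "test is degenerate")
    nz = d[d != 0]
    exact = nz.size <= 25 and nz.size == d.size and not _has_ties(np.abs(nz))
    method = "exact" if exact else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"wilcoxon-signed-rank ({method})", (int(d.size),))


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H across k independent groups (chi-square p)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    res = sps.kruskal(*groups)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "kruskal-wallis", tuple(len(g) for g in groups),
                      {"df": len(groups) - 1})


@lru_cache(maxsize=256)
def _q_crit(span: int, df: int, alpha: float) -> float:
    return float(studentized_range.ppf(1.0 - alpha, span, df))


def anova_with_posthoc(groups: dict | Sequence, alpha: float = 0.05
                       ) -> tuple[TestResult, list[PosthocPair]]:
    """One-way ANOVA with the Student-Newman-Keuls stepdown posthoc.

    ``groups`` is a mapping label -> sample (or a sequence of samples).
    SNK orders the group means, tests each range against the studentized
    range critical value for its span, and never tests inside a range
    already retained as non-significant.
    """
    if not isinstance(groups, dict):
        groups = {f"g{i + 1}": g for i, g in enumerate(groups)}
    labels = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(data) < 3:
        raise ValueError("SNK posthoc needs at least 3 groups")
    ns = [d.size for d in data]
    if any(n < 2 for n in ns):
        raise ValueError("every group needs at least 2 observations")
    f_res = sps.f_oneway(*data)
    n_total = sum(ns)
    k = len(data)
    df_err = n_total - k
    mse = sum((d.size - 1) * np.var(d, ddof=1) for d in data) / df_err
    anova = TestResult(float(f_res.statistic), float(f_res.pvalue),
                       "one-way ANOVA", tuple(ns),
                       {"df": (k - 1, df_err), "mse": float(mse)})

    means = np.array([d.mean() for d in data])
    order = np.argsort(means)
    pairs: list[PosthocPair] = []
    nonsig: list[tuple[int, int]] = []
    if mse <= 0:
        for i in range(k):
            for j in range(i + 1, k):
                pairs.append(PosthocPair((labels[i], labels[j]), 0.0, np.inf,
                                         k, False))
        return anova, pairs
    for span in range(k, 1, -1):
        crit = _q_crit(span, df_err, alpha)
        for i in range(0, k - span + 1):
            j = i + span - 1
            gi, gj = order[i], order[j]
            name = (labels[gi], labels[gj])
            if any(a <= i and j <= b for a, b in nonsig):
                pairs.append(PosthocPair(name, float("nan"), crit, span, False))
                continue
            se = np.sqrt(mse / 2.0 * (1.0 / ns[gi] + 1.0 / ns[gj]))
            q = (means[gj] - means[gi]) / se
            sig = bool(q > crit)
            pairs.append(PosthocPair(name, float(q), crit, span, sig))
            if not sig:
                nonsig.append((i, j))
    return anova, pairs


def two_way_anova(data: pd.DataFrame, response: str, factor_a: str,
                  factor_b: str, interaction: bool = True) -> dict[str, TestResult]:
    """Two-way ANOVA (type-II least squares) via an OLS fit.

    Returns a TestResult per effect keyed by factor name (and
    ``"interaction"`` when requested).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data[[response, factor_a, factor_b]].dropna().copy()
    df = df.rename(columns={response: "_y", factor_a: "_a", factor_b: "_b"})
    for fac in ("_a", "_b"):
        if df[fac].nunique() < 2:
            raise ValueError("each factor needs at least two levels")
    if interaction:
        cells = df.groupby(["_a", "_b"]).size()
        n_cells = df["_a"].nunique() * df["_b"].nunique()
        if len(cells) < n_cells:
            raise ValueError("empty design cell: cannot estimate the interaction")
    formula = "_y ~ C(_a) * C(_b)" if interaction else "_y ~ C(_a) + C(_b)"
    fit = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = sm.stats.anova_lm(fit, typ=2)
    out = {}
    mapping = {"C(_a)": factor_a, "C(_b)": factor_b, "C(_a):C(_b)": "interaction"}
    for row, key in mapping.items():
        if row in tab.index:
            out[key] = TestResult(float(tab.loc[row, "F"]),
                                  float(tab.loc[row, "PR(>F)"]),
                                  "two-way ANOVA", (int(len(df)),),
                                  {"df": float(tab.loc[row, "df"])})
    return out


def pearson_correlation_test(x, y) -> TestResult:
    """Pearson r with the two-sided t-test on df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "pearson-r (t-test)", (int(x.size),))


def build_contingency(outcomes: Sequence, row_key, phase: str,
                      row_labels: Optional[tuple[str, str]] = None) -> ContingencyTable:
    """Present/absent afterpotential counts per condition.

    ``row_key`` maps a PlasticityOutcome to its row label (exactly two
    labels must occur); presence in ``phase`` ('before'/'after') means at
    least one detected afterpotential in that phase's designated sweeps.
    Slices missing the phase are excluded with a warning, never silently.
    """
    if phase not in ("before", "after"):
        raise ValueError("phase must be 'before' or 'after'")
    attr = f"ap_present_{phase}"
    counts: dict[str, list[int]] = {}
    for o in outcomes:
        present = getattr(o, attr)
        if present is None:
            warnings.warn(f"slice {o.slice_id} has no {phase!r} phase; excluded "
                          "from the contingency table")
            continue
        counts.setdefault(str(row_key(o)), [0, 0])[0 if present else 1] += 1
    labels = list(row_labels) if row_labels is not None else sorted(counts)
    if len(labels) != 2:
        raise ValueError(f"contingency rows must have exactly 2 levels, got {labels}")
    for lab in labels:
        counts.setdefault(lab, [0, 0])
    (a, b), (c, d) = counts[labels[0]], counts[labels[1]]
    return ContingencyTable(a, b, c, d, (labels[0], labels[1]))
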