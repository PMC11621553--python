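"""Gated group-comparison statistics.

The decision procedure mirrors common practice for small-sample biology
datasets: per-group Shapiro-Wilk normality gates, a log10 then Box-Cox
transform attempt when normality fails, a variance-homogeneity gate (variance
ratio F test for two groups, Bartlett for more), and dispatch to Student t /
Welch t / one-way ANOVA + Tukey HSD when parametric assumptions hold, or
Mann-Whitney / Kruskal-Wallis otherwise.  Every gate decision is recorded in
an audit trail on the result.

The Mann-Whitney W statistic follows the R ``wilcox.test`` convention: the U
statistic of the first-listed group (rank sum minus n1(n1+1)/2).  The exact
null distribution is computed by dynamic programming over rank subsets
(valid without ties); the normal approximation applies the usual tie
correction and an optional continuity correction (on by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    DegenerateDataError,
    DomainError,
    InvalidParameterError,
    UnsupportedSizeError,
)

logger = logging.getLogger(__name__)

GATE_ALPHA = 0.05


@dataclass
class SampleGroup:
    """A labelled sample of real-valued measurements (one per biological unit)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise InvalidParameterError(f"group {self.label!r} is empty")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError(f"group {self.label!r} has non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class TestResult:
    """Outcome of a statistical comparison.

    ``df`` is a float (possibly fractional, Welch), a (df1, df2) tuple
    (ANOVA), or ``None`` (rank tests, Fisher exact).  ``posthoc`` carries the
    Tukey HSD pairwise table when applicable and ``letters`` the associated
    compact letter display.  ``audit`` preserves the gate p-values and
    transform decisions that led to the dispatched test.
    """

    test: str
    statistic_symbol: str
    statistic: float
    df: Optional[object]
    tail: str
    transform: str
    p: float
    posthoc: Optional[pd.DataFrame] = None
    letters: Optional[dict] = None
    audit: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "test": self.test,
            "statistic_symbol": self.statistic_symbol,
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "tail": self.tail,
            "transform": self.transform,
            "p": self.p,
            "audit": self.audit,
            "warnings": list(self.warnings),
        }
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        if self.letters is not None:
            d["letters"] = self.letters
        return d


@dataclass
class ContingencyTable:
    """A 2xk table of non-negative integer counts with labels."""

    counts: np.ndarray
    row_labels: Sequence[str] = ()
    col_labels: Sequence[str] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise InvalidParameterError("contingency counts must be integers")
            arr = np.round(arr).astype(int)
        if arr.ndim != 2 or np.any(arr < 0):
            raise InvalidParameterError("contingency table must be 2-D with counts >= 0")
        if np.any(arr.sum(axis=1) == 0) or np.any(arr.sum(axis=0) == 0):
            raise InvalidParameterError("every row and column margin must be positive")
        self.counts = arr


# ---------------------------------------------------------------------------
# transforms and gates
# ---------------------------------------------------------------------------


@dataclass
class TransformResult:
    values: np.ndarray
    kind: str
    lmbda: Optional[float] = None

    @property
    def label(self) -> str:
        if self.kind == "boxcox":
            return f"boxcox(lambda={self.lmbda:.6g})"
        return self.kind


def transform(values, kind: str, lmbda: Optional[float] = None) -> TransformResult:
    """Apply log10 or Box-Cox to a strictly positive sample.

    Box-Cox is (x^lambda - 1)/lambda for lambda != 0 and ln x at lambda = 0;
    when ``lmbda`` is not supplied it is fitted by maximum likelihood and
    reported on the result.
    """
    x = np.asarray(values, dtype=float).ravel()
    bad = np.flatnonzero(x <= 0)
    if kind in ("log10", "boxcox") and bad.size:
        raise DomainError(
            f"{kind} requires strictly positive values; offending index {int(bad[0])} "
            f"(value {x[bad[0]]})"
        )
    if kind == "none":
        return TransformResult(values=x, kind="none")
    if kind == "log10":
        return TransformResult(values=np.log10(x), kind="log10")
    if kind == "boxcox":
        if lmbda is None:
            xt, fitted = sps.boxcox(x)
            return TransformResult(values=xt, kind="boxcox", lmbda=float(fitted))
        if lmbda == 0:
            return TransformResult(values=np.log(x), kind="boxcox", lmbda=0.0)
        return TransformResult(values=(x**lmbda - 1.0) / lmbda, kind="boxcox", lmbda=float(lmbda))
    raise InvalidParameterError(f"unknown transform {kind!r}")


def shapiro_wilk(values) -> float:
    """Shapiro-Wilk normality p-value (Royston's algorithm via scipy), 3 <= n <= 5000."""
    x = np.asarray(values, dtype=float).ravel()
    if not 3 <= x.size <= 5000:
        raise UnsupportedSizeError(f"Shapiro-Wilk supports 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("Shapiro-Wilk is undefined for a constant sample")
    return float(sps.shapiro(x).pvalue)


def fisher_variance_test(x, y) -> tuple[float, tuple[int, int], float]:
    """Two-tailed variance-ratio F test for two groups.

    Returns (F, (df1, df2), p) with F = var(x)/var(y) (sample variances,
    ddof=1) and p = 2 * min(lower, upper tail), capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidParameterError("variance test needs n >= 2 per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise DegenerateDataError("both groups have zero variance")
    df = (x.size - 1, y.size - 1)
    if v2 == 0:
        return math.inf, df, 0.0
    f = v1 / v2
    p = 2 * min(sps.f.cdf(f, *df), sps.f.sf(f, *df))
    return float(f), df, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# p-value primitives
# ---------------------------------------------------------------------------


def t_pvalue(t: float, df: float, tail: str = "two") -> float:
    """p-value of a t statistic: two-tailed 2*S(|t|; df), one-tailed S(t; df),
    where S is the upper-tail probability of the t distribution."""
    if df <= 0:
        raise InvalidParameterError(f"df must be positive, got {df}")
    if tail == "two":
        return float(2 * sps.t.sf(abs(t), df))
    if tail == "one":
        return float(sps.t.sf(t, df))
    raise InvalidParameterError(f"tail must be 'one' or 'two', got {tail!r}")


def welch_df(n1: int, s1: float, n2: int, s2: float) -> float:
    """Welch-Satterthwaite degrees of freedom from group sizes and SDs."""
    if n1 < 2 or n2 < 2:
        raise InvalidParameterError("Welch df needs n >= 2 per group")
    if s1 == 0 and s2 == 0:
        raise DegenerateDataError("both groups have zero variance")
    v1 = s1**2 / n1
    v2 = s2**2 / n2
    return float((v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)))


def kw_pvalue(K: float, k_groups: int) -> float:
    """Upper-tail chi-square p of a Kruskal-Wallis statistic with k-1 df."""
    if k_groups < 2:
        raise InvalidParameterError("Kruskal-Wallis needs >= 2 groups")
    return float(sps.chi2.sf(K, k_groups - 1))


# ---------------------------------------------------------------------------
# two-sample tests
# ---------------------------------------------------------------------------


def student_t_test(x: SampleGroup, y: SampleGroup, tail: str = "two",
                   transform_label: str = "none") -> TestResult:
    """Pooled-variance two-sample t test."""
    n1, n2 = x.n, y.n
    if n1 < 2 or n2 < 2:
        raise InvalidParameterError("t test needs n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.values.var(ddof=1) + (n2 - 1) * y.values.var(ddof=1)) / df
    if sp2 == 0:
        raise DegenerateDataError("pooled variance is zero")
    t = (x.values.mean() - y.values.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return TestResult(
        test="student_t", statistic_symbol="t", statistic=float(t), df=float(df),
        tail=tail, transform=transform_label, p=t_pvalue(t, df, tail),
    )


def welch_t_test(x: SampleGroup, y: SampleGroup, tail: str = "two",
                 transform_label: str = "none") -> TestResult:
    """Welch unequal-variance two-sample t test with fractional df."""
    s1, s2 = x.values.std(ddof=1), y.values.std(ddof=1)
    df = welch_df(x.n, s1, y.n, s2)
    se = math.sqrt(s1**2 / x.n + s2**2 / y.n)
    t = (x.values.mean() - y.values.mean()) / se
    return TestResult(
        test="welch_t", statistic_symbol="t", statistic=float(t), df=df,
        tail=tail, transform=transform_label, p=t_pvalue(t, df, tail),
    )


@lru_cache(maxsize=None)
def _ranksum_counts(n1: int, n2: int) -> np.ndarray:
    """Number of ways to choose n1 of the ranks 1..n1+n2 with each rank sum.

    ``counts[s]`` is the number of n1-subsets of {1..N} whose rank sum is s.
    Classic 0/1-knapsack dynamic programme, exact in integer arithmetic.
    """
    N = n1 + n2
    max_s = n1 * (2 * N - n1 + 1) // 2  # sum of the n1 largest ranks
    dp = np.zeros((n1 + 1, max_s + 1), dtype=object)
    dp[0, 0] = 1
    for r in range(1, N + 1):
        for k in range(min(n1, r), 0, -1):
            row = dp[k - 1, : max_s + 1 - r]
            dp[k, r:] = dp[k, r:] + row
    return dp[n1]


def _exact_u_pvalue(u: float, n1: int, n2: int, tail: str) -> float:
    """Exact Mann-Whitney p from the DP null distribution (no ties)."""
    counts = _ranksum_counts(n1, n2)
    base = n1 * (n1 + 1) // 2
    # U = ranksum - n1(n1+1)/2, support 0 .. n1*n2
    u_counts = counts[base : base + n1 * n2 + 1]
    total = int(sum(u_counts))
    lo = int(math.floor(u + 1e-9))
    hi = int(math.ceil(u - 1e-9))
    p_le = int(sum(u_counts[: lo + 1])) / total
    p_ge = int(sum(u_counts[hi:])) / total
    if tail == "one":
        return float(min(p_ge, 1.0))
    return float(min(2 * min(p_le, p_ge), 1.0))


def _normal_approx_pvalue(
    u: float, n1: int, n2: int, tail: str, continuity: bool, tie_term: float = 0.0
) -> float:
    """Normal approximation to the Mann-Whitney null, with tie correction.

    ``tie_term`` is sum(t^3 - t) over tie group sizes in the pooled sample.
    """
    N = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        raise DegenerateDataError("all observations identical: rank variance is zero")
    sd = math.sqrt(var)
    d = u - mu
    if continuity:
        d = d - 0.5 * np.sign(d) if d != 0 else 0.0
    z = d / sd
    if tail == "one":
        return float(sps.norm.sf(z))
    return float(min(2 * sps.norm.sf(abs(z)), 1.0))


def p_from_W(W: float, n1: int, n2: int, method: str = "normal_approx",
             continuity: bool = True, tail: str = "two") -> float:
    """p-value from a Mann-Whitney W (= U of the first group) without the data.

    Assumes no ties.  ``method`` is ``"normal_approx"`` or ``"exact"``.
    """
    if not (n1 >= 1 and n2 >= 1):
        raise InvalidParameterError("group sizes must be >= 1")
    if not 0 <= W <= n1 * n2:
        raise InvalidParameterError(f"W must lie in [0, {n1 * n2}]")
    if method == "exact":
        return _exact_u_pvalue(W, n1, n2, tail)
    if method == "normal_approx":
        return _normal_approx_pvalue(W, n1, n2, tail, continuity)
    raise InvalidParameterError(f"unknown method {method!r}")


#: exact Mann-Whitney is used automatically up to this pooled sample size
EXACT_MW_MAX_N = 50


def mann_whitney(x: SampleGroup, y: SampleGroup, method: str = "auto",
                 continuity: bool = True, tail: str = "two") -> TestResult:
    """Mann-Whitney rank test; W is the U statistic of the first group.

    ``method="auto"`` uses the exact DP distribution when n1+n2 <= 50 and the
    pooled sample has no ties, otherwise the tie-corrected normal
    approximation.  Requesting ``"exact"`` with ties falls back to the
    approximation with a logged warning.
    """
    pooled = np.concatenate([x.values, y.values])
    ranks = sps.rankdata(pooled)
    n1, n2 = x.n, y.n
    W = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    warnings: list[str] = []
    if method == "auto":
        method = "exact" if (n1 + n2 <= EXACT_MW_MAX_N and not has_ties) else "normal_approx"
    if method == "exact" and has_ties:
        warnings.append("ties present: exact method unavailable, using normal approximation")
        logger.warning(warnings[-1])
        method = "normal_approx"
    if method == "exact":
        p = _exact_u_pvalue(W, n1, n2, tail)
    else:
        p = _normal_approx_pvalue(W, n1, n2, tail, continuity, tie_term)
    return TestResult(
        test="mann_whitney", statistic_symbol="W", statistic=W, df=None, tail=tail,
        transform="none", p=p, audit={"method": method, "ties": has_ties},
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# k-sample tests
# ---------------------------------------------------------------------------


def kruskal_wallis(groups: Sequence[SampleGroup]) -> TestResult:
    """Kruskal-Wallis rank test with tie correction; p from chi-square (k-1 df)."""
    if len(groups) < 2:
        raise InvalidParameterError("Kruskal-Wallis needs >= 2 groups")
    pooled = np.concatenate([g.values for g in groups])
    if np.ptp(pooled) == 0:
        return TestResult(
            test="kruskal_wallis", statistic_symbol="K", statistic=0.0, df=None,
            tail="two", transform="none", p=1.0,
            warnings=["all observations identical: test undefined, p set to 1"],
        )
    K, p = sps.kruskal(*[g.values for g in groups])
    return TestResult(
        test="kruskal_wallis", statistic_symbol="K", statistic=float(K), df=None,
        tail="two", transform="none", p=float(p),
        audit={"k_groups": len(groups)},
    )


def _letter_display(labels: Sequence[str], means: Sequence[float],
                    p_matrix: np.ndarray, alpha: float = 0.05) -> dict:
    """Compact letter display from a pairwise adjusted-p matrix.

    Groups sharing a letter are not significantly different.  Letters are the
    maximal cliques of the non-significance graph, ordered by group mean.
    """
    k = len(labels)
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if p_matrix[i, j] > alpha:
                g.add_edge(i, j)
    cliques = sorted(
        (sorted(c) for c in nx.find_cliques(g)),
        key=lambda c: (min(means[i] for i in c), c),
    )
    letters: dict[str, str] = {lab: "" for lab in labels}
    for letter_idx, clique in enumerate(cliques):
        letter = chr(ord("a") + letter_idx)
        for i in clique:
            letters[labels[i]] += letter
    return {lab: "".join(sorted(v)) for lab, v in letters.items()}


def anova_tukey(groups: Sequence[SampleGroup], tukey_alpha: float = 0.05,
                transform_label: str = "none") -> TestResult:
    """One-way ANOVA with Tukey HSD post-hoc and a letter-grouping display.

    The F statistic carries (k-1, N-k) degrees of freedom; Tukey adjusted
    p-values come from the studentized range distribution.
    """
    if len(groups) < 3:
        raise InvalidParameterError("anova_tukey expects >= 3 groups")
    if any(g.n < 2 for g in groups):
        raise InvalidParameterError("each group needs n >= 2")
    pooled = np.concatenate([g.values for g in groups])
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all observations identical: F undefined")
    k = len(groups)
    N = pooled.size
    F, p = sps.f_oneway(*[g.values for g in groups])
    hsd = sps.tukey_hsd(*[g.values for g in groups])
    labels = [g.label for g in groups]
    means = [float(g.values.mean()) for g in groups]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            rows.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "mean_diff": means[i] - means[j],
                    "p_adj": float(hsd.pvalue[i, j]),
                }
            )
    posthoc = pd.DataFrame(rows)
    letters = _letter_display(labels, means, np.asarray(hsd.pvalue), alpha=tukey_alpha)
    return TestResult(
        test="anova_tukey", statistic_symbol="F", statistic=float(F),
        df=(float(k - 1), float(N - k)), tail="two", transform=transform_label,
        p=float(p), posthoc=posthoc, letters=letters,
    )


def fisher_exact(table: ContingencyTable, tail: str = "two") -> TestResult:
    """Fisher exact test on a 2x2 table.

    Two-tailed p sums the hypergeometric probabilities of all tables at most
    as likely as the observed one (the minimum-likelihood rule).
    """
    counts = table.counts
    if counts.shape != (2, 2):
        raise InvalidParameterError("fisher_exact requires a 2x2 table")
    alternative = "two-sided" if tail == "two" else "greater"
    odds, p = sps.fisher_exact(counts, alternative=alternative)
    return TestResult(
        test="fisher_exact", statistic_symbol="OR",
        statistic=float(odds) if np.isfinite(odds) else math.inf,
        df=None, tail=tail, transform="none", p=float(p),
    )


# ---------------------------------------------------------------------------
# the decision tree
# ---------------------------------------------------------------------------


def choose_and_run(groups: Sequence[SampleGroup], tail: str = "two",
                   alpha_gate: float = GATE_ALPHA) -> TestResult:
    """Gate-and-dispatch group comparison.

    1. Shapiro-Wilk per group at ``alpha_gate``; if any group fails, attempt a
       log10 then a Box-Cox transform (single ML lambda fitted on the pooled
       sample) and re-test.
    2. If normal (possibly after transform): variance gate — variance-ratio F
       test for two groups, Bartlett for more.  Two homoscedastic groups get
       Student t, two heteroscedastic groups Welch t, three or more
       homoscedastic groups one-way ANOVA + Tukey HSD (a failed Bartlett gate
       with >2 groups falls back to Kruskal-Wallis).
    3. Not normal after transforms: Mann-Whitney (2 groups) or Kruskal-Wallis.

    Any group with n < 3 forces the nonparametric branch with a logged
    warning (the normality gate cannot be evaluated).  The full audit trail —
    gate p-values, the transform chosen, the decision path — is recorded on
    the result.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise InvalidParameterError("need at least two groups")
    audit: dict = {"alpha_gate": alpha_gate, "decision_path": []}
    warnings: list[str] = []

    def _nonparametric(note: str) -> TestResult:
        audit["decision_path"].append(note)
        if len(groups) == 2:
            res = mann_whitney(groups[0], groups[1], tail=tail)
        else:
            res = kruskal_wallis(groups)
        res.audit = {**audit, **res.audit}
        res.warnings = warnings + res.warnings
        return res

    if any(g.n < 3 for g in groups):
        small = [g.label for g in groups if g.n < 3]
        warnings.append(f"groups {small} have n < 3: normality gate skipped")
        logger.warning(warnings[-1])
        return _nonparametric("n<3 -> nonparametric")

    chosen: Optional[TransformResult] = None
    transformed: list[SampleGroup] = groups
    normal = False
    for kind in ("none", "log10", "boxcox"):
        pooled = np.concatenate([g.values for g in groups])
        if kind != "none" and np.any(pooled <= 0):
            audit["decision_path"].append(f"{kind} skipped (non-positive values)")
            continue
        if kind == "boxcox":
            fitted = transform(pooled, "boxcox")
            lmbda = fitted.lmbda
            cand = [
                SampleGroup(g.label, transform(g.values, "boxcox", lmbda=lmbda).values)
                for g in groups
            ]
            label = fitted.label
        elif kind == "log10":
            cand = [SampleGroup(g.label, transform(g.values, "log10").values) for g in groups]
            label = "log10"
        else:
            cand = groups
            label = "none"
        try:
            sw = {g.label: shapiro_wilk(g.values) for g in cand}
        except DegenerateDataError:
            audit["decision_path"].append(f"{kind}: constant group, gate undefined")
            continue
        audit.setdefault("shapiro", {})[label] = sw
        if all(p > alpha_gate for p in sw.values()):
            normal = True
            transformed = cand
            chosen = TransformResult(values=np.empty(0), kind=kind,
                                     lmbda=lmbda if kind == "boxcox" else None)
            audit["transform"] = label
            audit["decision_path"].append(f"normal under transform '{label}'")
            break
        audit["decision_path"].append(f"normality rejected under '{label}'")

    if not normal:
        return _nonparametric("non-normal after transforms -> nonparametric")

    tlabel = chosen.label if chosen else "none"
    if len(transformed) == 2:
        try:
            fstat, fdf, fp = fisher_variance_test(transformed[0].values, transformed[1].values)
        except DegenerateDataError:
            return _nonparametric("zero variance in both groups -> nonparametric")
        audit["variance_gate"] = {"test": "fisher_F", "statistic": fstat, "df": list(fdf), "p": fp}
        if fp > alpha_gate:
            audit["decision_path"].append("homoscedastic -> student_t")
            res = student_t_test(transformed[0], transformed[1], tail=tail, transform_label=tlabel)
        else:
            audit["decision_path"].append("heteroscedastic -> welch_t")
            res = welch_t_test(transformed[0], transformed[1], tail=tail, transform_label=tlabel)
    else:
        bstat, bp = sps.bartlett(*[g.values for g in transformed])
        audit["variance_gate"] = {"test": "bartlett", "statistic": float(bstat), "p": float(bp)}
        if bp > alpha_gate:
            audit["decision_path"].append("homoscedastic -> anova_tukey")
            res = anova_tukey(transformed, transform_label=tlabel)
        else:
            warnings.append("variance heterogeneity with >2 groups: nonparametric fallback")
            return _nonparametric("heteroscedastic >2 groups -> kruskal_wallis")
    res.audit = {**audit, **res.audit}
    res.warnings = warnings + res.warnings
    return res


#: forced-test registry used by the command-line interface
TEST_REGISTRY = {
    "student_t": lambda groups, tail: student_t_test(groups[0], groups[1], tail=tail),
    "welch_t": lambda groups, tail: welch_t_test(groups[0], groups[1], tail=tail),
    "mann_whitney": lambda groups, tail: mann_whitney(groups[0], groups[1], tail=tail),
    "anova_tukey": lambda groups, tail: anova_tukey(groups),
    "kruskal_wallis": lambda groups, tail: kruskal_wallis(groups),
}
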