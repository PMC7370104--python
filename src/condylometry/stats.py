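"""Nonparametric comparison and reliability statistics for volumetric
readings of condylar models.

The battery mirrors common practice for multi-software segmentation
studies: a distributional gate (Shapiro–Wilk per group + Levene across
groups) decides parametric vs nonparametric; group differences use
Kruskal–Wallis with Mann–Whitney U post-hocs; paired readings use the
Wilcoxon signed-rank test; and test–retest / between-rater reliability
uses intraclass correlation coefficients from a two-way ANOVA
decomposition (ICC(3,1) consistency for intra-operator, ICC(2,1)
absolute agreement for inter-operator).

Rank statistics use midranks throughout; Mann–Whitney and Wilcoxon
p-values are exact by full enumeration for small samples (limits below)
and normal approximations with tie and continuity corrections otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ICCResult",
    "normality_gate",
    "kruskal_wallis",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "icc",
    "compare_software_volumes",
]

ALPHA = 0.05
#: combined-sample limit below which Mann–Whitney p is fully enumerated
MWU_EXACT_LIMIT = 10
#: pair-count limit below which the signed-rank p is fully enumerated
WILCOXON_EXACT_LIMIT = 14


@dataclass
class TestResult:
    """One hypothesis-test outcome."""

    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    direction: int = 0  # sign of the effect where meaningful
    note: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


# ---------------------------------------------------------------------------
# distributional gate
# ---------------------------------------------------------------------------


def normality_gate(
    groups: list[np.ndarray], alpha: float = ALPHA
) -> tuple[str, list[TestResult]]:
    """Decide parametric vs nonparametric analysis.

    Shapiro–Wilk runs per group and Levene across groups; the decision is
    ``"nonparametric"`` when any Shapiro p or the Levene p falls below
    ``alpha``.  A constant group makes Shapiro undefined and forces the
    nonparametric branch with a note.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(len(g) < 3 for g in groups):
        raise ValueError("normality gate needs >=3 observations per group")
    results: list[TestResult] = []
    nonparametric = False
    for i, g in enumerate(groups):
        if np.ptp(g) == 0:
            results.append(
                TestResult(
                    "shapiro-wilk", np.nan, np.nan, (len(g),),
                    note=f"group {i}: constant sample, normality undefined",
                )
            )
            nonparametric = True
            continue
        stat, p = sps.shapiro(g)
        results.append(TestResult("shapiro-wilk", float(stat), float(p), (len(g),)))
        if p < alpha:
            nonparametric = True
    if len(groups) >= 2:
        stat, p = sps.levene(*groups)
        results.append(
            TestResult(
                "levene", float(stat), float(p), tuple(len(g) for g in groups)
            )
        )
        if p < alpha:
            nonparametric = True
    return ("nonparametric" if nonparametric else "parametric"), results


# ---------------------------------------------------------------------------
# Kruskal–Wallis
# ---------------------------------------------------------------------------


def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal–Wallis H with midranks and tie correction; p from the
    chi-square approximation with k−1 degrees of freedom."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 observations each")
    ns = [len(g) for g in groups]
    n = sum(ns)
    pooled = np.concatenate(groups)
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for g, ni in zip(groups, ns):
        r = ranks[start : start + ni]
        h += r.sum() ** 2 / ni
        start += ni
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if correction == 0.0:  # all observations identical
        return TestResult("kruskal-wallis", 0.0, 1.0, tuple(ns))
    h /= correction
    df = len(groups) - 1
    p = float(sps.chi2.sf(h, df))
    return TestResult("kruskal-wallis", float(h), p, tuple(ns))


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------


def _mwu_statistic(a: np.ndarray, b: np.ndarray) -> float:
    ranks = _midranks(np.concatenate([a, b]))
    r1 = ranks[: len(a)].sum()
    return r1 - len(a) * (len(a) + 1) / 2.0


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided Mann–Whitney U.

    For combined samples of at most ``MWU_EXACT_LIMIT`` the p-value is
    exact: every split of the pooled midranks is enumerated, which stays
    valid under ties.  Larger samples use the normal approximation with
    tie and continuity corrections.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    u1 = _mwu_statistic(a, b)
    u2 = n1 * n2 - u1
    direction = int(np.sign(u1 - n1 * n2 / 2.0))

    if n1 + n2 <= MWU_EXACT_LIMIT:
        pooled = np.concatenate([a, b])
        ranks = _midranks(pooled)
        offset = n1 * (n1 + 1) / 2.0
        lo, hi = min(u1, u2), max(u1, u2)
        count = 0
        total = comb(n1 + n2, n1)
        for pick in combinations(range(n1 + n2), n1):
            u = ranks[list(pick)].sum() - offset
            if u <= lo + 1e-12 or u >= hi - 1e-12:
                count += 1
        p = count / total
        return TestResult(
            "mann-whitney-u-exact", float(u1), min(1.0, p), (n1, n2),
            direction=direction,
        )

    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    mu = n1 * n2 / 2.0
    if sigma2 <= 0:
        return TestResult(
            "mann-whitney-u", float(u1), 1.0, (n1, n2),
            note="all observations identical",
        )
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    p = float(2.0 * sps.norm.sf(max(z, 0.0)))
    return TestResult(
        "mann-whitney-u", float(u1), min(1.0, p), (n1, n2), direction=direction
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(first: np.ndarray, second: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired readings.

    Zero differences are dropped (noted in the result).  For at most
    ``WILCOXON_EXACT_LIMIT`` non-zero pairs all 2^n sign assignments of
    the midranked |differences| are enumerated (exact under ties);
    otherwise the normal approximation with tie and continuity
    corrections is used.
    """
    first = np.asarray(first, dtype=np.float64)
    second = np.asarray(second, dtype=np.float64)
    if first.shape != second.shape:
        raise ValueError("paired samples must have equal length")
    d = second - first
    note = ""
    nz = d[d != 0]
    n_dropped = len(d) - len(nz)
    if n_dropped:
        note = f"{n_dropped} zero differences dropped"
    if len(nz) == 0:
        return TestResult(
            "wilcoxon-signed-rank", 0.0, 1.0, (len(d),),
            note="all differences zero",
        )
    ranks = _midranks(np.abs(nz))
    w_plus = ranks[nz > 0].sum()
    w_minus = ranks[nz < 0].sum()
    w = min(w_plus, w_minus)
    direction = int(np.sign(w_plus - w_minus))
    n = len(nz)

    if n <= WILCOXON_EXACT_LIMIT:
        total_rank = ranks.sum()
        lo, hi = min(w_plus, w_minus), max(w_plus, w_minus)
        count = 0
        for signs in range(1 << n):
            wp = 0.0
            for i in range(n):
                if signs >> i & 1:
                    wp += ranks[i]
            if wp <= lo + 1e-12 or wp >= hi - 1e-12:
                count += 1
        p = count / (1 << n)
        return TestResult(
            "wilcoxon-signed-rank-exact", float(w), min(1.0, p), (n,),
            direction=direction, note=note,
        )

    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(nz), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        counts**3 - counts
    ) / 48.0
    z = (abs(w_plus - mu) - 0.5) / np.sqrt(sigma2)
    p = float(2.0 * sps.norm.sf(max(z, 0.0)))
    return TestResult(
        "wilcoxon-signed-rank", float(w), min(1.0, p), (n,),
        direction=direction, note=note,
    )


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------


@dataclass
class ICCResult:
    """Single-measure intraclass correlation with its ANOVA components."""

    design: str
    form: str
    value: float
    ms_rows: float  # between-condyle mean square
    ms_cols: float  # between-reading mean square
    ms_error: float
    n_subjects: int
    n_readings: int


def _icc_from_matrix(data: np.ndarray, design: str) -> ICCResult:
    n, k = data.shape
    data = data - data.mean()  # centering: conditioning only, no effect on MS
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_error = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))
    if ms_rows <= 0 or np.isclose(ms_rows, 0.0):
        raise ValueError(
            "ICC undefined: no between-condyle variance "
            "(all subjects read identically)"
        )
    if design == "intra":
        # two-way mixed, consistency, single measure: ICC(3,1)
        value = (ms_rows - ms_error) / (ms_rows + (k - 1) * ms_error)
        form = "ICC(3,1)"
    elif design == "inter":
        # two-way random, absolute agreement, single measure: ICC(2,1)
        value = (ms_rows - ms_error) / (
            ms_rows
            + (k - 1) * ms_error
            + k * (ms_cols - ms_error) / n
        )
        form = "ICC(2,1)"
    else:
        raise ValueError("design must be 'intra' or 'inter'")
    return ICCResult(
        design=design,
        form=form,
        value=float(value),
        ms_rows=float(ms_rows),
        ms_cols=float(ms_cols),
        ms_error=float(ms_error),
        n_subjects=n,
        n_readings=k,
    )


def icc(table: pd.DataFrame, design: str) -> ICCResult:
    """Reliability of repeated volumetric readings.

    ``table`` is long format with columns ``condyle``, ``value`` and
    either ``occasion`` (design='intra': readings of one rater, ICC(3,1)
    consistency) or ``rater`` (design='inter': first reading of each
    rater, ICC(2,1) absolute agreement).  Requires two or more readings
    per condyle and at least three condyles.
    """
    if design == "intra":
        sub = table
        if "rater" in table.columns and table["rater"].nunique() > 1:
            sub = table[table["rater"] == table["rater"].min()]
        wide = sub.pivot_table(
            index="condyle", columns="occasion", values="value"
        )
    elif design == "inter":
        sub = table
        if "occasion" in table.columns and table["occasion"].nunique() > 1:
            sub = table[table["occasion"] == table["occasion"].min()]
        wide = sub.pivot_table(index="condyle", columns="rater", values="value")
    else:
        raise ValueError("design must be 'intra' or 'inter'")
    if wide.isna().any().any():
        raise ValueError("rating table has missing cells")
    data = wide.to_numpy(dtype=np.float64)
    if data.shape[0] < 3 or data.shape[1] < 2:
        raise ValueError(
            f"need >=3 condyles and >=2 readings, have {data.shape}"
        )
    return _icc_from_matrix(data, design)


# ---------------------------------------------------------------------------
# full group comparison
# ---------------------------------------------------------------------------


def compare_software_volumes(
    groups: dict[str, np.ndarray],
    alpha: float = ALPHA,
    bootstrap_seed: int = 0,
    n_bootstrap: int = 2000,
) -> dict:
    """Compare condylar volumes (or matching percentages) across
    segmentation methods.

    Runs the distributional gate, then Kruskal–Wallis; when significant,
    all pairwise Mann–Whitney post-hocs with raw and Bonferroni-adjusted
    p-values plus compact-letter-style labels listing, for each method,
    the methods it differs from.  Group medians, bootstrap standard
    errors of the median, and ranges are always reported.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=np.float64) for n in names]
    decision, gate_results = normality_gate(arrays, alpha=alpha)
    kw = kruskal_wallis(arrays)
    rng = np.random.default_rng(bootstrap_seed)
    summary = {}
    for name, arr in zip(names, arrays):
        boots = np.median(
            rng.choice(arr, size=(n_bootstrap, len(arr)), replace=True), axis=1
        )
        summary[name] = {
            "n": len(arr),
            "median": float(np.median(arr)),
            "se_median": float(boots.std(ddof=1)),
            "min": float(arr.min()),
            "max": float(arr.max()),
        }
    posthoc = []
    letters: dict[str, list[str]] = {n: [] for n in names}
    if kw.p_value < alpha:
        pairs = list(combinations(range(len(names)), 2))
        m = len(pairs)
        for i, j in pairs:
            res = mann_whitney_u(arrays[i], arrays[j])
            adj = min(1.0, res.p_value * m)
            posthoc.append(
                {
                    "a": names[i],
                    "b": names[j],
                    "U": res.statistic,
                    "p_raw": res.p_value,
                    "p_bonferroni": adj,
                    "significant": adj < alpha,
                }
            )
            if adj < alpha:
                letters[names[i]].append(names[j])
                letters[names[j]].append(names[i])
    return {
        "gate_decision": decision,
        "gate_tests": gate_results,
        "kruskal_wallis": kw,
        "summary": summary,
        "posthoc": posthoc,
        "differs_from": letters,
    }
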