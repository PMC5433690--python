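"""Group-comparison statistics for LPD cohorts.

Implements the test battery used on the clinical summary table: Pearson
chi-square (uncorrected by default), two-tailed Fisher exact, pooled- and
Welch-variance t tests from raw data or from published summary statistics,
Pearson correlation, least-significant-difference (LSD) ANOVA post-hoc, and
pairwise comparison with the alpha/n multiple-comparison rule.

Method auto-selection for categorical rows follows the usual "as
appropriate" convention: Fisher exact when any expected cell count is below
5, otherwise uncorrected chi-square. This combination reproduces the
published pairwise p-values on the printed contingency tables (sex 0.002,
laterality 0.001, pain 1.00, ...); rows that no provided method reproduces
are flagged in the summary report rather than forced.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortTable, Diagnosis, PublishedCounts

__all__ = [
    "ContingencyTable",
    "TestResult",
    "SummaryStats",
    "CohortSummary",
    "chi2_test",
    "fisher_exact_test",
    "t_test_from_summary",
    "t_test_from_raw",
    "pearson_correlation",
    "anova_lsd",
    "pairwise_with_correction",
    "summarize_cohort",
    "format_p",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class SummaryStats:
    """Group summary (n, mean, sd) as printed in clinical tables."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"summary requires n >= 2, got n={self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "SummaryStats":
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError("at least two observations are required")
        return cls(n=int(arr.size), mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: float | None = None
    alpha_effective: float | None = None
    estimate: float | None = None  # e.g. Pearson r
    note: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool | None:
        if self.alpha_effective is None:
            return None
        return self.p_value < self.alpha_effective

    def with_alpha(self, alpha_effective: float) -> "TestResult":
        return TestResult(
            statistic=self.statistic,
            p_value=self.p_value,
            method=self.method,
            df=self.df,
            alpha_effective=alpha_effective,
            estimate=self.estimate,
            note=self.note,
        )


class ContingencyTable:
    """Labeled non-negative integer count matrix, at least 2x2."""

    def __init__(
        self,
        counts,
        row_labels: Sequence[str] | None = None,
        col_labels: Sequence[str] | None = None,
    ) -> None:
        arr = np.asarray(counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(f"contingency table must be at least 2x2, got shape {arr.shape}")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer) and np.any(arr != np.floor(arr)):
            raise ValueError("counts must be non-negative integers")
        self.counts = arr.astype(np.int64)
        self.row_labels = tuple(row_labels or [f"r{i}" for i in range(arr.shape[0])])
        self.col_labels = tuple(col_labels or [f"c{j}" for j in range(arr.shape[1])])

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def expected(self) -> np.ndarray:
        t = self.counts
        n = t.sum()
        if n == 0 or np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
            raise ValueError("zero margin: expected counts undefined")
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / n


def _as_table(table) -> ContingencyTable:
    return table if isinstance(table, ContingencyTable) else ContingencyTable(table)


def chi2_test(table, *, continuity_correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence.

    Uncorrected by default: on the published 2x2 tables the uncorrected
    statistic reproduces the printed p-values and the Yates-corrected one
    does not. ``continuity_correction=True`` applies Yates on 2x2 tables.
    """
    t = _as_table(table)
    if np.any(t.counts.sum(axis=1) == 0) or np.any(t.counts.sum(axis=0) == 0):
        raise ValueError(
            "zero row or column margin: chi-square is undefined; "
            "consider fisher_exact_test for sparse 2x2 tables"
        )
    stat, p, df, _ = sps.chi2_contingency(t.counts, correction=continuity_correction)
    return TestResult(statistic=float(stat), p_value=float(p), df=float(df),
                      method="pearson_chi2")


# relative tie tolerance when summing tables "as extreme as" the observed
# one; pmf values are floats, so exact equality would split true ties
_FISHER_REL_TOL = 1.0 + 1e-7


def fisher_family_p(n: int, r1: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed Fisher p for every table in one fixed-margin family.

    Given total n, first-row margin r1 and first-column margin c1, returns
    the support of the [0,0] cell and the vector of two-tailed p-values:
    for each observed cell value, the sum of hypergeometric probabilities
    not exceeding the observed one (up to a relative float tolerance for
    ties). Working family-at-a-time keeps exhaustive sweeps cheap.
    """
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    order = np.argsort(pmf)
    csum = np.cumsum(pmf[order])
    pos = np.searchsorted(pmf[order], pmf * _FISHER_REL_TOL, side="right")
    p = np.minimum(1.0, csum[np.maximum(pos - 1, 0)])
    return support, p


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    support, p = fisher_family_p(a + b + c + d, a + b, a + c)
    return float(p[a - support[0]])


def fisher_exact_test(table) -> TestResult:
    """Two-tailed Fisher exact test for a 2x2 table.

    The statistic is the sample odds ratio (inf when b*c == 0 < a*d)."""
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError(f"Fisher exact test requires a 2x2 table, got {t.shape}")
    (a, b), (c, d) = t.counts
    p = fisher_two_sided_p(int(a), int(b), int(c), int(d))
    denom = b * c
    odds = math.inf if denom == 0 and a * d > 0 else (a * d / denom if denom else math.nan)
    return TestResult(statistic=float(odds), p_value=p, method="fisher_exact")


def t_test_from_summary(
    a: SummaryStats, b: SummaryStats, variant: str = "student"
) -> TestResult:
    """Two-sided two-sample t test from group summaries.

    ``student`` pools variances (df = n_a + n_b - 2); ``welch`` uses the
    Welch-Satterthwaite approximation.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"variant must be 'student' or 'welch', got {variant!r}")
    if a.sd == 0 and b.sd == 0 and a.mean == b.mean:
        raise ValueError("all values identical in both groups: t statistic undefined")
    res = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(variant == "student")
    )
    if variant == "student":
        df = a.n + b.n - 2
    else:  # Welch-Satterthwaite
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      df=float(df), method=f"{variant}_t")


def t_test_from_raw(a: Sequence[float], b: Sequence[float], variant: str = "student") -> TestResult:
    """Two-sided two-sample t test from raw values (independent code path
    from :func:`t_test_from_summary`; the two agree to floating precision)."""
    xa, xb = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each group requires n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError(f"variant must be 'student' or 'welch', got {variant!r}")
    if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa[0] == xb[0]:
        raise ValueError("all values identical in both groups: t statistic undefined")
    res = sps.ttest_ind(xa, xb, equal_var=(variant == "student"))
    df = xa.size + xb.size - 2 if variant == "student" else float(res.df)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      df=float(df), method=f"{variant}_t")


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with the two-sided t-transform p (df = n - 2)."""
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(xa, ya)
    r = float(res.statistic)
    df = xa.size - 2
    t = r * math.sqrt(df / max(1e-300, 1 - r * r)) if abs(r) < 1 else math.inf
    return TestResult(statistic=t, p_value=float(res.pvalue), df=float(df),
                      method="pearson_correlation", estimate=r)


def anova_lsd(groups: Mapping[str, SummaryStats]) -> dict:
    """One-way ANOVA from summaries plus Fisher-LSD pairwise post-hoc.

    LSD compares each pair with a pooled-t using the ANOVA residual mean
    square and its df, as classical statistical packages do.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    labels = list(groups)
    ns = np.array([groups[g].n for g in labels], dtype=float)
    means = np.array([groups[g].mean for g in labels])
    sds = np.array([groups[g].sd for g in labels])
    N, k = ns.sum(), len(labels)
    sse = float(np.sum((ns - 1) * sds**2))
    mse = sse / (N - k)
    grand = float(np.sum(ns * means) / N)
    ssb = float(np.sum(ns * (means - grand) ** 2))
    f = (ssb / (k - 1)) / mse
    p = float(sps.f.sf(f, k - 1, N - k))
    overall = TestResult(statistic=f, p_value=p, df=float(k - 1), method="anova_lsd")
    pairwise: dict[tuple[str, str], TestResult] = {}
    for g1, g2 in itertools.combinations(labels, 2):
        a, b = groups[g1], groups[g2]
        se = math.sqrt(mse * (1 / a.n + 1 / b.n))
        t = (a.mean - b.mean) / se
        pairwise[(g1, g2)] = TestResult(
            statistic=t, p_value=float(2 * sps.t.sf(abs(t), N - k)),
            df=float(N - k), method="anova_lsd",
        )
    return {"overall": overall, "pairwise": pairwise}


def pairwise_with_correction(
    groups: Mapping[str, object],
    test: Callable[[object, object], TestResult],
    alpha: float = DEFAULT_ALPHA,
) -> dict[tuple[str, str], TestResult]:
    """All pairwise comparisons with the alpha/n multiple-comparison rule.

    ``alpha_effective = alpha / C(k, 2)``; for three groups that is alpha/3.
    Each returned result carries the effective level and its significance
    flag is evaluated against it, never against raw alpha.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("pairwise comparison requires at least two groups")
    pairs = list(itertools.combinations(labels, 2))
    alpha_eff = alpha / len(pairs)
    return {
        (g1, g2): test(groups[g1], groups[g2]).with_alpha(alpha_eff)
        for g1, g2 in pairs
    }


def format_p(p: float) -> str:
    """Publication-style p formatting: three decimals, '< 0.001' below 0.0005."""
    if p < 0.0005:
        return "< 0.001"
    return f"{p:.3f}"


def _printed_matches(printed: str, p: float) -> bool:
    printed = printed.strip()
    if printed.startswith("<"):
        return p < float(printed.lstrip("< "))
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    return round(p, decimals) == float(printed)


# ---------------------------------------------------------------------------
# Cohort summarization (clinical-features table reproduction)
# ---------------------------------------------------------------------------


@dataclass
class CohortSummary:
    """Clinical-features summary: per-group n, per-category counts and
    percentages, age summaries, and overall plus pairwise test results."""

    groups: tuple[Diagnosis, ...]
    n: dict[Diagnosis, int]
    counts: dict[str, dict[str, dict[Diagnosis, int]]]  # variable -> category -> group -> count
    age: dict[Diagnosis, SummaryStats]
    age_range: dict[Diagnosis, tuple[float, float] | None]
    overall_counts: dict[str, int]
    tests: dict[str, dict] = field(default_factory=dict)  # variable -> {"overall": TestResult, "pairwise": {...}}
    flags: list[str] = field(default_factory=list)
    alpha: float = DEFAULT_ALPHA

    def group_n(self, group: Diagnosis | str) -> int:
        return self.n[Diagnosis(group)]

    @property
    def total_n(self) -> int:
        return sum(self.n.values())

    def count(self, group: Diagnosis | str, variable: str, category: str) -> int:
        return self.counts[variable][category][Diagnosis(group)]

    def percent(self, group: Diagnosis | str, variable: str, category: str) -> float:
        g = Diagnosis(group)
        return 100.0 * self.count(g, variable, category) / self.n[g]

    def overall_percent(self, key: str) -> float:
        return 100.0 * self.overall_counts[key] / self.total_n

    def p_value(self, variable: str, comparison: str = "overall") -> float | None:
        t = self.tests.get(variable)
        if t is None:
            return None
        if comparison == "overall":
            r = t.get("overall")
            return None if r is None else r.p_value
        for (g1, g2), r in t.get("pairwise", {}).items():
            if {g1, g2} == set(comparison.split("&")):
                return r.p_value
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for variable, cats in self.counts.items():
            for category, per_group in cats.items():
                row: dict[str, object] = {"variable": variable, "category": category}
                for g in self.groups:
                    c = per_group[g]
                    row[g.value] = f"{c} ({100.0 * c / self.n[g]:.2f})"
                t = self.tests.get(variable, {})
                row["P"] = format_p(t["overall"].p_value) if t.get("overall") else ""
                for (g1, g2), r in t.get("pairwise", {}).items():
                    row[f"P_{g1}&{g2}"] = format_p(r.p_value)
                rows.append(row)
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = ["Clinical features summary"]
        lines.append(
            "Groups: " + ", ".join(f"{g.value} (n={self.n[g]})" for g in self.groups)
        )
        t = self.tests.get("age", {})
        if self.age:
            parts = [
                f"{g.value} {self.age[g].mean:.2f} +/- {self.age[g].sd:.2f}"
                for g in self.groups if g in self.age
            ]
            line = "Age (years): " + "; ".join(parts)
            if t.get("overall"):
                line += f"  P={format_p(t['overall'].p_value)}"
            lines.append(line)
        frame = self.to_frame()
        if len(frame):
            lines.append(frame.to_string(index=False))
        for key, cnt in self.overall_counts.items():
            lines.append(f"Overall {key}: {cnt}/{self.total_n} ({self.overall_percent(key):.1f}%)")
        for flag in self.flags:
            lines.append(f"NOTE: {flag}")
        return "\n".join(lines)


def _select_2x2_test(table: np.ndarray, continuity_correction: bool) -> TestResult:
    ct = ContingencyTable(table)
    try:
        expected = ct.expected()
    except ValueError:
        return fisher_exact_test(ct)
    if table.shape == (2, 2) and np.any(expected < 5):
        return fisher_exact_test(ct)
    return chi2_test(ct, continuity_correction=continuity_correction)


def _counts_from_cohort(table: CohortTable) -> tuple[dict, dict, dict, dict]:
    frame = table.frame
    diag = frame["diagnosis"].map(lambda d: Diagnosis(str(d)))
    groups = [g for g in Diagnosis if (diag == g).any()]
    n = {g: int((diag == g).sum()) for g in groups}

    counts: dict[str, dict[str, dict[Diagnosis, int]]] = {}
    counts["sex"] = {
        cat: {g: int(((diag == g) & (frame["sex"] == cat)).sum()) for g in groups}
        for cat in ("female", "male")
    }
    counts["laterality"] = {
        cat: {g: int(((diag == g) & (frame["laterality"] == cat)).sum()) for g in groups}
        for cat in ("unilateral", "bilateral")
    }
    site_tokens = frame["sites"].astype(str).str.split(";")
    symptom_tokens = frame["symptoms"].astype(str).str.split(";")
    from .cohort import Site, Symptom

    for var_enum, toks, key in ((Site, site_tokens, "site"), (Symptom, symptom_tokens, "symptom")):
        for member in var_enum:
            has = toks.map(lambda ts: member.value in ts)
            counts[member.value] = {
                "present": {g: int(((diag == g) & has).sum()) for g in groups},
                "absent": {g: int(((diag == g) & ~has).sum()) for g in groups},
            }

    age = {
        g: SummaryStats.from_values(
            pd.to_numeric(frame.loc[diag == g, "age"]).to_numpy()
        )
        for g in groups
        if n[g] >= 2
    }
    age_range = {
        g: (
            float(pd.to_numeric(frame.loc[diag == g, "age"]).min()),
            float(pd.to_numeric(frame.loc[diag == g, "age"]).max()),
        )
        for g in groups
    }
    overall = {
        "orbital_soft_tissue_any": int(site_tokens.map(lambda ts: "orbital_soft_tissue" in ts).sum()),
        "multi_compartment": int(site_tokens.map(lambda ts: len([t for t in ts if t]) >= 2).sum()),
    }
    return {g: n[g] for g in groups}, counts, (age, age_range), overall


def _counts_from_fixture(fx: PublishedCounts) -> tuple[dict, dict, dict, dict]:
    groups = list(fx.groups)
    n = {g: fx.group_n(g) for g in groups}
    counts: dict[str, dict[str, dict[Diagnosis, int]]] = {}
    variables = fx.variables()
    counts["sex"] = {
        cat: {g: fx.count(g, sex=cat) for g in groups} for cat in variables["sex"]
    }
    counts["laterality"] = {
        cat: {g: fx.count(g, laterality=cat) for g in groups}
        for cat in variables["laterality"]
    }
    for site in variables["sites"]:
        counts[site] = {
            "present": {g: fx.count(g, site=site) for g in groups},
            "absent": {g: n[g] - fx.count(g, site=site) for g in groups},
        }
    for sym in variables["symptoms"]:
        counts[sym] = {
            "present": {g: fx.count(g, symptom=sym) for g in groups},
            "absent": {g: n[g] - fx.count(g, symptom=sym) for g in groups},
        }
    age = {
        g: SummaryStats(n=n[g], mean=fx.age_summary(g)["mean"], sd=fx.age_summary(g)["sd"])
        for g in groups
    }
    age_range = {
        g: (fx.age_summary(g)["min"], fx.age_summary(g)["max"]) for g in groups
    }
    overall = {
        "orbital_soft_tissue_any": fx.overall_count("orbital_soft_tissue_any"),
        "multi_compartment": fx.overall_count("multi_compartment"),
    }
    return n, counts, (age, age_range), overall


def summarize_cohort(
    source: CohortTable | PublishedCounts,
    *,
    alpha: float = DEFAULT_ALPHA,
    continuity_correction: bool = False,
    t_variant: str = "student",
) -> CohortSummary:
    """Build the clinical-features summary with overall and pairwise tests.

    Accepts either a per-patient cohort or the packaged printed-count
    fixture. Categorical rows use uncorrected chi-square, switching to
    two-tailed Fisher exact on 2x2 tables with any expected cell < 5; age
    uses the overall one-way ANOVA plus pairwise t tests ("student" pools
    variances). Pairwise results carry alpha/N_pairs as effective level.
    When the fixture's transcribed published p-values disagree with the
    recomputed ones, the rows are flagged, never altered.
    """
    if isinstance(source, PublishedCounts):
        n, counts, (age, age_range), overall = _counts_from_fixture(source)
        fx: PublishedCounts | None = source
    else:
        n, counts, (age, age_range), overall = _counts_from_cohort(source)
        fx = None
    groups = tuple(n.keys())

    summary = CohortSummary(
        groups=groups, n=n, counts=counts, age=age, age_range=age_range,
        overall_counts=overall, alpha=alpha,
    )

    if len(groups) < 2:
        summary.flags.append("single-group cohort: significance tests skipped")
        return summary

    n_pairs = math.comb(len(groups), 2)
    alpha_eff = alpha / n_pairs if n_pairs > 1 else alpha

    # categorical variables
    for variable, cats in counts.items():
        cat_names = list(cats)
        mat = np.array(
            [[cats[c][g] for c in cat_names] for g in groups], dtype=int
        )
        entry: dict[str, object] = {}
        if np.all(mat.sum(axis=1) > 0) and np.all(mat.sum(axis=0) > 0):
            entry["overall"] = chi2_test(mat, continuity_correction=continuity_correction)
        else:
            entry["overall"] = None
            summary.flags.append(
                f"{variable}: zero margin in the overall table; chi-square skipped"
            )
        pw: dict[tuple[str, str], TestResult] = {}
        for g1, g2 in itertools.combinations(groups, 2):
            sub = np.array(
                [[cats[c][g1] for c in cat_names], [cats[c][g2] for c in cat_names]]
            )
            try:
                r = _select_2x2_test(sub, continuity_correction)
            except ValueError as exc:
                summary.flags.append(f"{variable} {g1.value}&{g2.value}: {exc}")
                continue
            pw[(g1.value, g2.value)] = r.with_alpha(alpha_eff)
        entry["pairwise"] = pw
        summary.tests[variable] = entry

    # age: overall ANOVA + pairwise t from summaries
    if len(age) == len(groups) and len(groups) >= 2:
        labeled = {g.value: age[g] for g in groups}
        if len(groups) > 2:
            overall_age = anova_lsd(labeled)["overall"]
        else:
            overall_age = t_test_from_summary(*labeled.values(), variant=t_variant)
        pw_age = pairwise_with_correction(
            labeled, lambda a, b: t_test_from_summary(a, b, variant=t_variant), alpha=alpha
        )
        summary.tests["age"] = {"overall": overall_age, "pairwise": pw_age}

    # compare against transcribed published p-values, flag mismatches
    if fx is not None:
        for variable, entry in summary.tests.items():
            printed = fx.printed_p(variable, "overall")
            r = entry.get("overall")
            if printed and r is not None and not _printed_matches(printed, r.p_value):
                summary.flags.append(
                    f"{variable} overall: recomputed {format_p(r.p_value)} vs published {printed}"
                )
            for (g1, g2), rr in entry.get("pairwise", {}).items():
                printed = fx.printed_p(variable, f"{g1}&{g2}")
                if printed and not _printed_matches(printed, rr.p_value):
                    summary.flags.append(
                        f"{variable} {g1}&{g2}: recomputed {format_p(rr.p_value)} "
                        f"vs published {printed}"
                    )
    return summary
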