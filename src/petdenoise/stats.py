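"""Nonparametric comparison machinery for the five image sets.

For each quantitative metric (SUVmax, SUVpeak, liver COV) measured on all
five image sets of every subject/lesion: a Friedman omnibus test over the
related samples, then all C(5,2) = 10 pairwise Wilcoxon signed-rank tests
against a Bonferroni-corrected threshold (0.05/10 = 0.005). Reader scores
are compared per reader/category with a Kruskal-Wallis omnibus followed by
all pairwise Mann-Whitney U tests under the same correction, and image
sets are ranked by mean score. Test engines are scipy.stats; this module
fixes the conventions (two-sided throughout, zero-difference handling,
exact/approximate crossovers) and the table-shaped reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "IMAGE_SETS",
    "TestResult",
    "RelatedSamplesTable",
    "ScoreTable",
    "ComparisonReport",
    "friedman",
    "wilcoxon_signed_rank",
    "bonferroni_threshold",
    "kruskal_wallis",
    "mann_whitney_u",
    "rank_by_mean",
    "run_comparison_suite",
]

#: canonical order of the five evaluated image sets
IMAGE_SETS = ("4 min", "1.5 min", "1.5 min CNN", "1 min", "1 min CNN")


class ValidationError(ValueError):
    """Input table is incomplete; the message lists the missing cells."""


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    n: int
    method: str
    threshold: Optional[float] = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")


@dataclass
class RelatedSamplesTable:
    """Subjects/lesions (rows) x image sets (columns) measurement matrix."""

    values: np.ndarray
    columns: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column labels do not match the matrix width")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError("need at least 2 rows and 2 columns")
        if not np.isfinite(self.values).all():
            raise ValueError("missing or non-finite cells")


def friedman(table: RelatedSamplesTable) -> TestResult:
    """Friedman rank test over related samples (chi-square approximation)."""
    cols = [table.values[:, j] for j in range(table.values.shape[1])]
    if all(np.array_equal(c, cols[0]) for c in cols[1:]):
        return TestResult(0.0, 1.0, table.values.shape[0], "Friedman", degenerate=True)
    stat, p = sps.friedmanchisquare(*cols)
    return TestResult(float(stat), float(p), table.values.shape[0], "Friedman")


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; ties are mid-ranked; the exact null
    distribution is used for n <= 25 without ties, otherwise the normal
    approximation with continuity and tie corrections.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, 0, "Wilcoxon signed-rank", degenerate=True)
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    return TestResult(
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        n,
        f"Wilcoxon signed-rank ({method})",
    )


def bonferroni_threshold(alpha: float, n_groups: int) -> Tuple[float, int]:
    """Corrected per-comparison threshold for all pairwise comparisons.

    m = n_groups (n_groups - 1) / 2 comparisons; threshold = alpha / m.
    """
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    m = n_groups * (n_groups - 1) // 2
    return alpha / m, m


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test with tie correction across independent groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("groups must be non-empty")
    n = int(sum(a.size for a in arrs))
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0, n, "Kruskal-Wallis", degenerate=True)
    stat, p = sps.kruskal(*arrs)
    return TestResult(float(stat), float(p), n, "Kruskal-Wallis")


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U with mid-rank ties.

    Exact p for min(n) <= 8 without ties, tie-corrected normal
    approximation with continuity correction otherwise.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        int(a.size + b.size),
        f"Mann-Whitney U ({method})",
    )


@dataclass
class ScoreTable:
    """Per-reader, per-category image-quality scores on the 5-point scale.

    Holds either raw per-examination scores (long form) or printed
    mean/SD summaries per (reader, category, image set).
    """

    summary: pd.DataFrame  # columns: reader, category, image_set, mean [, sd]
    raw: Optional[pd.DataFrame] = None  # columns: reader, category, image_set, score

    @classmethod
    def from_means(
        cls, means: Mapping[Tuple[str, str], Mapping[str, float]]
    ) -> "ScoreTable":
        rows = [
            {"reader": r, "category": c, "image_set": s, "mean": m}
            for (r, c), per_set in means.items()
            for s, m in per_set.items()
        ]
        return cls(summary=pd.DataFrame(rows))

    def means(self, reader: str, category: str) -> Dict[str, float]:
        sub = self.summary[
            (self.summary["reader"] == reader)
            & (self.summary["category"] == category)
        ]
        return dict(zip(sub["image_set"], sub["mean"]))


def rank_by_mean(
    scores: ScoreTable,
    reader: str,
    category: str,
    image_sets: Sequence[str] = IMAGE_SETS,
) -> Tuple[List[str], bool]:
    """Image sets ordered best-first by mean score (rank 1 = highest mean).

    Ties are broken by the given label order and flagged.
    """
    means = scores.means(reader, category)
    missing = [s for s in image_sets if s not in means]
    if missing:
        raise ValueError(f"missing image sets for {reader}/{category}: {missing}")
    order = sorted(
        image_sets, key=lambda s: (-means[s], list(image_sets).index(s))
    )
    vals = [means[s] for s in image_sets]
    tied = len(set(vals)) < len(vals)
    return order, tied


@dataclass
class ComparisonReport:
    """Omnibus + pairwise tables in the conventional post-hoc reporting layout."""

    omnibus: pd.DataFrame
    pairwise: pd.DataFrame
    alpha: float
    threshold: float
    n_comparisons: int
    reader_omnibus: Optional[pd.DataFrame] = None
    reader_pairwise: Optional[pd.DataFrame] = None

    def summary(self) -> str:
        lines = [
            f"alpha = {self.alpha}; {self.n_comparisons} pairwise comparisons; "
            f"Bonferroni threshold = {self.threshold:g}",
            "",
            "Omnibus (Friedman):",
            self.omnibus.to_string(index=False),
            "",
            "Pairwise (Wilcoxon signed-rank):",
            self.pairwise.to_string(index=False),
        ]
        if self.reader_pairwise is not None:
            lines += [
                "",
                "Reader scores, omnibus (Kruskal-Wallis):",
                self.reader_omnibus.to_string(index=False),
                "",
                "Reader scores, pairwise (Mann-Whitney U):",
                self.reader_pairwise.to_string(index=False),
            ]
        return "\n".join(lines)


def _pivot_complete(
    df: pd.DataFrame, value: str, index_cols: List[str], image_sets: Sequence[str]
) -> pd.DataFrame:
    sub = df.dropna(subset=[value])
    pivot = sub.pivot_table(
        index=index_cols, columns="image_set", values=value, aggfunc="first"
    )
    missing = []
    for s in image_sets:
        if s not in pivot.columns:
            missing.extend((str(i), s) for i in pivot.index)
        else:
            missing.extend((str(i), s) for i in pivot.index[pivot[s].isna()])
    if missing:
        raise ValidationError(f"incomplete image-set coverage for {value}: {missing}")
    return pivot[list(image_sets)]


def run_comparison_suite(
    metrics: pd.DataFrame,
    scores: Optional[pd.DataFrame] = None,
    alpha: float = 0.05,
    image_sets: Sequence[str] = IMAGE_SETS,
) -> ComparisonReport:
    """The full statistical battery over a tidy metrics table.

    `metrics` has columns subject, image_set, lesion, suv_max, suv_peak,
    cov (one row per subject x image set x optional lesion). Per metric:
    Friedman omnibus over the related samples, then every pairwise
    Wilcoxon signed-rank test at the Bonferroni threshold. `scores`
    (optional) has columns reader, category, image_set, score with one
    row per examination; per reader/category: Kruskal-Wallis omnibus then
    all pairwise Mann-Whitney U tests at the same threshold.
    """
    threshold, m = bonferroni_threshold(alpha, len(image_sets))
    pairs = list(combinations(image_sets, 2))

    omnibus_rows = []
    pair_rows = []
    for metric, index_cols in (
        ("suv_peak", ["subject", "lesion"]),
        ("suv_max", ["subject", "lesion"]),
        ("cov", ["subject"]),
    ):
        if metric not in metrics.columns or metrics[metric].dropna().empty:
            continue
        pivot = _pivot_complete(metrics, metric, index_cols, image_sets)
        table = RelatedSamplesTable(pivot.to_numpy(), tuple(image_sets))
        fr = friedman(table)
        omnibus_rows.append(
            {
                "metric": metric,
                "statistic": fr.statistic,
                "pvalue": fr.pvalue,
                "n": fr.n,
                "significant": fr.pvalue < alpha,
            }
        )
        for a, b in pairs:
            res = wilcoxon_signed_rank(pivot[a].to_numpy(), pivot[b].to_numpy())
            pair_rows.append(
                {
                    "metric": metric,
                    "pair": f"{a}-{b}",
                    "statistic": res.statistic,
                    "pvalue": res.pvalue,
                    "n": res.n,
                    "significant": res.pvalue < threshold,
                }
            )

    reader_omnibus = reader_pairwise = None
    if scores is not None:
        ro_rows, rp_rows = [], []
        for (reader, category), sub in scores.groupby(["reader", "category"]):
            groups = {
                s: sub.loc[sub["image_set"] == s, "score"].to_numpy()
                for s in image_sets
            }
            empty = [s for s, g in groups.items() if g.size == 0]
            if empty:
                raise ValidationError(
                    f"no scores for {reader}/{category} in image sets {empty}"
                )
            kw = kruskal_wallis([groups[s] for s in image_sets])
            ro_rows.append(
                {
                    "reader": reader,
                    "category": category,
                    "statistic": kw.statistic,
                    "pvalue": kw.pvalue,
                    "significant": kw.pvalue < alpha,
                }
            )
            for a, b in pairs:
                res = mann_whitney_u(groups[a], groups[b])
                rp_rows.append(
                    {
                        "reader": reader,
                        "category": category,
                        "pair": f"{a}-{b}",
                        "statistic": res.statistic,
                        "pvalue": res.pvalue,
                        "significant": res.pvalue < threshold,
                    }
                )
        reader_omnibus = pd.DataFrame(ro_rows)
        reader_pairwise = pd.DataFrame(rp_rows)

    return ComparisonReport(
        omnibus=pd.DataFrame(omnibus_rows),
        pairwise=pd.DataFrame(pair_rows),
        alpha=alpha,
        threshold=threshold,
        n_comparisons=m,
        reader_omnibus=reader_omnibus,
        reader_pairwise=reader_pairwise,
    )
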