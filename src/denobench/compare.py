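"""Paired statistical comparison of two denoisers.

Given per-image metric vectors (usually PSNR) for two methods, runs the
paired t-test and the exact Wilcoxon signed-rank test and emits a
significance table.  The Wilcoxon p-value is exact: the null
distribution of the signed-rank sum is obtained by enumerating all 2^n
sign assignments of the ranked absolute differences (midranks for
ties), so for n = 10 images the p-values are exact dyadic rationals such
as 2/1024 = 0.001953125.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import MetricReport

ALPHA = 0.05

#: aliases from user-facing metric names to MetricReport attributes
_METRIC_ALIASES = {
    "psnr": "psnr_db",
    "time": "elapsed_seconds",
    "time_s": "elapsed_seconds",
}


class DegenerateVarianceError(ValueError):
    """All paired differences identical: the t statistic is undefined."""


class NoInformationError(ValueError):
    """All paired differences zero: the signed-rank test is undefined."""


class PairingError(ValueError):
    """The two report lists do not cover the same image ids."""


@dataclass
class PairedComparison:
    """Result record for one method pair on one metric."""

    method_a: str
    method_b: str
    metric: str
    values_a: np.ndarray
    values_b: np.ndarray
    t_stat: float
    p_t: float
    w_stat: float
    p_w: float
    n: int
    verdict: str


def paired_t(values_a, values_b) -> tuple[float, float, int]:
    """Paired t-test: t = mean(d) / (s_d / sqrt(n)), two-sided p, df = n-1.

    ``s_d`` is the sample standard deviation of the differences
    (divisor n-1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_t needs two equal-length 1-D vectors")
    n = a.size
    if n < 2:
        raise ValueError(f"paired_t needs n >= 2, got {n}")
    d = a - b
    s_d = float(np.std(d, ddof=1))
    if s_d == 0.0:
        raise DegenerateVarianceError("all paired differences are identical")
    t = float(np.mean(d) / (s_d / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return t, p, n - 1


def signed_rank_null_sums(ranks: np.ndarray) -> np.ndarray:
    """All 2^n positive-rank sums over the sign assignments of ``ranks``.

    Iterative doubling: after processing rank r the sum multiset is the
    union of the previous multiset and the previous multiset shifted by
    r — identical to enumerating every sign configuration.
    """
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    return sums


def wilcoxon_signed_rank_exact(values_a, values_b) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test.

    Zero differences are dropped; absolute differences are ranked with
    midranks for ties; W is the smaller of the positive- and
    negative-rank sums.  The two-sided p is min(1, 2 * P(W* <= W)) with
    W* the positive-rank sum under a uniform random sign assignment,
    enumerated exhaustively for n <= 25 (normal approximation with
    continuity correction beyond that).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("wilcoxon needs two equal-length 1-D vectors")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise NoInformationError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    if n <= 25:
        sums = signed_rank_null_sums(ranks)
        count = int(np.sum(sums <= w + 1e-9))
        p = min(1.0, 2.0 * count / 2.0**n)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        z = (w - mean + 0.5) / np.sqrt(var)
        p = min(1.0, 2.0 * float(stats.norm.cdf(z)))
    return w, p


def compare_methods(
    reports_a: list[MetricReport],
    reports_b: list[MetricReport],
    metric: str = "psnr_db",
) -> PairedComparison:
    """Align two report lists by image id and run both paired tests.

    The significance verdict is taken from the exact Wilcoxon p-value at
    alpha = 0.05.
    """
    attr = _METRIC_ALIASES.get(metric, metric)
    by_id_a = {r.image_id: r for r in reports_a}
    by_id_b = {r.image_id: r for r in reports_b}
    if set(by_id_a) != set(by_id_b) or len(by_id_a) != len(reports_a):
        raise PairingError("report lists must cover the same unique image ids")
    ids = sorted(by_id_a)
    values_a = np.array([getattr(by_id_a[i], attr) for i in ids], dtype=float)
    values_b = np.array([getattr(by_id_b[i], attr) for i in ids], dtype=float)
    t_stat, p_t, _ = paired_t(values_a, values_b)
    w_stat, p_w = wilcoxon_signed_rank_exact(values_a, values_b)
    method_a = reports_a[0].method if reports_a else "A"
    method_b = reports_b[0].method if reports_b else "B"
    return PairedComparison(
        method_a=method_a,
        method_b=method_b,
        metric=metric,
        values_a=values_a,
        values_b=values_b,
        t_stat=t_stat,
        p_t=p_t,
        w_stat=w_stat,
        p_w=p_w,
        n=len(ids),
        verdict="significant" if p_w < ALPHA else "not-significant",
    )


def comparisons_to_frame(comparisons: list[PairedComparison]) -> pd.DataFrame:
    """Significance table: one row per method pair."""
    rows = [
        {
            "pair": f"{c.method_a} vs {c.method_b}",
            "t": c.t_stat,
            "p_t": c.p_t,
            "W": c.w_stat,
            "p_w": c.p_w,
            "significance": c.verdict,
        }
        for c in comparisons
    ]
    return pd.DataFrame(rows, columns=["pair", "t", "p_t", "W", "p_w", "significance"])


def write_comparison_csv(comparisons: list[PairedComparison], path) -> None:
    comparisons_to_frame(comparisons).to_csv(path, index=False)


def write_comparison_markdown(comparisons: list[PairedComparison], path) -> None:
    frame = comparisons_to_frame(comparisons)
    cells = [list(frame.columns)] + [
        [f"{v:.6g}" if isinstance(v, float) else str(v) for v in row]
        for row in frame.itertuples(index=False)
    ]
    widths = [max(len(r[c]) for r in cells) for c in range(len(cells[0]))]
    lines = [
        "| " + " | ".join(v.ljust(w) for v, w in zip(row, widths)) + " |"
        for row in cells
    ]
    lines.insert(1, "|" + "|".join("-" * (w + 2) for w in widths) + "|")
    Path(path).write_text("\n".join(lines) + "\n")
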