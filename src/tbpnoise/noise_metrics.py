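"""Expression-noise measures and the statistical comparison toolkit.

Noise of a gene across a cell population is quantified as the
coefficient of variation (CV = s.d./mean of expression) and, because CV
falls with mean abundance, as DM — the "distance from the median": the
residual of log10 CV from a running median taken over genes of similar
mean abundance.  DM is the abundance-independent noise measure used for
all between-class comparisons.

The toolkit mirrors the conventions used throughout the analysis:
two-sided Wilcoxon rank-sum tests for distribution shifts,
Benjamini-Hochberg correction across a family of tests, chi-square
goodness-of-fit for enrichment of counts, and Tukey box-plot summaries
whose outliers are flagged for display but never removed from the data.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "compute_dm",
    "rank_sum_test",
    "bh_adjust",
    "chisq_enrichment",
    "boxplot_summary",
]


def compute_dm(
    records: pd.DataFrame, window: int = 50, log_base: float = 10.0
) -> pd.DataFrame:
    """Distance-from-median noise: residual of log CV from a running median.

    Genes are ranked by mean abundance; for each gene the median of
    log CV over a centered rank window of ``window`` genes is
    subtracted from the gene's own log CV.  At the edges the window
    shrinks symmetrically (gene *i* uses ranks ``i-k .. i+k`` with
    ``k = min(window//2, i, n-1-i)``), which keeps the gene centered and
    makes DM exactly zero whenever log CV is monotone in the mean.

    Parameters
    ----------
    records
        Columns ``mean`` and ``cv`` (and optionally ``gene_id``).  Rows
        with non-positive mean or CV are excluded with a warning.
    window
        Target rank-window width in genes.

    Returns
    -------
    The input rows (original order) with a ``dm`` column in
    ``log_base`` units; excluded rows carry NaN.
    """
    if len(records) < window:
        raise ValueError(
            f"need at least window={window} genes, got {len(records)}"
        )
    out = records.copy()
    mean = pd.to_numeric(out["mean"], errors="coerce")
    cv = pd.to_numeric(out["cv"], errors="coerce")
    valid = (mean > 0) & (cv > 0)
    if not valid.all():
        warnings.warn(
            f"excluding {(~valid).sum()} records with non-positive "
            "mean or CV from DM",
            stacklevel=2,
        )
    log_cv = np.log(cv[valid].to_numpy()) / np.log(log_base)
    order = np.argsort(mean[valid].to_numpy(), kind="stable")
    n = order.size
    half = window // 2
    running = np.empty(n)
    sorted_log_cv = log_cv[order]
    for i in range(n):
        k = min(half, i, n - 1 - i)
        running[i] = np.median(sorted_log_cv[i - k : i + k + 1])
    dm_sorted = sorted_log_cv - running
    dm = np.empty(n)
    dm[order] = dm_sorted
    out["dm"] = np.nan
    out.loc[valid[valid].index, "dm"] = dm
    return out


def rank_sum_test(
    x, y, exact_threshold: int = 8
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses exact enumeration of the U null when both samples are at most
    ``exact_threshold`` observations and tie-free; otherwise the normal
    approximation with tie correction and continuity correction.

    Returns ``(U statistic of x, two-sided p-value)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test requires non-empty samples")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    small = max(x.size, y.size) <= exact_threshold
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order preserved, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chisq_enrichment(observed, expected) -> tuple[float, float]:
    """Chi-square goodness-of-fit of observed counts against expected.

    Statistic ``sum((O-E)^2 / E)`` with ``k - 1`` degrees of freedom.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have the same length")
    if observed.size < 2:
        raise ValueError("need at least 2 categories (df >= 1)")
    if (expected <= 0).any():
        raise ValueError("expected counts must be strictly positive")
    # scale expected to the observed total so scipy accepts ratio inputs
    expected = expected * observed.sum() / expected.sum()
    res = stats.chisquare(observed, expected)
    return float(res.statistic), float(res.pvalue)


def boxplot_summary(values) -> dict:
    """Tukey five-number summary with 1.5*IQR outlier flags.

    Quartiles use linear interpolation of order statistics.  Outliers
    (below ``Q1 - 1.5 IQR`` or above ``Q3 + 1.5 IQR``) are returned for
    display purposes; the underlying data are never truncated.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = values[(values < lo) | (values > hi)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "lower_fence": float(lo),
        "upper_fence": float(hi),
        "outliers": outliers.tolist(),
        "n": int(values.size),
    }
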