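"""Alpha diversity, the CLR transform, and the univariate test battery.

Viral abundance tables are compositional and strongly zero-inflated, so
all multivariate work downstream runs on centered log-ratios computed
after adding a small pseudo-count (default 0.001 on the per-gigabase
abundance scale). Shannon diversity uses the natural logarithm.

The hypothesis tests here are the nonparametric battery used throughout
the analysis: two-sided Wilcoxon rank-sum and signed-rank tests with
Benjamini–Hochberg FDR correction, and the Friedman test (vOTUs as
blocks, timepoints as treatments) with Kendall's W as its effect size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .results import TestResult

DEFAULT_PSEUDO_COUNT = 0.001

#: sample size above which the rank tests switch from exact enumeration to
#: the tie- and continuity-corrected normal approximation
EXACT_N_MAX = 25


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(abundances) -> float:
    """Shannon index H = −Σ pᵢ ln pᵢ over detected (non-zero) entries."""
    x = np.asarray(abundances, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        return 0.0
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def alpha_diversity(matrix: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-sample alpha-diversity table.

    Columns: richness (S, vOTUs with abundance > 0), richness_per_gb
    (S per gigabase of quality-trimmed reads), shannon (natural log),
    pielou (H / ln S, NaN when S < 2), mean_abundance (mean normalized
    abundance over all vOTUs in the matrix).
    """
    missing = set(matrix.columns) - set(metadata.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    records = []
    for sample in matrix.columns:
        x = matrix[sample].to_numpy(dtype=float)
        s = int(np.count_nonzero(x > 0))
        h = shannon(x)
        j = h / np.log(s) if s >= 2 else np.nan
        gb = metadata.loc[sample, "total_bases"] / 1e9
        records.append({
            "sample_id": sample,
            "richness": s,
            "richness_per_gb": s / gb,
            "shannon": h,
            "pielou": j,
            "mean_abundance": float(x.mean()),
        })
    return pd.DataFrame.from_records(records).set_index("sample_id")


# ---------------------------------------------------------------------------
# compositional transform
# ---------------------------------------------------------------------------

def clr_transform(matrix: pd.DataFrame,
                  pseudo_count: float = DEFAULT_PSEUDO_COUNT) -> pd.DataFrame:
    """Centered log-ratio transform, per sample (column).

    clrᵢ = ln(xᵢ + c) − mean_j ln(xⱼ + c). Each sample's CLR values sum to
    zero. The pseudo-count c handles the zero inflation of viral
    abundance tables; it must be positive whenever zeros are present.
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundance matrix must be non-negative")
    if pseudo_count <= 0 and (values == 0).any():
        raise ValueError("pseudo_count must be > 0 when the matrix contains zeros")
    logged = np.log(values + pseudo_count)
    clr = logged - logged.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def _rank_method(n_largest: int, *groups) -> str:
    has_ties = len(np.unique(np.concatenate(groups))) < sum(len(g) for g in groups)
    return "asymptotic" if (n_largest > EXACT_N_MAX or has_ties) else "exact"


def wilcoxon_rank_sum(group_a, group_b, method: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact enumeration for small, tie-free samples; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if method == "auto":
        method = _rank_method(max(a.size, b.size), a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      method="wilcoxon_rank_sum", extra={"mode": method})


def wilcoxon_signed_rank(paired_a, paired_b, method: str = "auto") -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    When every difference is zero the test is degenerate; p = 1 is
    returned with a ``degenerate`` flag instead of an error.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult(statistic=0.0, p=1.0, method="wilcoxon_signed_rank",
                          extra={"degenerate": True})
    if method == "auto":
        method = ("asymptotic" if nz.size > EXACT_N_MAX
                  or len(np.unique(np.abs(nz))) < nz.size else "exact")
    res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                         alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      method="wilcoxon_signed_rank", extra={"mode": method})


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def friedman_with_kendall(matrix) -> TestResult:
    """Friedman test over a blocks × treatments table, with Kendall's W.

    In the temporal analysis the blocks (rows) are vOTUs and the
    treatments (columns) are timepoints, so df = n_timepoints − 1. Ranks
    are mid-ranks within each block and the χ² statistic carries the
    standard tie correction. Kendall's W = χ² / (n·(k−1)).
    """
    data = np.asarray(matrix, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected a 2-D blocks × treatments table")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    if np.isnan(data).any():
        raise ValueError("missing cells are not allowed (no imputation)")
    ranks = stats.rankdata(data, axis=1)
    col_sums = ranks.sum(axis=0)
    ssbn = float((col_sums ** 2).sum())
    chi2 = (12.0 / (n * k * (k + 1))) * ssbn - 3.0 * n * (k + 1)
    # tie correction: 1 - sum(t^3 - t) over tie groups / (n k (k^2 - 1))
    ties = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts ** 3 - counts).sum())
    c = 1.0 - ties / (n * k * (k * k - 1))
    if c <= 0:  # every row constant: no information, chi2 = 0
        chi2 = 0.0
    else:
        chi2 /= c
    df = k - 1
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    w = kendalls_w(chi2, n, k)
    return TestResult(statistic=float(chi2), p=p, df=df, effect_size=w,
                      method="friedman")


def kendalls_w(chi2: float, n_blocks: int, k_treatments: int) -> float:
    """Kendall's coefficient of concordance W = χ² / (n·(k−1))."""
    return float(chi2) / (n_blocks * (k_treatments - 1))


def consecutive_timepoint_tests(clr: pd.DataFrame) -> pd.DataFrame:
    """Post-hoc paired signed-rank tests between consecutive timepoints.

    Runs across vOTUs (rows) for each adjacent pair of the time-ordered
    sample columns, with BH correction over the pairs.
    """
    cols = list(clr.columns)
    rows = []
    for left, right in zip(cols[:-1], cols[1:]):
        res = wilcoxon_signed_rank(clr[left], clr[right])
        rows.append({"timepoint_a": left, "timepoint_b": right,
                     "statistic": res.statistic, "p": res.p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = benjamini_hochberg(out["p"].to_numpy())
    return out
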