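"""Temporal structure of viral communities.

Distance decay uses Bray–Curtis dissimilarity on log(x+1) abundances,
partitioned after Baselga into a balanced-variation (turnover) component
and an abundance-gradient component, and related to pairwise time lags
(whole months) with a Mantel test (Spearman by default).

vOTUs are also classified into occupancy-based dynamic classes over the
series: sporadic (detected in <25% of timepoints), intermittent
(25%–75%), and persistent (>75%); at 14 timepoints these bins are
exactly 1–3, 4–10, and 11–14 detections.
"""

from __future__ import annotations

import warnings
from datetime import date as _date

import numpy as np
import pandas as pd
from scipy import stats

from .results import TestResult

DYNAMIC_CLASSES = ("sporadic", "intermittent", "persistent")


def _log_vectors(x, y, pre_transform):
    u = np.asarray(x, dtype=float)
    v = np.asarray(y, dtype=float)
    if u.shape != v.shape:
        raise ValueError("abundance vectors must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("abundances must be non-negative")
    if pre_transform is not None:
        u, v = pre_transform(u), pre_transform(v)
    if u.sum() + v.sum() == 0:
        raise ValueError("Bray–Curtis is undefined when both vectors are all zero")
    return u, v


def bray_curtis_log(x, y, pre_transform=np.log1p) -> float:
    """Bray–Curtis dissimilarity on log(x+1)-transformed abundances."""
    u, v = _log_vectors(x, y, pre_transform)
    return float(np.abs(u - v).sum() / (u + v).sum())


def baselga_partition(x, y, pre_transform=np.log1p) -> tuple[float, float, float]:
    """Partition Bray–Curtis into balanced-variation and gradient parts.

    With A = Σ min(u,v), B = Σ(u − min), C = Σ(v − min):
    d_balanced = min(B,C) / (A + min(B,C)) is the substitution-like
    turnover component, and d_gradient = d_bray − d_balanced the
    abundance-gradient component. Applied to the same log(x+1) scale as
    the dissimilarity it decomposes.

    Returns (d_balanced, d_gradient, d_bray).
    """
    u, v = _log_vectors(x, y, pre_transform)
    m = np.minimum(u, v)
    a = float(m.sum())
    b = float((u - m).sum())
    c = float((v - m).sum())
    d_bray = (b + c) / (2 * a + b + c)
    mn = min(b, c)
    d_balanced = mn / (a + mn) if (a + mn) > 0 else 0.0
    return d_balanced, d_bray - d_balanced, d_bray


def months_apart(date_i, date_j) -> int:
    """Absolute whole-month difference between two calendar dates."""
    di, dj = pd.Timestamp(date_i), pd.Timestamp(date_j)
    return abs(12 * (di.year - dj.year) + (di.month - dj.month))


def distance_decay(matrix: pd.DataFrame, dates: pd.Series,
                   pre_transform=np.log1p) -> pd.DataFrame:
    """Pairwise decay table over the time-ordered samples of ``matrix``.

    One row per unordered sample pair with the months apart, the log
    Bray–Curtis dissimilarity and its balanced/gradient components.
    """
    samples = list(matrix.columns)
    rows = []
    for i, si in enumerate(samples):
        for sj in samples[i + 1:]:
            bal, grad, bray = baselga_partition(matrix[si], matrix[sj],
                                                pre_transform)
            rows.append({"sample_i": si, "sample_j": sj,
                         "months_apart": months_apart(dates[si], dates[sj]),
                         "d_bray": bray, "d_balanced": bal, "d_gradient": grad})
    return pd.DataFrame(rows)


def time_distance_matrix(dates: pd.Series) -> pd.DataFrame:
    """Sample × sample matrix of whole-month time lags."""
    ids = list(dates.index)
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = months_apart(dates.iloc[i], dates.iloc[j])
    return pd.DataFrame(out, index=ids, columns=ids)


def mantel_test(d1: pd.DataFrame, d2: pd.DataFrame, method: str = "spearman",
                n_perm: int = 999, seed: int | None = None) -> TestResult:
    """Mantel correlation between two distance matrices.

    Correlates the upper triangles (Spearman by default, Pearson as an
    option) and assesses significance by jointly permuting the rows and
    columns of ``d2``; two-sided p with the add-one convention.
    """
    if list(d1.index) != list(d2.index):
        d2 = d2.loc[d1.index, d1.index]
    a = d1.to_numpy(dtype=float)
    b = d2.to_numpy(dtype=float)
    n = a.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    iu = np.triu_indices(n, k=1)
    corr = {"spearman": lambda x, y: stats.spearmanr(x, y).statistic,
            "pearson": lambda x, y: stats.pearsonr(x, y).statistic}[method]
    r_obs = float(corr(a[iu], b[iu]))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        if abs(corr(a[iu], bp[iu])) >= abs(r_obs) - 1e-15:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return TestResult(statistic=r_obs, p=float(p), method=f"mantel_{method}",
                      extra={"n_perm": n_perm})


def classify_dynamics(detection: pd.DataFrame) -> pd.DataFrame:
    """Occupancy-based dynamic classes from a vOTU × timepoint presence table.

    occupancy f = detections / timepoints; sporadic when 0 < f < 0.25,
    intermittent when 0.25 ≤ f ≤ 0.75, persistent when f > 0.75. vOTUs
    never detected are excluded from the output.
    """
    det = detection.astype(bool)
    t = det.shape[1]
    if t < 1:
        raise ValueError("need at least one timepoint")
    n_det = det.sum(axis=1)
    out = pd.DataFrame({"n_detections": n_det, "n_timepoints": t})
    out = out[out["n_detections"] > 0]
    out["occupancy"] = out["n_detections"] / t
    f = out["occupancy"]
    out["dynamic_class"] = np.where(f < 0.25, "sporadic",
                                    np.where(f <= 0.75, "intermittent",
                                             "persistent"))
    out.index.name = "votu_id"
    return out


def dynamics_fractions_over_time(detection: pd.DataFrame,
                                 classification: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint percentage of detected vOTUs in each dynamic class.

    Rows (timepoints) sum to 100. Timepoints with zero detections are
    omitted with a warning.
    """
    det = detection.astype(bool).loc[classification.index]
    classes = classification["dynamic_class"]
    rows = {}
    for tp in det.columns:
        present = det[tp]
        total = int(present.sum())
        if total == 0:
            warnings.warn(f"timepoint {tp!r} has zero detections; omitted",
                          stacklevel=2)
            continue
        counts = classes[present].value_counts()
        rows[tp] = {cls: 100.0 * counts.get(cls, 0) / total
                    for cls in DYNAMIC_CLASSES}
    out = pd.DataFrame.from_dict(rows, orient="index")[list(DYNAMIC_CLASSES)]
    out.index.name = "timepoint"
    return out
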