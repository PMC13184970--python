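"""Beta diversity and community-structure statistics.

Sample dissimilarity is the Aitchison distance (Euclidean distance on
CLR-transformed abundances), embedded by principal coordinate analysis.
Group structure is probed with k-means (k chosen by mean silhouette
width), PERMANOVA (global and pairwise, with FDR over pairs), and
post-hoc environmental vector fitting onto the first two ordination
axes. Permutation p-values use the add-one convention
(b + 1) / (m + 1), whose floor at 999 permutations is 0.001.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .diversity import benjamini_hochberg
from .results import OrdinationResult, TestResult

DEFAULT_N_PERM = 999
DEFAULT_K_MAX = 8
DEFAULT_N_RESTARTS = 100


def aitchison_distance(clr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distance between the CLR vectors of samples.

    ``clr`` is vOTU × sample; the result is a symmetric sample × sample
    DataFrame with a zero diagonal.
    """
    if clr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(clr.to_numpy(dtype=float).T, metric="euclidean"))
    return pd.DataFrame(d, index=clr.columns, columns=clr.columns)


def _check_distance(dist: pd.DataFrame) -> np.ndarray:
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    return d


def pcoa(dist: pd.DataFrame) -> OrdinationResult:
    """Principal coordinate analysis (classical MDS) of a distance matrix.

    Double-centers −½D², eigendecomposes, and keeps axes with positive
    eigenvalues; coordinates are eigenvectors scaled by √λ and
    percent_variance is 100·λᵢ/Σλ⁺ over the positive eigenvalues.
    """
    d = _check_distance(dist)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12, 1e-10 * max(eigval.max(), 1.0))
    lam = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(lam)
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dist.index, columns=axes),
        eigenvalues=eigval,
        percent_variance=100.0 * lam / lam.sum(),
    )


def select_k_by_silhouette(ordination: OrdinationResult,
                           k_min: int = 2,
                           k_max: int | None = None,
                           n_restarts: int = DEFAULT_N_RESTARTS,
                           seed: int | None = None,
                           n_axes: int | None = None) -> tuple[int, np.ndarray]:
    """k-means over a range of k; returns the smallest k with the highest
    mean silhouette width, and its labels.

    Runs on all positive-eigenvalue PCoA axes by default (``n_axes``
    restricts to the leading axes). ``n_restarts`` k-means restarts are
    used per k.
    """
    coords = ordination.coordinates.to_numpy(dtype=float)
    if n_axes is not None:
        coords = coords[:, :n_axes]
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to select k")
    if k_max is None:
        k_max = min(DEFAULT_K_MAX, n - 1)
    k_max = min(k_max, n - 1)
    rng = np.random.default_rng(seed)
    best: dict[int, tuple[float, np.ndarray]] = {}
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts,
                    random_state=int(rng.integers(2 ** 31)))
        labels = km.fit_predict(coords)
        if len(np.unique(labels)) < 2:
            continue
        best[k] = (float(silhouette_score(coords, labels)), labels)
    if not best:
        raise ValueError("no valid clustering found in the k range")
    top = max(score for score, _ in best.values())
    k_sel = min(k for k, (score, _) in best.items() if score >= top - 1e-12)
    return k_sel, best[k_sel][1]


def _permanova_f(d2: np.ndarray, groups: list[np.ndarray], n: int,
                 ss_total: float) -> tuple[float, float]:
    ss_within = 0.0
    for idx in groups:
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    g = len(groups)
    f = (ss_between / (g - 1)) / (ss_within / (n - g))
    return f, ss_between / ss_total


def permanova(dist: pd.DataFrame, labels, n_perm: int = DEFAULT_N_PERM,
              seed: int | None = None) -> TestResult:
    """One-factor PERMANOVA on a distance matrix.

    Computes the pseudo-F from the partition of the total sum of squared
    distances into between- and within-group parts, with the p-value from
    ``n_perm`` label permutations: p = (#{F* ≥ F} + 1)/(n_perm + 1).
    ``effect_size`` is r² = SS_between / SS_total.
    """
    d = _check_distance(dist)
    labels = np.asarray(labels)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels must match the distance matrix")
    uniq, inv = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(inv)
    if sizes.min() < 2:
        raise ValueError("every group needs at least 2 samples")
    d2 = d ** 2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    groups = [np.flatnonzero(inv == g) for g in range(len(uniq))]
    f_obs, r2 = _permanova_f(d2, groups, n, ss_total)
    rng = np.random.default_rng(seed)
    # Strict exceedance: with small balanced groups a random label
    # permutation reproduces the observed partition (same F) with
    # probability 2/C(n, n_a) per draw; such re-draws are not more
    # extreme than the observed grouping and are not counted. The
    # observed grouping itself enters once through the add-one terms.
    tol = 1e-9 * max(abs(f_obs), 1.0)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(inv)
        perm_groups = [np.flatnonzero(perm == g) for g in range(len(uniq))]
        f_perm, _ = _permanova_f(d2, perm_groups, n, ss_total)
        if f_perm > f_obs + tol:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return TestResult(statistic=float(f_obs), p=float(p), effect_size=float(r2),
                      df=len(uniq) - 1, method="permanova",
                      extra={"df_residual": n - len(uniq), "n_perm": n_perm})


def pairwise_permanova(dist: pd.DataFrame, labels,
                       n_perm: int = DEFAULT_N_PERM,
                       seed: int | None = None) -> pd.DataFrame:
    """PERMANOVA on every pair of groups, BH-adjusted across pairs."""
    labels = pd.Series(np.asarray(labels), index=dist.index)
    uniq = sorted(pd.unique(labels))
    rng = np.random.default_rng(seed)
    rows = []
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            mask = labels.isin([a, b])
            sub = dist.loc[mask, mask]
            res = permanova(sub, labels[mask].to_numpy(), n_perm=n_perm,
                            seed=int(rng.integers(2 ** 31)))
            rows.append({"group_a": a, "group_b": b,
                         "pseudo_f": res.statistic, "r2": res.effect_size,
                         "p": res.p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def envfit_vectors(ordination: OrdinationResult, env: pd.DataFrame,
                   n_perm: int = DEFAULT_N_PERM, seed: int | None = None,
                   n_axes: int = 2) -> pd.DataFrame:
    """Post-hoc fit of environmental variables onto ordination axes.

    Each (centered) variable is regressed onto the first ``n_axes``
    ordination axes; r² is the coefficient of determination and the arrow
    is the unit-normalized coefficient vector. Significance comes from
    permuting the variable across samples (add-one convention). Samples
    with missing values are dropped per variable with a warning; constant
    variables are excluded with an ``excluded`` flag.
    """
    coords = ordination.coordinates.iloc[:, :n_axes]
    axes = list(coords.columns)
    rng = np.random.default_rng(seed)
    rows = []
    for var in env.columns:
        y_full = env[var].astype(float)
        keep = y_full.notna()
        if not keep.all():
            warnings.warn(f"envfit: dropping {int((~keep).sum())} samples with "
                          f"missing {var!r}", stacklevel=2)
        y = y_full[keep].to_numpy()
        x = coords.loc[keep.index[keep]].to_numpy(dtype=float)
        if y.size < 3 or np.ptp(y) == 0:
            rows.append({"variable": var, "r_squared": np.nan, "p": np.nan,
                         **{ax: np.nan for ax in axes}, "excluded": True})
            continue
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        coef, *_ = np.linalg.lstsq(xc, yc, rcond=None)
        sst = float(yc @ yc)
        r2 = float((xc @ coef) @ yc) / sst
        norm = np.linalg.norm(coef)
        arrow = coef / norm if norm > 0 else coef
        # permutation null: project permuted variable onto the axes
        q, _ = np.linalg.qr(xc)
        perms = np.stack([rng.permutation(yc) for _ in range(n_perm)])
        proj = perms @ q  # (n_perm, n_axes)
        r2_perm = (proj ** 2).sum(axis=1) / (perms ** 2).sum(axis=1)
        p = (int((r2_perm >= r2 - 1e-15).sum()) + 1) / (n_perm + 1)
        rows.append({"variable": var, "r_squared": r2, "p": p,
                     **dict(zip(axes, arrow)), "excluded": False})
    return pd.DataFrame(rows).set_index("variable")
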