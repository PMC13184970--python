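"""Annotation-based contrasts between ecosystems and over time.

Covers the overlap of vOTU inventories (Sørensen–Dice), propagation of
contig-level annotations to vOTUs, the temperate/virulent lifestyle call,
auxiliary-viral-gene (AVG) filtering and carrier summaries, per-sample
category percentages, and the filtered effect-size procedure: per-category
two-sided rank-sum tests across samples with FDR correction, retaining
categories with ≥5 vOTUs in at least one group and an absolute median
difference ≥0.1 percentage points.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .diversity import benjamini_hochberg, wilcoxon_rank_sum
from .results import OverlapResult, TestResult, VotuClustering

RECOMBINASE_BITSCORE_MIN = 50.0
ANNOTATION_BITSCORE_MIN = 60.0
LIFESTYLE_PROBABILITY_MIN = 0.95
AUX_SCORE_MAX = 3
HIGH_QUALITY_TIERS = ("complete", "high")

MIN_VOTUS_PER_CATEGORY = 5
MIN_ABS_EFFECT = 0.1


def sorensen_dice(set_a, set_b, label_a: str = "A", label_b: str = "B") -> OverlapResult:
    """Sørensen–Dice overlap: 100 × |A∩B| / mean(|A|, |B|)."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("both vOTU sets must be non-empty")
    shared = len(a & b)
    dice = 100.0 * shared / ((len(a) + len(b)) / 2)
    return OverlapResult(group_a=label_a, group_b=label_b, n_a=len(a),
                         n_b=len(b), n_shared=shared, dice_percent=dice)


def call_temperate(evidence: pd.DataFrame) -> str:
    """Lifestyle call for one vOTU from its per-contig evidence rows.

    temperate when any recombinase hit reaches bit score ≥50, or a
    complete/high-quality genome has temperate lifestyle probability
    ≥95%; virulent when a complete/high-quality genome has virulent
    probability ≥95%; otherwise undetermined. Thresholds inclusive.
    """
    bit = evidence.get("recombinase_bitscore")
    if bit is not None and (bit.dropna() >= RECOMBINASE_BITSCORE_MIN).any():
        return "temperate"
    prob = evidence.get("lifestyle_probability")
    cls = evidence.get("lifestyle_class")
    tier = evidence.get("quality_tier")
    if prob is not None and cls is not None and tier is not None:
        hq = tier.isin(HIGH_QUALITY_TIERS)
        ok = hq & (prob >= LIFESTYLE_PROBABILITY_MIN)
        if (ok & (cls == "temperate")).any():
            return "temperate"
        if (ok & (cls == "virulent")).any():
            return "virulent"
    return "undetermined"


def filter_avgs(genes: pd.DataFrame) -> pd.DataFrame:
    """Retain auxiliary viral genes passing the conservative filters.

    Keeps rows with annotation bit score ≥60, auxiliary score ≤3, and
    without the ``V`` amg_flag (viral-like gene).
    """
    flags = genes.get("amg_flags", pd.Series("", index=genes.index)).fillna("")
    keep = ((genes["bit_score"] >= ANNOTATION_BITSCORE_MIN)
            & (genes["aux_score"] <= AUX_SCORE_MAX)
            & ~flags.str.contains("V"))
    return genes[keep]


def propagate_contig_labels(contig_annotations: pd.DataFrame,
                            clustering: VotuClustering) -> pd.DataFrame:
    """Lift per-contig annotations to the vOTU (population) level.

    A vOTU is temperate when any member contig is temperate (members of a
    cluster putatively belong to the same population); its AVG category
    set is the union over members; host genus is taken from the
    representative contig. Idempotent: feeding the output's rows back
    reproduces the same table.

    ``contig_annotations`` has one row per contig with optional columns
    ``temperate`` (bool), ``avg_categories`` (iterable or ';'-joined
    string), ``host_genus``.
    """
    ann = contig_annotations.set_index("contig_id") \
        if "contig_id" in contig_annotations.columns else contig_annotations
    unknown = set(ann.index.astype(str)) - set(clustering.representative_of)
    if unknown:
        raise ValueError(f"annotated contigs missing from clustering: {sorted(unknown)[:5]}")

    def _cats(value) -> set:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return set()
        if isinstance(value, str):
            return {c for c in value.split(";") if c}
        return set(value)

    rows = []
    for rep, members in clustering.members.items():
        present = [c for c in members if c in ann.index]
        sub = ann.loc[present]
        temperate = bool(sub["temperate"].fillna(False).any()) \
            if "temperate" in sub.columns and len(sub) else False
        cats: set = set()
        if "avg_categories" in sub.columns:
            for v in sub["avg_categories"]:
                cats |= _cats(v)
        host = None
        if "host_genus" in ann.columns and rep in ann.index:
            h = ann.loc[rep, "host_genus"]
            host = None if pd.isna(h) else h
        rows.append({"votu_id": rep, "temperate": temperate,
                     "avg_categories": ";".join(sorted(cats)),
                     "host_genus": host,
                     "n_member_contigs": len(members)})
    return pd.DataFrame(rows).set_index("votu_id")


def carrier_percent(n_carriers: int, n_total: int) -> float:
    """Percentage of vOTUs carrying ≥1 retained AVG, to one decimal."""
    if n_total <= 0:
        raise ValueError("total vOTU count must be > 0")
    return round(100.0 * n_carriers / n_total, 1)


def avg_carrier_percent(annotations: pd.DataFrame, n_total: int | None = None) -> float:
    """AVG-carrier percentage from a vOTU annotation table.

    A carrier has a non-empty ``avg_categories`` entry; ``n_total``
    defaults to the number of rows of the table.
    """
    cats = annotations["avg_categories"].fillna("")
    carriers = int((cats.astype(str).str.len() > 0).sum())
    total = len(annotations) if n_total is None else n_total
    return carrier_percent(carriers, total)


def _category_lists(annotations: pd.DataFrame, category_type: str) -> pd.Series:
    """Per-vOTU list of category labels for the requested annotation type."""
    if category_type == "host":
        col = annotations["host_genus"]
        return col.map(lambda h: [] if pd.isna(h) or h is None else [h])
    if category_type == "strategy":
        def _strategy(row):
            if "lifestyle" in annotations.columns:
                v = row["lifestyle"]
                return [] if pd.isna(v) or v == "undetermined" else [v]
            return ["temperate"] if row.get("temperate") else ["virulent"]
        return annotations.apply(_strategy, axis=1)
    if category_type == "avg":
        return annotations["avg_categories"].fillna("").map(
            lambda s: [c for c in str(s).split(";") if c])
    raise ValueError(f"unknown category_type {category_type!r}")


def per_sample_category_percent(matrix: pd.DataFrame,
                                annotations: pd.DataFrame,
                                category_type: str,
                                denominator: str = "assigned") -> pd.DataFrame:
    """Percentage of detected vOTUs in each category, per sample.

    Detection is abundance > 0. With ``denominator="assigned"`` (default)
    the percentage is over detected vOTUs carrying any assignment of the
    same category type; ``denominator="all"`` uses all detected vOTUs.
    Categories absent from a sample yield 0 (zeros are kept as data
    points for the downstream effect-size tests).
    """
    if denominator not in ("assigned", "all"):
        raise ValueError("denominator must be 'assigned' or 'all'")
    ann = annotations.reindex(matrix.index)
    cat_lists = _category_lists(ann, category_type)
    all_cats = sorted({c for cats in cat_lists for c in cats})
    out = {}
    for sample in matrix.columns:
        detected = matrix[sample] > 0
        assigned = detected & (cat_lists.str.len() > 0)
        denom = int(assigned.sum()) if denominator == "assigned" else int(detected.sum())
        if denom == 0:
            warnings.warn(f"sample {sample!r} has no assigned detected vOTUs",
                          stacklevel=2)
            out[sample] = {c: np.nan for c in all_cats}
            continue
        counts = {c: 0 for c in all_cats}
        for cats in cat_lists[assigned]:
            for c in cats:
                counts[c] += 1
        out[sample] = {c: 100.0 * counts[c] / denom for c in all_cats}
    result = pd.DataFrame.from_dict(out, orient="index")
    result.index.name = "sample_id"
    return result


def effect_size_contrast(matrix: pd.DataFrame,
                         annotations: pd.DataFrame,
                         metadata: pd.DataFrame,
                         category_type: str,
                         group_a: str = "lagoon",
                         group_b: str = "open_sea",
                         exclude_shared: bool = False,
                         denominator: str = "assigned") -> pd.DataFrame:
    """Filtered per-category effect-size contrast between two groups.

    For every category: per-sample percentages in each group, a two-sided
    Wilcoxon rank-sum test across samples (zeros included), effect size =
    median(group A) − median(group B) in percentage points, and BH
    correction over the categories passing both retention filters
    (≥5 vOTUs in at least one group; |effect| ≥ 0.1). Excluded categories
    are reported with an ``excluded_reason``.

    With ``exclude_shared`` (used for strategy and AVG contrasts, whose
    annotations derive from contigs pooled across groups), vOTUs detected
    in both groups are removed before computing anything.
    """
    samples_a = metadata.index[metadata["ecosystem"] == group_a]
    samples_b = metadata.index[metadata["ecosystem"] == group_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    mat = matrix.copy()
    if exclude_shared:
        in_a = (mat[samples_a] > 0).any(axis=1)
        in_b = (mat[samples_b] > 0).any(axis=1)
        mat = mat[~(in_a & in_b)]
    ann = annotations.reindex(mat.index)
    cat_lists = _category_lists(ann, category_type)

    pct_a = per_sample_category_percent(mat[samples_a], ann, category_type,
                                        denominator)
    pct_b = per_sample_category_percent(mat[samples_b], ann, category_type,
                                        denominator)
    categories = sorted(set(pct_a.columns) | set(pct_b.columns))

    def _n_votus(samples, cat):
        detected = (mat[samples] > 0).any(axis=1)
        return int(sum(cat in cats for cats in cat_lists[detected]))

    rows = []
    for cat in categories:
        a = (pct_a[cat] if cat in pct_a.columns
             else pd.Series(0.0, index=pct_a.index)).fillna(0.0).to_numpy()
        b = (pct_b[cat] if cat in pct_b.columns
             else pd.Series(0.0, index=pct_b.index)).fillna(0.0).to_numpy()
        n_a, n_b = _n_votus(samples_a, cat), _n_votus(samples_b, cat)
        effect = float(np.median(a) - np.median(b))
        reason = None
        if max(n_a, n_b) < MIN_VOTUS_PER_CATEGORY:
            reason = f"fewer than {MIN_VOTUS_PER_CATEGORY} vOTUs in both groups"
        elif abs(effect) < MIN_ABS_EFFECT:
            reason = f"absolute median difference below {MIN_ABS_EFFECT}"
        res = wilcoxon_rank_sum(a, b)
        rows.append({"category": cat, "median_a": float(np.median(a)),
                     "median_b": float(np.median(b)), "effect_size": effect,
                     "statistic": res.statistic, "p": res.p,
                     "n_votus_a": n_a, "n_votus_b": n_b,
                     "included": reason is None, "excluded_reason": reason})
    out = pd.DataFrame(rows).set_index("category")
    out["p_adjusted"] = np.nan
    retained = out.index[out["included"]]
    if len(retained):
        out.loc[retained, "p_adjusted"] = benjamini_hochberg(
            out.loc[retained, "p"].to_numpy())
    return out


def spearman_env_correlation(series_a, series_b) -> TestResult:
    """Spearman correlation between two paired time series.

    Mid-ranks for ties; two-sided p (exact for n ≤ 9, t-approximation
    otherwise, as in scipy). Constant input is degenerate and flagged.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size != b.size:
        raise ValueError("series must be paired (equal length)")
    if a.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return TestResult(statistic=np.nan, p=np.nan, method="spearman",
                          extra={"degenerate": True})
    rho, p = stats.spearmanr(a, b)
    return TestResult(statistic=float(rho), p=float(p), method="spearman")


def heatmap_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """log10(x+1) transform plus average-linkage row clustering.

    Returns the transformed category × time matrix and the leaf order of
    the hierarchical clustering (Euclidean distance, average linkage) for
    reproducible heatmap plotting.
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("heatmap input must be non-negative")
    logged = pd.DataFrame(np.log10(values + 1.0), index=matrix.index,
                          columns=matrix.columns)
    if len(matrix) < 2:
        return logged, list(matrix.index)
    z = linkage(logged.to_numpy(), method="average", metric="euclidean")
    order = [matrix.index[i] for i in leaves_list(z)]
    return logged, order
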