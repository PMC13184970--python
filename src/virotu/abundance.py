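"""Coverage-based vOTU abundances and greedy centroid clustering.

The abundance of a viral population in a sample is the trimmed mean of the
per-position read depth over its representative contig, divided by the
total quality-trimmed bases sequenced for that sample and scaled to a
metagenome gigabase (×10⁹). A population counts as detected in a sample
only when read mapping covers at least ``breadth_min`` (default 70%) of
the contig; below that the abundance is zeroed.

Contigs are grouped into vOTUs at ≥95% average nucleotide identity over
≥80% of the shorter sequence with a greedy centroid pass: contigs are
visited from longest to shortest and join the first (longest) existing
representative they match, otherwise they found a new cluster.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .results import VotuClustering

DEFAULT_TRIM_FRACTION = 0.05
DEFAULT_BREADTH_MIN = 0.70
DEFAULT_ANI_MIN = 95.0
DEFAULT_AF_MIN = 0.80


def trimmed_mean(depth_vector, trim_fraction: float = DEFAULT_TRIM_FRACTION) -> float:
    """Two-sided trimmed mean of a per-position depth vector.

    ``floor(trim_fraction * L)`` positions are removed from each tail of the
    sorted vector before averaging, so ``trim_fraction=0`` is the plain mean.
    """
    depth_vector = np.asarray(depth_vector, dtype=float)
    if depth_vector.size == 0:
        raise ValueError("depth vector must contain at least one position")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError(f"trim_fraction must be in [0, 0.5), got {trim_fraction}")
    return float(stats.trim_mean(depth_vector, trim_fraction))


def breadth_of_coverage(depth_vector) -> float:
    """Fraction of positions covered by at least one read."""
    depth_vector = np.asarray(depth_vector, dtype=float)
    if depth_vector.size == 0:
        raise ValueError("depth vector must contain at least one position")
    return float(np.count_nonzero(depth_vector) / depth_vector.size)


def apply_detection_filter(coverage: pd.DataFrame,
                           breadth_min: float = DEFAULT_BREADTH_MIN) -> pd.DataFrame:
    """Zero the depth of contig/sample records below the breadth threshold.

    The threshold is inclusive: breadth exactly at ``breadth_min`` is
    retained. Identity and read-alignment filters are assumed applied
    upstream, by the mapper that produced the summary.
    """
    out = coverage.copy()
    out.loc[out["breadth"] < breadth_min, "trimmed_mean_depth"] = 0.0
    return out


def normalize_per_gigabase(trimmed_mean_depth: float, total_bases: float) -> float:
    """Depth normalized per metagenome gigabase: depth / total_bases × 10⁹."""
    if total_bases <= 0:
        raise ValueError(f"total_bases must be > 0, got {total_bases}")
    return trimmed_mean_depth / total_bases * 1e9


def cluster_votus(contig_lengths: Mapping[str, int],
                  similarities: pd.DataFrame,
                  ani_min: float = DEFAULT_ANI_MIN,
                  af_min: float = DEFAULT_AF_MIN) -> VotuClustering:
    """Greedy centroid clustering of contigs into vOTUs.

    Contigs are sorted by length descending (ties broken lexicographically
    by id) and each joins the first existing representative with
    ANI ≥ ``ani_min`` and aligned fraction of the shorter sequence
    ≥ ``af_min``; otherwise it founds a new cluster. The result is
    invariant to the order of the similarity records.

    Parameters
    ----------
    contig_lengths : mapping contig id → length (bp); must cover every
        contig named in ``similarities``.
    similarities : DataFrame with columns contig_a, contig_b, ani_percent,
        aligned_fraction_shorter. Pairs are treated as symmetric.
    """
    known = set(contig_lengths)
    pair_sim: dict[tuple[str, str], tuple[float, float]] = {}
    for row in similarities.itertuples(index=False):
        a, b = str(row.contig_a), str(row.contig_b)
        for c in (a, b):
            if c not in known:
                raise ValueError(f"similarity record references unknown contig {c!r}")
        key = (a, b) if a <= b else (b, a)
        prev = pair_sim.get(key)
        cur = (float(row.ani_percent), float(row.aligned_fraction_shorter))
        # keep the best evidence if a pair is listed more than once
        if prev is None or cur > prev:
            pair_sim[key] = cur

    def hits(x: str, y: str) -> bool:
        key = (x, y) if x <= y else (y, x)
        sim = pair_sim.get(key)
        return sim is not None and sim[0] >= ani_min and sim[1] >= af_min

    order = sorted(contig_lengths, key=lambda c: (-contig_lengths[c], c))
    members: dict[str, list[str]] = {}
    representative_of: dict[str, str] = {}
    for contig in order:
        for rep in members:  # founding order == length-descending order
            if hits(contig, rep):
                members[rep].append(contig)
                representative_of[contig] = rep
                break
        else:
            members[contig] = [contig]
            representative_of[contig] = contig
    return VotuClustering(representative_of=representative_of, members=members,
                          ani_min=ani_min, af_min=af_min)


def build_abundance_matrix(coverage: pd.DataFrame,
                           clustering: VotuClustering,
                           metadata: pd.DataFrame,
                           breadth_min: float = DEFAULT_BREADTH_MIN) -> pd.DataFrame:
    """Normalized abundance matrix of cluster representatives.

    Applies the breadth detection filter, keeps the coverage rows of the
    representatives, normalizes per gigabase with each sample's
    ``total_bases``, and returns a vOTU × sample DataFrame with samples
    ordered by metadata date then id. Representatives without a coverage
    row in some sample get abundance 0 there.
    """
    missing = set(coverage["sample_id"].astype(str)) - set(metadata.index)
    if missing:
        raise ValueError(f"coverage rows reference samples without metadata: {sorted(missing)}")
    filtered = apply_detection_filter(coverage, breadth_min)
    reps = list(clustering.members)
    filtered = filtered[filtered["contig_id"].isin(reps)]
    depth = (filtered.pivot_table(index="contig_id", columns="sample_id",
                                  values="trimmed_mean_depth", aggfunc="sum",
                                  fill_value=0.0)
             .reindex(index=reps, fill_value=0.0))
    sample_order = metadata.assign(_id=metadata.index).sort_values(
        ["date", "_id"]).index
    depth = depth.reindex(columns=sample_order, fill_value=0.0)
    totals = metadata.loc[sample_order, "total_bases"].to_numpy(dtype=float)
    if np.any(totals <= 0):
        raise ValueError("every sample needs total_bases > 0")
    matrix = depth.to_numpy(dtype=float) / totals[np.newaxis, :] * 1e9
    return pd.DataFrame(matrix, index=pd.Index(reps, name="votu_id"),
                        columns=sample_order)
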