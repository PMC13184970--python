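"""Independent reference implementations used only to check the package."""

from __future__ import annotations


def centroid_clusters(lengths: dict, pair_sims: dict,
                      ani_min: float = 95.0, af_min: float = 0.80) -> dict:
    """Plain-python evaluation of the greedy centroid rule.

    ``pair_sims`` maps frozenset({a, b}) → (ani_percent, aligned_fraction).
    Returns contig → representative. Written independently of the
    package implementation (no pandas, no dedup machinery) as its oracle.
    """
    order = sorted(lengths, key=lambda c: (-lengths[c], c))
    reps: list[str] = []
    assign: dict[str, str] = {}
    for contig in order:
        for rep in reps:
            sim = pair_sims.get(frozenset((contig, rep)))
            if sim is not None and sim[0] >= ani_min and sim[1] >= af_min:
                assign[contig] = rep
                break
        else:
            reps.append(contig)
            assign[contig] = contig
    return assign


def dice_percent_bruteforce(a, b) -> float:
    """Classic Sørensen–Dice on sets: 2|A∩B|/(|A|+|B|) × 100."""
    a, b = set(a), set(b)
    return 200.0 * len(a & b) / (len(a) + len(b))
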