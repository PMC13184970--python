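"""From read-mapping coverage to a normalized vOTU abundance matrix.

Simulates per-position coverage for a handful of contigs, clusters the
contigs into vOTUs at 95% ANI / 80% aligned fraction, applies the ≥70%
breadth detection filter, and normalizes trimmed-mean depths per
metagenome gigabase.
"""

import pandas as pd

import virotu

# coverage for 4 contigs in one sample; one contig has breadth ~0.5 and
# will fail the detection filter
profiles = virotu.generate_coverage_profiles(
    4, [12000, 9000, 6000, 5000], seed=3, breadths=[0.95, 0.9, 0.5, 0.85],
    mean_depth=6.0, total_bases=2e9)
cov = profiles.summary
print("coverage summary (trimmed-mean depth and breadth per contig):")
print(cov[["contig_id", "trimmed_mean_depth", "breadth"]].round(2).to_string(index=False))

# contigs 0 and 1 are near-identical; the longer founds the vOTU
sims = pd.DataFrame({
    "contig_a": ["contig_0000"], "contig_b": ["contig_0001"],
    "ani_percent": [97.2], "aligned_fraction_shorter": [0.91],
})
lengths = dict(zip(cov["contig_id"], cov["contig_length"]))
clustering = virotu.cluster_votus(lengths, sims)
print(f"\n{len(lengths)} contigs -> {len(clustering)} vOTUs;"
      f" representatives: {clustering.representatives}")

metadata = pd.DataFrame({
    "ecosystem": ["lagoon"], "date": [pd.Timestamp("2019-10-01")],
    "total_bases": [2e9],
}, index=pd.Index(["S1"], name="sample_id"))
matrix = virotu.build_abundance_matrix(cov, clustering, metadata)
print("\nnormalized abundances (per metagenome gigabase):")
print(matrix.round(3).to_string())
print("contig_0002 reads as 0: its breadth (0.5) is below the 70% "
      "detection threshold, so it does not count as present")
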