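"""Result containers shared across the statistical modules."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TestResult:
    """Uniform output of every hypothesis test in the package.

    Attributes
    ----------
    statistic : float
        The test statistic (U, W, χ², pseudo-F, ρ, ... depending on ``method``).
    p : float
        Two-sided (or permutation) p-value in [0, 1].
    method : str
        Short label of the procedure that produced the result.
    df : int, optional
        Degrees of freedom, where the test defines them.
    p_adjusted : float, optional
        FDR (Benjamini–Hochberg) adjusted p-value, filled in by batch callers.
    effect_size : float, optional
        Method-specific effect size (Kendall's W, PERMANOVA r², median
        difference, ...).
    extra : dict
        Auxiliary quantities (e.g. degenerate-input flags, r², permutation
        counts) that do not fit the common fields.
    """

    statistic: float
    p: float
    method: str
    df: int | None = None
    p_adjusted: float | None = None
    effect_size: float | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class OverlapResult:
    """Sørensen–Dice overlap between two vOTU sets."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    n_shared: int
    dice_percent: float


@dataclass
class OrdinationResult:
    """PCoA embedding of a sample distance matrix.

    ``coordinates`` is a samples × axes DataFrame; only axes with positive
    eigenvalues are kept, ordered by decreasing eigenvalue.
    ``percent_variance`` is computed over the positive eigenvalues only.
    """

    coordinates: "pandas.DataFrame"  # noqa: F821 - avoid import cycle
    eigenvalues: "numpy.ndarray"  # noqa: F821
    percent_variance: "numpy.ndarray"  # noqa: F821


@dataclass
class VotuClustering:
    """Assignment of contigs to vOTUs by the greedy centroid rule.

    ``representative_of`` maps every contig to its cluster representative;
    ``members`` maps each representative to the list of member contigs
    (representative included). Representatives are the longest member of
    their cluster, ties broken lexicographically.
    """

    representative_of: dict
    members: dict
    ani_min: float = 95.0
    af_min: float = 0.80

    @property
    def representatives(self) -> list:
        return list(self.members)

    def __len__(self) -> int:
        return len(self.members)
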