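"""Seeded synthetic datasets with the structure the analysis assumes.

The generators emulate, at desk scale, the statistical features of a
two-ecosystem viral metagenomic survey: a species-rich, high-abundance
coastal lagoon versus an oligotrophic open sea with a small shared vOTU
inventory; a monthly lagoon time series with smooth community turnover,
episodic disturbances that inject cohorts of sporadic vOTUs, and one
environmental covariate constructed to track the leading community axis
at a planted r² next to pure-noise decoys; per-position coverage
profiles with controllable breadth; and annotation tables with planted
per-group enrichments of host genera, temperate calls, and auxiliary
gene categories.

Every generator draws from a single ``numpy.random.default_rng(seed)``
instance, so regeneration with the same configuration is bit-identical.
Nonzero abundances are lognormal on top of Bernoulli/occupancy zeros,
matching the zero-inflated shape that motivates the CLR pseudo-count
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import clr_transform
from .structure import aitchison_distance, pcoa

START_DATE = "2019-10-01"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-community generators.

    Defaults mirror the study conditions at desk scale: a lagoon pool
    twice as rich as the open-sea pool, a small shared inventory, a
    ~4.8-fold lagoon abundance excess, 7 samples per group, a 14-point
    monthly series with two disturbances, and an occupancy mixture
    dominated by sporadic and intermittent vOTUs with a small persistent
    core.
    """

    seed: int = 0
    n_votus_lagoon: int = 300
    n_votus_sea: int = 150
    shared_fraction: float = 0.05
    abundance_fold: float = 4.8
    n_samples_per_group: int = 7
    n_timepoints: int = 14
    disturbance_timepoints: tuple = (0, 8)
    occupancy_mixture: tuple = (0.42, 0.46, 0.12)
    env_signal_r2: float = 0.5
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.5
    detection_prob: float = 0.7
    disturbance_cohort_fraction: float = 0.15

    def validate(self) -> None:
        for name in ("n_votus_lagoon", "n_votus_sea", "n_samples_per_group",
                     "n_timepoints"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        for name in ("shared_fraction", "env_signal_r2", "detection_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.abundance_fold <= 0:
            raise ValueError("abundance_fold must be positive")
        mix = np.asarray(self.occupancy_mixture, dtype=float)
        if mix.shape != (3,) or (mix < 0).any() or abs(mix.sum() - 1) > 1e-9:
            raise ValueError("occupancy_mixture must be 3 proportions summing to 1")
        for t in self.disturbance_timepoints:
            if not 0 <= t < self.n_timepoints:
                raise ValueError(
                    f"disturbance_timepoints index {t} out of range "
                    f"[0, {self.n_timepoints})")


@dataclass
class GroundTruth:
    """Planted structure emitted alongside each synthetic dataset."""

    votu_ecosystem_origin: dict = field(default_factory=dict)
    planted_occupancy_class: dict = field(default_factory=dict)
    planted_env_driver_ids: list = field(default_factory=list)
    planted_enriched_categories: dict = field(default_factory=dict)


def _monthly_dates(n: int, start: str = START_DATE) -> pd.DatetimeIndex:
    return pd.date_range(start, periods=n, freq="MS")


def _lognormal(rng, mu, sigma, size):
    return rng.lognormal(mean=mu, sigma=sigma, size=size)


def generate_two_ecosystem_dataset(config: SimulationConfig):
    """Two-ecosystem vOTU abundance dataset with planted contrasts.

    Lagoon samples draw from ``n_votus_lagoon`` vOTUs and sea samples
    from ``n_votus_sea``; ``shared_fraction`` of the sea pool also occurs
    in the lagoon pool. Nonzero abundances are lognormal, with lagoon
    draws scaled by ``abundance_fold``.

    Returns (abundance matrix, metadata, ground truth).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_shared = int(round(config.shared_fraction * config.n_votus_sea))
    if n_shared > min(config.n_votus_lagoon, config.n_votus_sea):
        raise ValueError("shared_fraction implies more shared vOTUs than the "
                         "smaller pool holds")
    n_lagoon_only = config.n_votus_lagoon - n_shared
    n_sea_only = config.n_votus_sea - n_shared
    lagoon_only = [f"vOTU_L{i:05d}" for i in range(n_lagoon_only)]
    sea_only = [f"vOTU_S{i:05d}" for i in range(n_sea_only)]
    shared = [f"vOTU_X{i:05d}" for i in range(n_shared)]
    all_ids = lagoon_only + shared + sea_only
    origin = {**{v: "lagoon" for v in lagoon_only},
              **{v: "shared" for v in shared},
              **{v: "open_sea" for v in sea_only}}

    n = config.n_samples_per_group
    samples = [f"MM_{i:02d}" for i in range(n)] + [f"MED_{i:02d}" for i in range(n)]
    ecosystems = ["lagoon"] * n + ["open_sea"] * n
    matrix = np.zeros((len(all_ids), 2 * n))
    pools = {"lagoon": [v for v in all_ids if origin[v] != "open_sea"],
             "open_sea": [v for v in all_ids if origin[v] != "lagoon"]}
    index = {v: i for i, v in enumerate(all_ids)}
    for j, eco in enumerate(ecosystems):
        pool = pools[eco]
        detected = rng.random(len(pool)) < config.detection_prob
        vals = _lognormal(rng, config.lognormal_mu, config.lognormal_sigma,
                          len(pool))
        if eco == "lagoon":
            vals = vals * config.abundance_fold
        for v, det, x in zip(pool, detected, vals):
            if det:
                matrix[index[v], j] = x

    dates = list(_monthly_dates(n)) * 2
    metadata = pd.DataFrame({
        "ecosystem": ecosystems,
        "date": dates,
        "total_bases": rng.uniform(5e9, 1.5e10, size=2 * n),
    }, index=pd.Index(samples, name="sample_id"))
    abundance = pd.DataFrame(matrix, index=pd.Index(all_ids, name="votu_id"),
                             columns=samples)
    truth = GroundTruth(votu_ecosystem_origin=origin)
    return abundance, metadata, truth


def _occupancy_bins(t: int) -> dict[str, tuple[int, int]]:
    """Inclusive detection-count ranges of each dynamic class at T timepoints.

    The sporadic bin is empty (hi < lo) when no detection count satisfies
    0 < n/T < 0.25, e.g. at T = 4; callers fold its mixture weight into
    the intermittent class then.
    """
    spor_hi = int(np.ceil(0.25 * t)) - 1          # largest n with n/t < 0.25
    inter_hi = int(np.floor(0.75 * t))            # largest n with n/t <= 0.75
    return {"sporadic": (1, spor_hi),
            "intermittent": (max(spor_hi + 1, 1), inter_hi),
            "persistent": (inter_hi + 1, t)}


def generate_time_series(config: SimulationConfig):
    """Lagoon time series with planted occupancy classes, disturbances,
    smooth temporal turnover, and an environmental driver.

    Each vOTU gets a dynamic class from ``occupancy_mixture`` and a
    Gaussian temporal activity profile; its detected timepoints are the
    profile's top-``n_det`` points, so communities turn over smoothly
    and the Mantel correlation with time is positive by construction.
    At each disturbance timepoint an extra cohort of sporadic vOTUs
    (``disturbance_cohort_fraction`` of the pool) is detected only
    there. One environmental variable ("Iz_percent") is a linear
    combination of the first community axis and Gaussian noise scaled to
    ``env_signal_r2``; "temperature", "salinity" and "nitrate" are
    pure-noise decoys.

    Returns (abundance matrix, metadata, ground truth).
    """
    config.validate()
    if config.n_timepoints < 4:
        raise ValueError("n_timepoints must be >= 4 for a time series")
    rng = np.random.default_rng(config.seed)
    t = config.n_timepoints
    n = config.n_votus_lagoon
    bins = _occupancy_bins(t)
    classes = rng.choice(len(bins), size=n, p=np.asarray(config.occupancy_mixture))
    class_names = list(bins)

    ids = [f"vOTU_T{i:05d}" for i in range(n)]
    timegrid = np.arange(t, dtype=float)
    matrix = np.zeros((n, t))
    planted_class = {}
    for i, cls_idx in enumerate(classes):
        cls = class_names[cls_idx]
        lo, hi = bins[cls]
        if hi < lo:  # class unreachable at this T; fall back to intermittent
            cls = "intermittent"
            lo, hi = bins[cls]
        n_det = int(rng.integers(lo, hi + 1))
        peak = rng.uniform(0, t - 1)
        width = rng.uniform(t / 6, t / 2)
        profile = np.exp(-0.5 * ((timegrid - peak) / width) ** 2)
        top = np.argsort(-profile, kind="stable")[:n_det]
        base = _lognormal(rng, config.lognormal_mu, config.lognormal_sigma, 1)[0]
        matrix[i, top] = base * profile[top]
        planted_class[ids[i]] = cls

    # disturbance cohorts: sporadic vOTUs detected only at the event
    extra_rows = []
    extra_ids = []
    n_cohort = int(round(config.disturbance_cohort_fraction * n))
    cohort_class = "sporadic" if bins["sporadic"][1] >= 1 else "intermittent"
    for t_d in config.disturbance_timepoints:
        for c in range(n_cohort):
            vid = f"vOTU_D{t_d:02d}_{c:04d}"
            row = np.zeros(t)
            row[t_d] = _lognormal(rng, config.lognormal_mu,
                                  config.lognormal_sigma, 1)[0]
            extra_rows.append(row)
            extra_ids.append(vid)
            planted_class[vid] = cohort_class
    if extra_rows:
        matrix = np.vstack([matrix, np.array(extra_rows)])
        ids = ids + extra_ids

    samples = [f"MM_t{k:02d}" for k in range(t)]
    abundance = pd.DataFrame(matrix, index=pd.Index(ids, name="votu_id"),
                             columns=samples)

    # environmental driver tied to the leading community axis
    clr = clr_transform(abundance)
    ordination = pcoa(aitchison_distance(clr))
    axis1 = ordination.coordinates.iloc[:, 0].to_numpy()
    z = (axis1 - axis1.mean()) / axis1.std()
    r2 = config.env_signal_r2
    if r2 == 0:
        driver = rng.standard_normal(t)
    else:
        sigma = np.sqrt((1 - r2) / r2)
        driver = z + sigma * rng.standard_normal(t)
    metadata = pd.DataFrame({
        "ecosystem": "lagoon",
        "date": _monthly_dates(t),
        "total_bases": rng.uniform(5e9, 1.5e10, size=t),
        "Iz_percent": driver,
        "temperature": rng.standard_normal(t),
        "salinity": rng.standard_normal(t),
        "nitrate": rng.standard_normal(t),
    }, index=pd.Index(samples, name="sample_id"))

    truth = GroundTruth(
        votu_ecosystem_origin={v: "lagoon" for v in ids},
        planted_occupancy_class=planted_class,
        planted_env_driver_ids=["Iz_percent"],
    )
    return abundance, metadata, truth


@dataclass
class CoverageProfiles:
    """Per-position depth vectors and their tabular summary."""

    depths: dict
    summary: pd.DataFrame


def generate_coverage_profiles(n_contigs: int, lengths, seed: int,
                               breadths=None, mean_depth: float = 4.0,
                               total_bases: float = 1e9,
                               sample_id: str = "S1") -> CoverageProfiles:
    """Per-position coverage with controllable breadth, plus the summary.

    Each contig gets a target breadth (drawn uniformly from [0.3, 1] when
    not given); that fraction of its positions is chosen at random and
    assigned Poisson(``mean_depth``) depths (shifted to ≥1), the rest are
    zero. The summary carries the per-sample total bases needed by the
    normalization step.
    """
    lengths = [int(x) for x in lengths]
    if len(lengths) != n_contigs:
        raise ValueError("lengths must have one entry per contig")
    if any(x < 1 for x in lengths):
        raise ValueError("contig lengths must be >= 1 bp")
    rng = np.random.default_rng(seed)
    if breadths is None:
        breadths = rng.uniform(0.3, 1.0, size=n_contigs)
    else:
        breadths = np.asarray(breadths, dtype=float)
        if breadths.shape != (n_contigs,):
            raise ValueError("breadths must have one entry per contig")
    depths = {}
    rows = []
    from .abundance import breadth_of_coverage, trimmed_mean
    for i, (length, target) in enumerate(zip(lengths, breadths)):
        cid = f"contig_{i:04d}"
        depth = np.zeros(length)
        n_cov = int(round(target * length))
        if n_cov > 0:
            pos = rng.choice(length, size=n_cov, replace=False)
            depth[pos] = 1 + rng.poisson(max(mean_depth - 1, 0), size=n_cov)
        depths[cid] = depth
        rows.append({"contig_id": cid, "sample_id": sample_id,
                     "contig_length": length,
                     "breadth": breadth_of_coverage(depth),
                     "trimmed_mean_depth": trimmed_mean(depth),
                     "total_bases": total_bases})
    return CoverageProfiles(depths=depths, summary=pd.DataFrame(rows))


@dataclass
class AnnotationConfig:
    """Planted annotation frequencies, per ecosystem group.

    ``avg_category_probs`` and ``host_probs`` map category/genus →
    {group: probability}; ``temperate_fraction`` maps group →
    probability that a vOTU is flagged temperate.
    """

    seed: int = 0
    temperate_fraction: dict = field(default_factory=lambda: {
        "lagoon": 0.08, "open_sea": 0.08})
    host_assignment_rate: float = 0.12
    host_probs: dict = field(default_factory=lambda: {
        "Vibrio": {"lagoon": 0.35, "open_sea": 0.10},
        "Aurantivirga": {"lagoon": 0.25, "open_sea": 0.10},
        "Pelagibacter": {"lagoon": 0.20, "open_sea": 0.55},
        "Synechococcus_C": {"lagoon": 0.20, "open_sea": 0.25},
    })
    avg_category_probs: dict = field(default_factory=lambda: {
        "DNA_methyltransferase": {"lagoon": 0.08, "open_sea": 0.03},
        "2OG_FeII_oxygenase": {"lagoon": 0.07, "open_sea": 0.02},
        "heme_biosynthesis": {"lagoon": 0.02, "open_sea": 0.06},
        "LPS_biosynthesis": {"lagoon": 0.02, "open_sea": 0.06},
    })


def generate_annotations(votu_ids, groups, config: AnnotationConfig):
    """vOTU-level annotation table with planted group enrichments.

    ``groups`` maps (or lists, aligned with ``votu_ids``) each vOTU to an
    ecosystem group; host genera, temperate flags and AVG categories are
    drawn independently at the per-group planted frequencies, so every
    frequency is recoverable within binomial error.

    Returns (annotation table, ground truth).
    """
    votu_ids = list(votu_ids)
    if not votu_ids:
        raise ValueError("votu_ids must be non-empty")
    if not isinstance(groups, dict):
        groups = dict(zip(votu_ids, groups))
    rng = np.random.default_rng(config.seed)
    genera = list(config.host_probs)
    avg_cats = list(config.avg_category_probs)
    rows = []
    for vid in votu_ids:
        grp = groups[vid]
        temperate = bool(rng.random() < config.temperate_fraction.get(grp, 0.0))
        host = None
        if rng.random() < config.host_assignment_rate and genera:
            weights = np.array([config.host_probs[g].get(grp, 0.0)
                                for g in genera])
            if weights.sum() > 0:
                host = genera[rng.choice(len(genera),
                                         p=weights / weights.sum())]
        cats = [c for c in avg_cats
                if rng.random() < config.avg_category_probs[c].get(grp, 0.0)]
        rows.append({"votu_id": vid, "temperate": temperate,
                     "host_genus": host,
                     "avg_categories": ";".join(cats)})
    table = pd.DataFrame(rows).set_index("votu_id")
    enriched = {}
    for grp in set(groups.values()):
        others = [g for g in set(groups.values()) if g != grp]
        cats = []
        for c, probs in config.avg_category_probs.items():
            p_here = probs.get(grp, 0.0)
            if all(p_here > probs.get(o, 0.0) for o in others) and others:
                cats.append(c)
        enriched[grp] = cats
    truth = GroundTruth(votu_ecosystem_origin=dict(groups),
                        planted_enriched_categories=enriched)
    return table, truth
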