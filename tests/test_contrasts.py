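import numpy as np
import pandas as pd
import pytest

import virotu
from virotu.contrasts import carrier_percent

from _oracles import dice_percent_bruteforce


class TestSorensenDice:
    def test_identical_sets(self):
        res = virotu.sorensen_dice({"a", "b"}, {"a", "b"})
        assert res.dice_percent == 100.0

    def test_disjoint_sets(self):
        res = virotu.sorensen_dice({"a"}, {"b", "c"})
        assert res.dice_percent == 0.0

    def test_formula_evaluation(self):
        # |A|=3, |B|=5, shared 2 → 100×2/4 = 50
        res = virotu.sorensen_dice({"a", "b", "c"}, {"b", "c", "d", "e", "f"})
        assert res.dice_percent == pytest.approx(50.0)
        assert res.n_shared == 2

    def test_symmetry_and_classic_form(self, rng):
        for _ in range(50):
            a = set(rng.choice(100, size=rng.integers(1, 30), replace=False))
            b = set(rng.choice(100, size=rng.integers(1, 30), replace=False))
            ab = virotu.sorensen_dice(a, b).dice_percent
            ba = virotu.sorensen_dice(b, a).dice_percent
            assert ab == ba == pytest.approx(dice_percent_bruteforce(a, b))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            virotu.sorensen_dice(set(), {"a"})


class TestCallTemperate:
    def _evidence(self, **cols):
        defaults = {"recombinase_bitscore": [np.nan],
                    "lifestyle_probability": [np.nan],
                    "lifestyle_class": [None],
                    "quality_tier": ["low"]}
        defaults.update({k: list(v) for k, v in cols.items()})
        return pd.DataFrame(defaults)

    def test_bitscore_threshold_inclusive(self):
        assert virotu.call_temperate(
            self._evidence(recombinase_bitscore=[50.0])) == "temperate"
        assert virotu.call_temperate(
            self._evidence(recombinase_bitscore=[49.9])) == "undetermined"

    def test_lifestyle_probability_on_high_quality(self):
        ev = self._evidence(lifestyle_probability=[0.96],
                            lifestyle_class=["temperate"],
                            quality_tier=["high"])
        assert virotu.call_temperate(ev) == "temperate"

    def test_virulent_call(self):
        ev = self._evidence(lifestyle_probability=[0.99],
                            lifestyle_class=["virulent"],
                            quality_tier=["complete"])
        assert virotu.call_temperate(ev) == "virulent"

    def test_probability_on_low_quality_not_used(self):
        ev = self._evidence(lifestyle_probability=[0.99],
                            lifestyle_class=["temperate"],
                            quality_tier=["medium"])
        assert virotu.call_temperate(ev) == "undetermined"


class TestFilterAvgs:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "bit_score",
                                           "aux_score", "amg_flags"])

    @pytest.mark.parametrize("bit,aux,flags,kept", [
        (60.0, 3, "", True),     # all thresholds inclusive
        (60.0, 2, "V", False),   # V flag always dropped
        (60.0, 4, "", False),    # aux score above 3
        (59.9, 1, "", False),    # bit score below 60
        (80.0, 0, "MF", True),
    ])
    def test_retention_rules(self, bit, aux, flags, kept):
        out = virotu.filter_avgs(self._genes([("g1", bit, aux, flags)]))
        assert (len(out) == 1) is kept


class TestPropagation:
    def _clustering(self):
        sims = pd.DataFrame({"contig_a": ["A", "A"], "contig_b": ["B", "C"],
                             "ani_percent": [99.0, 99.0],
                             "aligned_fraction_shorter": [0.9, 0.9]})
        return virotu.cluster_votus({"A": 9000, "B": 8000, "C": 7000}, sims)

    def test_any_temperate_member_makes_votu_temperate(self):
        ann = pd.DataFrame({"contig_id": ["A", "B", "C"],
                            "temperate": [False, True, False],
                            "avg_categories": ["", "", ""]})
        out = virotu.propagate_contig_labels(ann, self._clustering())
        assert bool(out.loc["A", "temperate"])

    def test_avg_union_semantics(self):
        ann = pd.DataFrame({"contig_id": ["A", "B"],
                            "temperate": [False, False],
                            "avg_categories": ["X", "Y"]})
        out = virotu.propagate_contig_labels(ann, self._clustering())
        assert out.loc["A", "avg_categories"] == "X;Y"

    def test_unannotated_cluster_stays_unannotated(self):
        ann = pd.DataFrame({"contig_id": ["A"], "temperate": [False],
                            "avg_categories": [""]})
        sims = pd.DataFrame(columns=["contig_a", "contig_b", "ani_percent",
                                     "aligned_fraction_shorter"])
        cl = virotu.cluster_votus({"A": 9000, "Z": 5000}, sims)
        out = virotu.propagate_contig_labels(ann, cl)
        assert not out.loc["Z", "temperate"]
        assert out.loc["Z", "avg_categories"] == ""

    def test_idempotent(self):
        ann = pd.DataFrame({"contig_id": ["A", "B", "C"],
                            "temperate": [False, True, False],
                            "avg_categories": ["X", "Y", ""],
                            "host_genus": ["Vibrio", None, None]})
        cl = self._clustering()
        once = virotu.propagate_contig_labels(ann, cl)
        rep_cl = virotu.VotuClustering(
            representative_of={r: r for r in once.index},
            members={r: [r] for r in once.index})
        twice = virotu.propagate_contig_labels(
            once.reset_index().rename(columns={"votu_id": "contig_id"}), rep_cl)
        pd.testing.assert_frame_equal(
            once.drop(columns="n_member_contigs"),
            twice.drop(columns="n_member_contigs"))

    def test_unknown_contig_rejected(self):
        ann = pd.DataFrame({"contig_id": ["ZZ"], "temperate": [True],
                            "avg_categories": [""]})
        with pytest.raises(ValueError, match="ZZ"):
            virotu.propagate_contig_labels(ann, self._clustering())


class TestCarrierPercent:
    @pytest.mark.parametrize("carriers,total,expected", [
        (1754, 30637, 5.7),
        (0, 100, 0.0),
        (100, 100, 100.0),
    ])
    def test_known_values(self, carriers, total, expected):
        assert carrier_percent(carriers, total) == expected

    def test_from_annotation_table_order_invariant(self, rng):
        ann = pd.DataFrame({
            "avg_categories": ["X", "", "X;Y", "", ""],
        }, index=[f"v{i}" for i in range(5)])
        base = virotu.avg_carrier_percent(ann)
        shuffled = virotu.avg_carrier_percent(ann.sample(frac=1, random_state=1))
        assert base == shuffled == 40.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            carrier_percent(0, 0)


class TestPerSampleCategoryPercent:
    def _setup(self):
        mat = pd.DataFrame({"S1": [1.0, 2.0, 3.0, 4.0, 0.0],
                            "S2": [1.0, 0.0, 0.0, 0.0, 5.0]},
                           index=[f"v{i}" for i in range(5)])
        ann = pd.DataFrame({
            "temperate": [True, False, False, False, True],
            "avg_categories": ["X", "X", "Y", "", "Y"],
            "host_genus": [None] * 5,
            "lifestyle": ["temperate", "virulent", "virulent", "virulent",
                          "temperate"],
        }, index=mat.index)
        return mat, ann

    def test_counts_among_assigned(self):
        mat, ann = self._setup()
        out = virotu.per_sample_category_percent(mat, ann, "avg")
        # S1: assigned detected = v0 (X), v1 (X), v2 (Y) → X 66.7, Y 33.3
        assert out.loc["S1", "X"] == pytest.approx(200 / 3)
        assert out.loc["S1", "Y"] == pytest.approx(100 / 3)

    def test_absent_category_reported_as_zero(self):
        mat, ann = self._setup()
        out = virotu.per_sample_category_percent(mat, ann, "avg")
        # S2 detects v0 (X) and v4 (Y) only
        assert out.loc["S2", "X"] == pytest.approx(50.0)

    def test_all_temperate_sample(self):
        mat = pd.DataFrame({"S1": [1.0, 2.0]}, index=["a", "b"])
        ann = pd.DataFrame({"temperate": [True, True],
                            "lifestyle": ["temperate", "temperate"],
                            "avg_categories": ["", ""],
                            "host_genus": [None, None]}, index=mat.index)
        out = virotu.per_sample_category_percent(mat, ann, "strategy")
        assert out.loc["S1", "temperate"] == 100.0


class TestEffectSizeContrast:
    def _planted(self, seed, n=800, delta_cat="DNA_methyltransferase"):
        cfg = virotu.SimulationConfig(seed=seed, n_votus_lagoon=n,
                                      n_votus_sea=n, shared_fraction=0.0,
                                      abundance_fold=1.0)
        mat, md, truth = virotu.generate_two_ecosystem_dataset(cfg)
        groups = {v: ("open_sea" if o == "open_sea" else "lagoon")
                  for v, o in truth.votu_ecosystem_origin.items()}
        ann, _ = virotu.generate_annotations(mat.index, groups,
                                             virotu.AnnotationConfig(seed=seed))
        return mat, md, ann, delta_cat

    def test_small_category_excluded(self):
        mat = pd.DataFrame(np.ones((8, 6)),
                           index=[f"v{i}" for i in range(8)],
                           columns=[f"s{i}" for i in range(6)])
        md = pd.DataFrame({"ecosystem": ["lagoon"] * 3 + ["open_sea"] * 3,
                           "date": pd.Timestamp("2020-01-01"),
                           "total_bases": 1e9},
                          index=mat.columns)
        ann = pd.DataFrame({"avg_categories": ["X"] * 4 + [""] * 4,
                            "temperate": False, "host_genus": None},
                           index=mat.index)
        out = virotu.effect_size_contrast(mat, ann, md, "avg")
        assert not out.loc["X", "included"]
        assert "5 vOTUs" in out.loc["X", "excluded_reason"]

    def test_identical_distributions_excluded_by_effect_filter(self):
        mat = pd.DataFrame(np.ones((12, 6)),
                           index=[f"v{i}" for i in range(12)],
                           columns=[f"s{i}" for i in range(6)])
        md = pd.DataFrame({"ecosystem": ["lagoon"] * 3 + ["open_sea"] * 3,
                           "date": pd.Timestamp("2020-01-01"),
                           "total_bases": 1e9},
                          index=mat.columns)
        ann = pd.DataFrame({"avg_categories": ["X"] * 12,
                            "temperate": False, "host_genus": None},
                           index=mat.index)
        out = virotu.effect_size_contrast(mat, ann, md, "avg")
        assert out.loc["X", "effect_size"] == 0.0
        assert not out.loc["X", "included"]

    def test_planted_enrichment_recovered(self):
        """The +5-point planted AVG enrichment yields a positive effect
        size with adjusted p ≤ 0.05 in most seeds."""
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            mat, md, ann, cat = self._planted(seed)
            out = virotu.effect_size_contrast(mat, ann, md, "avg",
                                              denominator="all")
            row = out.loc[cat]
            hits += (row["effect_size"] > 0 and row["included"]
                     and row["p_adjusted"] <= 0.05)
        assert hits >= 0.9 * n_seeds

    def test_exclude_shared_noop_when_disjoint(self):
        mat, md, ann, _ = self._planted(0, n=100)
        a = virotu.effect_size_contrast(mat, ann, md, "avg",
                                        exclude_shared=False)
        b = virotu.effect_size_contrast(mat, ann, md, "avg",
                                        exclude_shared=True)
        pd.testing.assert_frame_equal(a, b)


class TestSpearman:
    def test_perfect_and_inverse(self):
        res = virotu.spearman_env_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(1.0)
        res = virotu.spearman_env_correlation([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.statistic == pytest.approx(-1.0)

    def test_exact_rank_formula(self):
        # Σd² = 2 → ρ = 1 − 12/60 = 0.8
        res = virotu.spearman_env_correlation([1, 2, 3, 4], [1, 2, 4, 3])
        assert res.statistic == pytest.approx(0.8)

    def test_constant_series_flagged(self):
        res = virotu.spearman_env_correlation([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.extra["degenerate"]


class TestHeatmapMatrix:
    def test_log_transform_values(self):
        mat = pd.DataFrame({"t1": [0.0, 9.0]}, index=["a", "b"])
        logged, order = virotu.heatmap_matrix(mat)
        assert logged.loc["a", "t1"] == 0.0
        assert logged.loc["b", "t1"] == pytest.approx(1.0)

    def test_identical_rows_adjacent(self):
        mat = pd.DataFrame([[1.0, 2.0], [9.0, 5.0], [1.0, 2.0]],
                           index=["a", "b", "c"], columns=["t1", "t2"])
        _, order = virotu.heatmap_matrix(mat)
        pos = {r: i for i, r in enumerate(order)}
        assert abs(pos["a"] - pos["c"]) == 1
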