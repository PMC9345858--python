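import numpy as np
import pandas as pd
import pytest

from tcellprox.cell_io import Marker, Region
from tcellprox.exceptions import ConfigError, ConsistencyError, ValidationError
from tcellprox.scoring import (
    COMPONENT_KEYS,
    Category,
    ComponentMatrix,
    Measure,
    PercentileReference,
    ScoreConfig,
    aggregate_components,
    categorize_score,
    component_key,
    composite_score,
    core_measures,
    cross_classify,
    percentile_transform,
    quartile_categories,
    score_patients,
)
from tcellprox.synthetic_data import SyntheticCoreParams, simulate_core


def components_from(values: dict, measure=Measure.DENSITY) -> ComponentMatrix:
    df = pd.DataFrame(values).T
    df.columns = COMPONENT_KEYS
    return ComponentMatrix(values=df, measure=measure,
                           radius=20.0 if measure == Measure.G_AT_R else None)


class TestAggregation:
    def _core_values(self):
        return pd.DataFrame(
            {
                "patient_id": ["P1"] * 5 + ["P2"] * 4,
                "marker": ["CD3", "CD3", "CD3", "CD8", "CD8",
                           "CD3", "CD3", "CD8", "CD8"],
                "region": ["CT", "CT", "IM", "CT", "IM", "CT", "IM", "CT", "IM"],
                "core_id": list("abcdefghi"),
                "value": [100.0, 200.0, 50.0, 70.0, 80.0, 10.0, 20.0, 30.0, 40.0],
            }
        )

    def test_multi_core_components_are_averaged(self):
        cm = aggregate_components(self._core_values(), Measure.DENSITY)
        assert cm.values.loc["P1", "CD3_CT"] == pytest.approx(150.0)
        assert cm.values.loc["P1", "CD3_IM"] == pytest.approx(50.0)
        assert cm.values.loc["P2", "CD8_IM"] == pytest.approx(40.0)

    def test_missing_component_is_an_internal_error(self):
        broken = self._core_values().iloc[:-1]  # P2 loses CD8/IM
        with pytest.raises(ConsistencyError):
            aggregate_components(broken, Measure.DENSITY)

    def test_g_values_averaged_same_as_densities(self):
        cv = self._core_values()
        cv["value"] = [0.2, 0.4, 0.5, 0.3, 0.6, 0.1, 0.2, 0.3, 0.4]
        cm = aggregate_components(cv, Measure.G_AT_R, radius=20.0)
        assert cm.values.loc["P1", "CD3_CT"] == pytest.approx(0.3)


class TestPercentileTransform:
    def test_rank_definition_on_1_to_100(self):
        ref = np.arange(1.0, 101.0)
        assert percentile_transform(50.0, ref) == pytest.approx(50.0)
        assert percentile_transform(0.5, ref) == 0.0
        assert percentile_transform(100.0, ref) == 100.0
        assert percentile_transform(1000.0, ref) == 100.0

    def test_ties_counted_as_less_or_equal(self):
        ref = np.array([1.0, 2.0, 2.0, 3.0])
        assert percentile_transform(2.0, ref) == pytest.approx(75.0)

    def test_non_finite_value_rejected(self):
        with pytest.raises(ValidationError):
            percentile_transform(np.nan, np.array([1.0, 2.0]))

    def test_self_reference_identity(self, rng):
        ref = np.sort(rng.normal(size=50))
        pct = [percentile_transform(v, ref) for v in ref]
        np.testing.assert_allclose(pct, 100 * np.arange(1, 51) / 50)

    def test_rank_invariance_under_monotone_transform(self, rng):
        values = rng.normal(size=30)
        ref = rng.normal(size=80)
        f = lambda x: np.expm1(2 * x) + 0.5 * x  # strictly increasing
        before = [percentile_transform(v, np.sort(ref)) for v in values]
        after = [percentile_transform(fv, np.sort(f(ref))) for fv in f(values)]
        np.testing.assert_allclose(before, after)


class TestCompositeAndCategories:
    def test_mean_of_four(self):
        assert composite_score([80, 90, 70, 60]) == pytest.approx(75.0)
        assert composite_score([0, 0, 0, 0]) == 0.0
        assert composite_score([100, 100, 100, 100]) == 100.0

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValidationError):
            composite_score([50, 50, 50])

    @pytest.mark.parametrize(
        "score,expected",
        [
            (0.0, Category.LOW),
            (25.0, Category.LOW),            # low band closes at 25
            (25.000001, Category.INTERMEDIATE),
            (70.0, Category.INTERMEDIATE),   # intermediate closes at 70
            (70.000001, Category.HIGH),
            (75.0, Category.HIGH),
            (100.0, Category.HIGH),
        ],
    )
    def test_band_boundaries(self, score, expected):
        assert categorize_score(score) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            categorize_score(101.0)

    def test_categories_partition_the_scale(self, rng):
        for s in rng.uniform(0, 100, 200):
            assert categorize_score(float(s)) in Category

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            ScoreConfig(low_max=80, intermediate_max=70)


class TestQuartiles:
    def test_even_split_1_to_8(self):
        labels = quartile_categories([1, 2, 3, 4, 5, 6, 7, 8])
        assert labels == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_983_values_split_246_246_246_245(self):
        labels = quartile_categories(np.arange(983, dtype=float))
        counts = pd.Series(labels).value_counts()
        assert counts["Q1"] == 246 and counts["Q2"] == 246
        assert counts["Q3"] == 246 and counts["Q4"] == 245

    def test_ties_go_to_lower_quartile(self):
        labels = quartile_categories([1, 1, 1, 2, 3, 4, 5, 6])
        assert labels[:3] == ["Q1", "Q1", "Q1"]

    def test_degenerate_all_equal_warns_all_q1(self):
        with pytest.warns(UserWarning, match="degenerate"):
            labels = quartile_categories([5.0] * 8)
        assert set(labels) == {"Q1"}


class TestCrossClassify:
    @pytest.mark.parametrize(
        "prox,dens,expected",
        [
            (Category.HIGH, Category.HIGH, "prox+/dens+"),
            (Category.LOW, Category.LOW, "prox-/dens-"),
            (Category.HIGH, Category.INTERMEDIATE, "prox+/dens+"),
            (Category.LOW, Category.INTERMEDIATE, "prox-/dens+"),
        ],
    )
    def test_default_dichotomisation(self, prox, dens, expected):
        assert cross_classify(prox, dens) == expected

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ConfigError):
            cross_classify(Category.LOW, Category.LOW, scheme="nonsense")


class TestScorePatients:
    def _perfectly_correlated(self, n=100):
        vals = np.arange(1.0, n + 1.0)
        data = {f"P{i:03d}": [v, v, v, v] for i, v in enumerate(vals)}
        return components_from(data), components_from(
            {k: [10 * x for x in v] for k, v in
             {f"P{i:03d}": [v] * 4 for i, v in enumerate(vals)}.items()}
        )

    def test_identical_components_give_exact_category_split(self):
        g, d = self._perfectly_correlated(100)
        scores = score_patients(g, d)
        counts = scores["proximity_category"].value_counts()
        assert counts["LOW"] == 25
        assert counts["INTERMEDIATE"] == 45
        assert counts["HIGH"] == 30

    def test_external_reference_mode(self):
        g, d = self._perfectly_correlated(20)
        ref_g = PercentileReference.from_components(g)
        ref_d = PercentileReference.from_components(d)
        # shift every value above the reference maximum -> all percentiles 100
        g2 = ComponentMatrix(g.values + 1000.0, Measure.DENSITY)
        d2 = ComponentMatrix(d.values + 1e6, Measure.DENSITY)
        scores = score_patients(g2, d2, g_reference=ref_g, density_reference=ref_d)
        assert (scores["proximity_score"] == 100.0).all()
        assert (scores["proximity_category"] == "HIGH").all()

    def test_reference_round_trip_through_csv(self, tmp_path):
        g, _ = self._perfectly_correlated(10)
        ref = PercentileReference.from_components(g)
        path = ref.save(tmp_path / "ref.csv")
        back = PercentileReference.load(path)
        for key in COMPONENT_KEYS:
            np.testing.assert_allclose(back.values[key], ref.values[key])

    def test_score_columns_complete(self):
        g, d = self._perfectly_correlated(8)
        scores = score_patients(g, d)
        for col in ("proximity_score", "density_score", "proximity_category",
                    "density_category", "combined_subgroup"):
            assert col in scores.columns
        for key in COMPONENT_KEYS:
            assert f"gcross_{key}_pct" in scores.columns
            assert f"density_{key}_quartile" in scores.columns


class TestCoreMeasures:
    def test_pooled_vs_per_core_modes(self):
        cores = [
            simulate_core(
                SyntheticCoreParams(seed=s, rho=0.5, lambda_t=300.0),
                core_id=f"c{s}", patient_id="P1",
                region=Region.CT, marker=Marker.CD3,
            )
            for s in (1, 2)
        ]
        per_core = core_measures(cores, Measure.G_AT_R, radius=20.0)
        pooled = core_measures(cores, Measure.G_AT_R, radius=20.0, pool_cores=True)
        assert len(per_core) == 2 and len(pooled) == 1
        # both estimate the same quantity from the same cells
        assert pooled["value"].iloc[0] == pytest.approx(per_core["value"].mean(), abs=0.05)

    def test_component_key_layout(self):
        assert component_key(Marker.CD3, Region.CT) == "CD3_CT"
        assert COMPONENT_KEYS == ["CD3_CT", "CD3_IM", "CD8_CT", "CD8_IM"]
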