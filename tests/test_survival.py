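import numpy as np
import pandas as pd
import pytest

from tcellprox.exceptions import FitError, ValidationError
from tcellprox.spatial_stats import NNDistanceData, gcross_from_distances, evaluate_g_at
from tcellprox.survival import (
    DAYS_PER_YEAR,
    km_logrank,
    ph_fit,
    result_to_frame,
    subgroup_and_interaction,
    truncate_followup,
)


def simulate_records(rng, n, beta=0.0, *, weights=(0.25, 0.45, 0.30),
                     h0=0.08, censor_rate=0.03, horizon=15.0, covariate=False):
    """Exponential survival with ordinal category exposure."""
    g = rng.choice(3, p=list(weights), size=n)
    rate = h0 * np.exp(beta * g)
    t = rng.exponential(1.0 / rate)
    c = np.minimum(rng.exponential(1.0 / censor_rate, size=n), horizon)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "time_days": np.minimum(t, c) * DAYS_PER_YEAR,
            "event_css": (t <= c).astype(int),
            "category": pd.Categorical.from_codes(g, ["LOW", "INTERMEDIATE", "HIGH"]),
        }
    )
    df["event_os"] = df["event_css"]
    if covariate:
        df["mmr"] = rng.choice(["proficient", "deficient"], p=[0.85, 0.15], size=n)
    return df


CAT_LEVELS = {"category": ("LOW", "INTERMEDIATE", "HIGH")}


class TestTruncateFollowup:
    def test_event_beyond_horizon_becomes_censored(self):
        df = pd.DataFrame({"time_days": [12 * DAYS_PER_YEAR], "event_css": [1],
                           "event_os": [1]})
        out = truncate_followup(df, 10.0)
        assert out["time_days"].iloc[0] == pytest.approx(10 * DAYS_PER_YEAR)
        assert out["event_css"].iloc[0] == 0 and out["event_os"].iloc[0] == 0

    def test_below_horizon_unchanged(self):
        df = pd.DataFrame({"time_days": [8 * DAYS_PER_YEAR], "event_css": [1],
                           "event_os": [1]})
        out = truncate_followup(df, 10.0)
        pd.testing.assert_frame_equal(out, df)

    def test_infinite_horizon_is_identity(self, rng):
        df = simulate_records(rng, 50)
        pd.testing.assert_frame_equal(truncate_followup(df, np.inf), df)

    def test_never_increases_time_or_creates_events(self, rng):
        df = simulate_records(rng, 200)
        out = truncate_followup(df, 5.0)
        assert (out["time_days"] <= df["time_days"]).all()
        assert (out["event_css"] <= df["event_css"]).all()


class TestKMLogrank:
    def test_identical_groups_statistic_zero(self):
        base = pd.DataFrame({"time_days": [100, 200, 300, 400],
                             "event_css": [1, 0, 1, 1], "event_os": [1, 0, 1, 1]})
        a = base.assign(group="A")
        b = base.assign(group="B")
        res = km_logrank(pd.concat([a, b], ignore_index=True), "group")
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_p_decreases_with_sample_size_under_separation(self, rng):
        ps = []
        for n in (40, 400):
            g = rng.integers(0, 2, n)
            t = rng.exponential(1.0 / (0.05 * np.exp(0.9 * g)))
            df = pd.DataFrame({"time_days": t * 365, "event_css": 1,
                               "event_os": 1, "group": g})
            ps.append(km_logrank(df, "group").p_value)
        assert ps[1] < ps[0]

    def test_single_group_rejected(self):
        df = pd.DataFrame({"time_days": [1, 2], "event_css": [1, 1],
                           "event_os": [1, 1], "group": ["A", "A"]})
        with pytest.raises(ValidationError):
            km_logrank(df, "group")

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time_days": [1, 2], "event_css": [0, 0],
                           "event_os": [0, 0], "group": ["A", "B"]})
        with pytest.raises(ValidationError, match="no events"):
            km_logrank(df, "group")

    def test_pooled_km_matches_g_estimator_kernel(self, rng):
        """The survival KM and the spatial G product-limit share one kernel.

        Feeding the same censored pairs to both, G(r) must equal 1 - S(r).
        """
        d = rng.exponential(50, size=60)
        b = rng.uniform(5, 120, size=60)
        curve = gcross_from_distances(NNDistanceData(d=d, b=b), "KM", n_tcell=1)
        t = np.minimum(d, b)
        df = pd.DataFrame({"time_days": t, "event_css": (d <= b).astype(int),
                           "event_os": (d <= b).astype(int),
                           "group": ["A"] * 30 + ["B"] * 30})
        res = km_logrank(df, "group")
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter().fit(t, d <= b)
        for r in (10, 30, 60, 100):
            s = float(kmf.survival_function_at_times(r).iloc[0])
            assert evaluate_g_at(curve, r) == pytest.approx(1 - s, abs=1e-12)


class TestPHFit:
    def test_matches_independent_partial_likelihood_oracle(self):
        """Frozen oracle: survival::coxph (Efron ties) on this exact dataset
        gives trend coef -0.33638313 (se 0.35810991) and indicator
        log-HRs 0.12723405 / -0.70797715."""
        rng = np.random.default_rng(42)
        n = 40
        x = rng.integers(0, 3, n)
        z = rng.integers(0, 2, n)
        t = rng.exponential(1 / (0.1 * np.exp(-0.4 * x + 0.3 * z)))
        c = rng.exponential(8.0, n)
        df = pd.DataFrame(
            {
                "time_days": np.minimum(t, c).round(3),
                "event_css": (t <= c).astype(int),
                "event_os": (t <= c).astype(int),
                "x": pd.Categorical.from_codes(x, ["L0", "L1", "L2"]),
                "z": z.astype(float),
            }
        )
        res = ph_fit(df, "x", adjust=["z"], level_map={"x": ("L0", "L1", "L2")})
        assert res.trend_coef["x"] == pytest.approx(-0.33638313, abs=1e-4)
        assert res.trend_se["x"] == pytest.approx(0.35810991, abs=1e-4)
        log_hr = np.log(res.table["hr"].to_numpy())
        np.testing.assert_allclose(log_hr, [0.0, 0.12723405, -0.70797715], atol=1e-4)

    def test_trend_coefficient_recovery(self, rng):
        df = simulate_records(rng, 1000, beta=-0.5)
        res = ph_fit(df, "category", level_map=CAT_LEVELS)
        coef, se = res.trend_coef["category"], res.trend_se["category"]
        assert abs(coef - (-0.5)) < 3 * se

    def test_reference_level_hr_is_one_and_counts_reported(self, rng):
        df = simulate_records(rng, 300, beta=-0.4)
        res = ph_fit(df, "category", level_map=CAT_LEVELS)
        table = res.table
        assert table.loc[table.level == "LOW", "hr"].iloc[0] == 1.0
        assert table["n"].sum() == 300
        assert table["events"].sum() == df["event_css"].sum()
        assert (table["ci_low"] <= table["hr"]).all()
        assert (table["hr"] <= table["ci_high"]).all()

    def test_missing_covariate_imputed_to_majority_with_count(self, rng):
        df = simulate_records(rng, 120, beta=-0.5, covariate=True)
        df.loc[3, "mmr"] = np.nan
        res = ph_fit(df, "category", adjust=["mmr"], level_map=CAT_LEVELS)
        assert res.n_imputed == {"mmr": 1}

    def test_constant_exposure_rejected(self, rng):
        df = simulate_records(rng, 50)
        df["category"] = "LOW"
        with pytest.raises(FitError):
            ph_fit(df, "category", level_map=CAT_LEVELS)

    def test_reciprocal_adjustment_two_exposures_one_model(self, rng):
        df = simulate_records(rng, 400, beta=-0.5)
        noisy = rng.permutation(df["category"].to_numpy())
        df["density_cat"] = pd.Categorical(noisy, ["LOW", "INTERMEDIATE", "HIGH"])
        res = ph_fit(
            df, ["category", "density_cat"],
            level_map=dict(CAT_LEVELS, density_cat=("LOW", "INTERMEDIATE", "HIGH")),
        )
        assert set(res.p_trend) == {"category", "density_cat"}
        assert set(res.table["variable"]) == {"category", "density_cat"}

    def test_result_frame_export(self, rng):
        df = simulate_records(rng, 200, beta=-0.5)
        frame = result_to_frame(ph_fit(df, "category", level_map=CAT_LEVELS))
        assert {"variable", "level", "hr", "p_trend", "endpoint"} <= set(frame.columns)


class TestSubgroupInteraction:
    def test_homogeneous_strata_agree(self, rng):
        df = simulate_records(rng, 1500, beta=-0.6, covariate=True)
        per_stratum, p_int = subgroup_and_interaction(
            df, "category", "mmr", level_map=CAT_LEVELS
        )
        coefs = [r.trend_coef["category"] for r in per_stratum.values()]
        assert len(coefs) == 2
        assert abs(coefs[0] - coefs[1]) < 0.5
        assert p_int > 0.005

    def test_generated_interaction_detected(self, rng):
        n = 2000
        strat = rng.integers(0, 2, n)
        g = rng.choice(3, p=[0.25, 0.45, 0.30], size=n)
        beta = np.where(strat == 1, 0.5, -0.5)
        t = rng.exponential(1.0 / (0.08 * np.exp(beta * g)))
        c = np.minimum(rng.exponential(30.0, size=n), 15.0)
        df = pd.DataFrame(
            {
                "time_days": np.minimum(t, c) * 365.25,
                "event_css": (t <= c).astype(int),
                "event_os": (t <= c).astype(int),
                "category": pd.Categorical.from_codes(g, ["LOW", "INTERMEDIATE", "HIGH"]),
                "stratum": np.where(strat == 1, "B", "A"),
            }
        )
        _, p_int = subgroup_and_interaction(
            df, "category", "stratum",
            level_map=dict(CAT_LEVELS, stratum=("A", "B")),
        )
        assert p_int < 0.001

    def test_single_level_stratifier_rejected(self, rng):
        df = simulate_records(rng, 60, covariate=True)
        df["mmr"] = "proficient"
        with pytest.raises(ValidationError):
            subgroup_and_interaction(df, "category", "mmr", level_map=CAT_LEVELS)
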