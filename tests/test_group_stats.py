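import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurocollin import (
    fit_subregion_model,
    generate_multilevel_dataset,
    quantile_normalize_by_slide,
)


def obs(values, slide="s1", subregion="CA1", case="c1"):
    return pd.DataFrame({"dev_deg": values, "slide_id": slide,
                         "subregion": subregion, "case_id": case})


class TestQuantileNormalize:
    def test_three_values_map_to_standard_normal_quartiles(self):
        out = quantile_normalize_by_slide(obs([1.0, 2.0, 3.0]))
        assert out["z"].to_numpy() == pytest.approx(
            [-0.6745, 0.0, 0.6745], abs=1e-3)

    def test_all_tied_values_map_to_zero(self):
        out = quantile_normalize_by_slide(obs([5.0] * 6))
        assert out["z"].to_numpy() == pytest.approx(np.zeros(6), abs=1e-12)

    def test_large_slide_matches_theoretical_quantiles(self, rng):
        out = quantile_normalize_by_slide(obs(rng.gamma(2.0, 10.0, size=500)))
        z = np.sort(out["z"].to_numpy())
        theo = stats.norm.ppf(np.arange(1, 501) / 501.0)
        assert np.corrcoef(z, theo)[0, 1] > 0.999

    def test_rank_preserving_within_slide(self, rng):
        vals = rng.uniform(0, 90, 40)
        out = quantile_normalize_by_slide(obs(vals))
        assert (np.argsort(out["z"].to_numpy()) == np.argsort(vals)).all()

    def test_slide_locality(self, rng):
        a = obs(rng.uniform(0, 90, 30), slide="s1")
        b = obs(rng.uniform(0, 90, 30), slide="s2")
        z_alone = quantile_normalize_by_slide(a)["z"].to_numpy()
        z_joint = quantile_normalize_by_slide(
            pd.concat([a, b], ignore_index=True))["z"].to_numpy()[:30]
        assert z_joint == pytest.approx(z_alone, abs=1e-12)

    def test_small_slide_skipped_with_warning(self):
        df = pd.concat([obs([1.0], slide="tiny"),
                        obs([1.0, 2.0, 3.0], slide="ok")], ignore_index=True)
        with pytest.warns(UserWarning, match="n < 2"):
            out = quantile_normalize_by_slide(df)
        assert np.isnan(out.loc[out.slide_id == "tiny", "z"]).all()
        assert out.loc[out.slide_id == "ok", "z"].notna().all()

    def test_offset_formula_variant(self):
        out = quantile_normalize_by_slide(obs([1.0, 2.0, 3.0]),
                                          formula="(r-0.5)/n")
        expected = stats.norm.ppf([0.5 / 3, 1.5 / 3, 2.5 / 3])
        assert out["z"].to_numpy() == pytest.approx(expected, abs=1e-9)


def _lme4_oracle_dataset():
    """400 observations with known crossed structure; fitted in lme4 the
    expected values below were frozen from its output."""
    rng = np.random.default_rng(1)
    n = 400
    cases = rng.integers(0, 7, n)
    slides = rng.integers(0, 5, n)
    sub = rng.integers(0, 8, n)
    u_c = rng.normal(0, 0.3, 7)
    u_s = rng.normal(0, 0.3, 5)
    eff = np.zeros(8)
    eff[3] = 0.5
    z = eff[sub] + u_c[cases] + u_s[slides] + rng.normal(0, 1, n)
    return pd.DataFrame({"z": z,
                         "subregion": [f"S{i}" for i in sub],
                         "case_id": [f"c{i}" for i in cases],
                         "slide_id": [f"l{i}" for i in slides]})


class TestMixedModel:
    def test_matches_frozen_lme4_fit(self):
        df = _lme4_oracle_dataset()
        res = fit_subregion_model(df)
        assert res.lrt_stat == pytest.approx(12.59175, abs=1e-3)
        fe = res.model.fe_params
        expected = {
            "Intercept": -0.28537686,
            "C(subregion)[T.S1]": -0.13724641,
            "C(subregion)[T.S2]": -0.25737644,
            "C(subregion)[T.S3]": 0.37444435,
            "C(subregion)[T.S4]": 0.03059052,
            "C(subregion)[T.S5]": -0.05047686,
            "C(subregion)[T.S6]": -0.09599227,
            "C(subregion)[T.S7]": -0.21122297,
        }
        for name, value in expected.items():
            assert fe[name] == pytest.approx(value, abs=1e-4)

    def test_contrast_count_is_k_choose_2(self):
        df = _lme4_oracle_dataset()
        res = fit_subregion_model(df)
        assert len(res.contrasts) == 8 * 7 // 2

    def test_null_data_contrast_estimates_near_zero(self):
        df = generate_multilevel_dataset(k_subregions=2, n_cases=4, n_slides=3,
                                         n_per_cell=60, seed=5)
        df = quantile_normalize_by_slide(df)
        res = fit_subregion_model(df)
        est = res.contrasts["estimate"].iloc[0]
        se = res.contrasts["std_error"].iloc[0]
        assert abs(est) < 3 * se

    def test_invariant_to_relabeling_group_ids(self):
        df = _lme4_oracle_dataset()
        res1 = fit_subregion_model(df)
        relabeled = df.copy()
        relabeled["case_id"] = relabeled["case_id"].map(
            {f"c{i}": f"zz{9 - i}" for i in range(7)})
        relabeled["slide_id"] = relabeled["slide_id"].map(
            {f"l{i}": f"qq{7 - i}" for i in range(5)})
        res2 = fit_subregion_model(relabeled)
        assert res2.lrt_stat == pytest.approx(res1.lrt_stat, abs=1e-5)

    def test_fewer_than_two_levels_rejected(self):
        df = obs(np.arange(10.0))
        df["z"] = np.arange(10.0)
        with pytest.raises(ValueError):
            fit_subregion_model(df)

    def test_effect_recovery_on_raw_scale(self):
        # 0.5 residual-SD shift (5 deg at sigma=10) recovered within 0.15 SD
        eff = [0.0, 5.0]
        df = generate_multilevel_dataset(k_subregions=2, n_cases=3, n_slides=2,
                                         effect_sizes=eff, n_per_cell=200,
                                         seed=21)
        res = fit_subregion_model(df, response="dev_deg")
        est = res.contrasts["estimate"].iloc[0]
        assert est == pytest.approx(5.0, abs=1.5)
        assert est > 0


class TestTukeyContrasts:
    def test_two_levels_adjusted_equals_unadjusted(self):
        df = generate_multilevel_dataset(k_subregions=2, n_cases=3, n_slides=3,
                                         n_per_cell=20, seed=3)
        df = quantile_normalize_by_slide(df)
        res = fit_subregion_model(df)
        c = res.contrasts
        assert c["p_adj"].iloc[0] == pytest.approx(c["p_unadj"].iloc[0])

    def test_adjusted_never_below_unadjusted(self):
        df = _lme4_oracle_dataset()
        res = fit_subregion_model(df)
        assert (res.contrasts["p_adj"] >= res.contrasts["p_unadj"] - 1e-12).all()

    def test_bonferroni_fallback_mode(self):
        df = _lme4_oracle_dataset()
        res = fit_subregion_model(df, adjust_method="bonferroni")
        c = res.contrasts
        assert np.allclose(c["p_adj"],
                           np.minimum(c["p_unadj"] * len(c), 1.0))

    def test_estimates_antisymmetric_under_pair_reversal(self):
        df = _lme4_oracle_dataset()
        res = fit_subregion_model(df)
        c = res.contrasts.set_index("pair")
        # S1 - S0 must equal -(difference computed the other way round)
        fe = res.model.fe_params
        assert c.loc["S1 - S0", "estimate"] == pytest.approx(
            fe["C(subregion)[T.S1]"])
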