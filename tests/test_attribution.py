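"""Driver-variance attribution: OLS fits, LMG shares, dominance, ternary."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import zoometals as zm
from zoometals.attribution import PREDICTORS, classify_dominance, ternary_coordinates
from zoometals.synthetic import _lmg_from_r2

from conftest import random_panel


def make_panel(x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(x, columns=list(PREDICTORS))
    df["response"] = y
    return df


class TestStandardize:
    def test_moments_and_idempotence(self, synthetic_panel):
        _, panel, _ = synthetic_panel
        out, record = zm.standardize(panel)
        for col in ("response", *PREDICTORS):
            assert out[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert out[col].std(ddof=1) == pytest.approx(1.0, rel=1e-12)
        again, _ = zm.standardize(out)
        pd.testing.assert_frame_equal(
            again[list(PREDICTORS)], out[list(PREDICTORS)], atol=1e-10
        )

    def test_transform_record_inverts(self, synthetic_panel):
        _, panel, _ = synthetic_panel
        out, record = zm.standardize(panel)
        mu, sd = record["fq"]
        back = out["fq"] * sd + mu
        assert np.allclose(back, panel["fq"])

    def test_zero_variance_column_named(self, synthetic_panel):
        _, panel, _ = synthetic_panel
        bad = panel.copy()
        bad["sst"] = 5.0
        with pytest.raises(ValueError, match="zero-variance column: sst"):
            zm.standardize(bad)


class TestFitGLM:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((200, 4))
        panel = make_panel(x, 2.0 * x[:, 0])
        fit = zm.fit_glm(panel)
        assert fit.coefficients["fq"] == pytest.approx(2.0, abs=1e-10)
        for p in ("prey_q", "sst", "zoo_b"):
            assert fit.coefficients[p] == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.greek["alpha"] == fit.coefficients["fq"]

    def test_pure_noise_r2_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((10000, 4))
        panel = make_panel(x, rng.standard_normal(10000))
        assert zm.fit_glm(panel).r_squared < 0.01

    def test_duplicate_predictor_raises(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((100, 4))
        x[:, 1] = x[:, 0]
        with pytest.raises(ValueError, match="collinear"):
            zm.fit_glm(make_panel(x, x.sum(axis=1)))

    def test_too_few_rows_rejected(self):
        x = np.eye(4)
        with pytest.raises(ValueError, match="at least"):
            zm.fit_glm(make_panel(x, np.ones(4)))

    def test_missing_values_rejected(self, synthetic_panel):
        _, panel, _ = synthetic_panel
        bad = panel.copy()
        bad.loc[3, "fq"] = np.nan
        with pytest.raises(ValueError, match="missing values"):
            zm.fit_glm(bad)


class TestLMG:
    def test_subset_weight_hand_example_p2(self):
        # two predictors with R2({1})=0.3, R2({2})=0.2, R2({1,2})=0.6:
        # averaging both orderings gives shares (0.35, 0.25)
        r2 = {(): 0.0, (0,): 0.3, (1,): 0.2, (0, 1): 0.6}
        shares = _lmg_from_r2(r2, 2)
        assert shares == pytest.approx([0.35, 0.25])

    def test_orthogonal_design_equals_squared_correlations(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((50000, 4))
        x -= x.mean(0)
        # orthogonalize exactly
        q, _ = np.linalg.qr(x)
        x = q * math.sqrt(len(q))
        y = x @ np.array([1.0, 0.5, -0.3, 0.0]) + rng.standard_normal(len(x))
        panel = make_panel(x, y)
        shares = zm.lmg_shares(panel)
        for j, p in enumerate(PREDICTORS):
            r = np.corrcoef(x[:, j], y)[0, 1]
            assert shares.shares[p] == pytest.approx(r * r, abs=1e-10)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle(self, seed):
        panel = random_panel(seed)
        a = zm.lmg_shares(panel)
        b = zm.lmg_shares_bruteforce(panel)
        for p in PREDICTORS:
            assert a.shares[p] == pytest.approx(b.shares[p], abs=1e-12)
        assert sum(a.shares.values()) == pytest.approx(a.r_squared, abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_shares_nonnegative_and_sum_to_r2(self, seed):
        panel = random_panel(seed + 100)
        shares = zm.lmg_shares(panel)
        assert all(v >= -1e-14 for v in shares.shares.values())
        assert sum(shares.shares.values()) == pytest.approx(shares.r_squared, abs=1e-10)

    def test_invariant_under_affine_rescaling(self):
        panel = random_panel(7)
        base = zm.lmg_shares(panel)
        scaled = panel.copy()
        scaled["fq"] = scaled["fq"] * 12.5 - 3.0
        scaled["zoo_b"] = scaled["zoo_b"] * -0.5 + 1.0
        scaled["response"] = scaled["response"] * 5.0 + 7.0
        other = zm.lmg_shares(scaled)
        for p in PREDICTORS:
            assert other.shares[p] == pytest.approx(base.shares[p], abs=1e-10)

    def test_population_recovery_at_large_n(self):
        spec = zm.PanelSpec(
            n_per_region=20000,
            coefficients=(2.0, -1.0, 0.5, 1.5),
            target_r2=0.6,
            seed=11,
        )
        panel, truth = zm.generate_driver_panel(spec)
        emp = zm.lmg_shares(panel)
        for p in PREDICTORS:
            assert emp.shares[p] == pytest.approx(
                truth.population_shares[p], abs=0.02
            )


class TestDominanceAndTernary:
    def test_normalize_by_hand(self):
        shares = zm.ImportanceShares(
            shares={"fq": 0.1, "prey_q": 0.2, "sst": 0.05, "zoo_b": 0.6},
            r_squared=0.95,
        )
        pt = classify_dominance(shares)
        assert (pt.qual, pt.quant, pt.zoo) == pytest.approx(
            (0.1 / 0.9, 0.2 / 0.9, 0.6 / 0.9)
        )
        assert pt.dominant == "zoo"
        assert pt.included and not pt.tie
        assert pt.temperature_share == pytest.approx(0.05)

    def test_low_r2_not_included(self):
        shares = zm.ImportanceShares(
            shares={"fq": 0.1, "prey_q": 0.1, "sst": 0.1, "zoo_b": 0.1},
            r_squared=0.4,
        )
        assert not classify_dominance(shares).included

    def test_equal_shares_centroid_and_tie(self):
        shares = zm.ImportanceShares(
            shares={"fq": 0.2, "prey_q": 0.2, "sst": 0.0, "zoo_b": 0.2},
            r_squared=0.6,
        )
        pt = classify_dominance(shares)
        assert (pt.qual, pt.quant, pt.zoo) == pytest.approx((1 / 3,) * 3)
        assert pt.tie and pt.dominant == "qual"  # fixed tie order

    def test_all_zero_biotic_shares_sentinel(self):
        shares = zm.ImportanceShares(
            shares={"fq": 0.0, "prey_q": 0.0, "sst": 0.8, "zoo_b": 0.0},
            r_squared=0.8,
        )
        pt = classify_dominance(shares)
        assert not pt.included and pt.dominant is None
        assert math.isnan(pt.qual)

    @pytest.mark.parametrize("coords,expected", [
        ((1, 0, 0), (0.0, 0.0)),
        ((0, 1, 0), (1.0, 0.0)),
        ((0, 0, 1), (0.5, math.sqrt(3) / 2)),
        ((1 / 3, 1 / 3, 1 / 3), (0.5, math.sqrt(3) / 6)),
    ])
    def test_ternary_embedding(self, coords, expected):
        pt = zm.TernaryPoint(*coords, 0.0, 1.0, True, None, False)
        assert ternary_coordinates(pt) == pytest.approx(expected)


class TestAttributeByGroup:
    def test_two_regions_with_distinct_dominance(self):
        cov = np.eye(4)
        spec = zm.PanelSpec(
            n_per_region=4000,
            regions=[zm.RegionSpec("A", np.zeros(4), cov),
                     zm.RegionSpec("B", np.zeros(4), cov)],
            coefficients=(3.0, 0.1, 0.1, 0.1),
            target_r2=0.8,
            seed=5,
        )
        panel_a, _ = zm.generate_driver_panel(spec)
        panel_a = panel_a[panel_a.region == "A"]
        spec_b = zm.PanelSpec(
            n_per_region=4000,
            regions=[zm.RegionSpec("B", np.zeros(4), cov)],
            coefficients=(0.1, 0.1, 0.1, 3.0),
            target_r2=0.8,
            seed=6,
        )
        panel_b, _ = zm.generate_driver_panel(spec_b)
        panel = pd.concat([panel_a, panel_b], ignore_index=True)
        res = zm.attribute_by_group(panel, by=["region"])
        dom = dict(zip(res.table["region"], res.table["dominant"]))
        assert dom == {"A": "qual", "B": "zoo"}

    def test_single_group_matches_direct_pipeline(self, synthetic_panel):
        _, panel, _ = synthetic_panel
        res = zm.attribute_by_group(panel, by=["region"])
        assert len(res.table) == 1
        direct = zm.lmg_shares(panel)
        for p in PREDICTORS:
            assert res.table.iloc[0][f"share_{p}"] == pytest.approx(
                direct.shares[p], abs=1e-12
            )

    def test_degenerate_group_reported_not_dropped(self, synthetic_panel):
        _, panel, _ = synthetic_panel
        bad = panel.copy()
        bad["region"] = "OK"
        frozen = panel.iloc[:50].copy()
        frozen["region"] = "FLAT"
        frozen["sst"] = 12.0
        res = zm.attribute_by_group(pd.concat([bad, frozen], ignore_index=True),
                                    by=["region"])
        assert list(res.table["region"]) == ["OK"]
        assert len(res.failures) == 1
        assert "zero-variance" in res.failures.iloc[0]["reason"]
        assert res.failures.iloc[0]["region"] == "FLAT"
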