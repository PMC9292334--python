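"""Box-model operators, integration, conservation and scaling laws."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import zoometals as zm
from zoometals.ecosystem import (
    EcosystemState,
    temperature_factor,
    trajectory_state_vector,
)
from zoometals.elements import DEFAULT_ELEMENT_PARAMS, ELEMENTS
from zoometals.experiments import order_check_setup


def biology_free_state(params, n=2e-3):
    d = {e: 1e-7 for e in ELEMENTS}
    return EcosystemState(
        n=n,
        d=d,
        p_c={"nano": 0.0, "diatom": 0.0},
        p_m={(g, e): 0.0 for g in ("nano", "diatom") for e in ELEMENTS},
        z_c=0.0,
        poc=0.0,
        pom={e: 0.0 for e in ELEMENTS},
    )


class TestTemperatureFactor:
    @pytest.mark.parametrize("t,q10,expected", [
        (20.0, 2.0, 1.0),
        (30.0, 2.0, 2.0),
        (10.0, 1.88, 1 / 1.88),
    ])
    def test_q10_scaling(self, t, q10, expected):
        assert temperature_factor(t, q10) == pytest.approx(expected)

    def test_invalid_q10(self):
        with pytest.raises(ValueError):
            temperature_factor(20.0, 0.0)


class TestGrowthRate:
    def test_unlimited_case(self, params):
        s = zm.initial_state(params)
        s.n = 1.0  # n >> k_n
        for e in ELEMENTS:
            s.p_m[("nano", e)] = params.elements[e].q_max_nano * s.p_c["nano"]
        mu = zm.growth_rate(s, params, t=20.0, group="nano")
        assert mu == pytest.approx(params.mu_max[0], rel=1e-3)

    def test_droop_floor(self, params):
        s = zm.initial_state(params)
        s.n = 1.0
        s.p_m[("nano", "Fe")] = params.fe_q_min * s.p_c["nano"]
        assert zm.growth_rate(s, params, t=20.0, group="nano") == 0.0

    def test_half_saturation(self, params):
        s = zm.initial_state(params)
        s.n = params.k_n[0]
        s.p_m[("nano", "Fe")] = params.elements["Fe"].q_max_nano * s.p_c["nano"]
        mu = zm.growth_rate(s, params, t=20.0, group="nano")
        assert mu == pytest.approx(0.5 * params.mu_max[0])


class TestMetalUptake:
    def test_quota_saturation(self, params):
        s = zm.initial_state(params)
        s.p_m[("nano", "Zn")] = params.elements["Zn"].q_max_nano * s.p_c["nano"]
        assert zm.metal_uptake(s, params, "nano", "Zn") == 0.0

    def test_no_substrate(self, params):
        s = zm.initial_state(params)
        s.d["Zn"] = 0.0
        assert zm.metal_uptake(s, params, "nano", "Zn") == 0.0

    def test_half_half_case(self, params):
        s = zm.initial_state(params)
        s.d["Zn"] = params.elements["Zn"].k_uptake
        s.p_m[("nano", "Zn")] = 0.5 * params.elements["Zn"].q_max_nano * s.p_c["nano"]
        v = zm.metal_uptake(s, params, "nano", "Zn")
        assert v == pytest.approx(params.v_max["Zn"][0] / 4)


class TestGrazing:
    def test_starvation(self, params):
        s = biology_free_state(params)
        s.z_c = 1e-3
        assert zm.grazing_fluxes(s, params, 20.0) == {
            "nano": 0.0, "diatom": 0.0, "poc": 0.0
        }

    def test_single_prey_saturation(self, params):
        s = biology_free_state(params)
        s.z_c = 1e-3
        s.p_c["nano"] = 10.0  # F >> k_g
        g = zm.grazing_fluxes(s, params, 20.0)
        assert g["nano"] == pytest.approx(params.g_max * s.z_c, rel=1e-3)

    def test_zero_preference_excludes_prey(self):
        p = dataclasses.replace(zm.EcosystemParams(), preferences=(1.0, 0.0, 0.0))
        s = biology_free_state(p)
        s.z_c = 1e-3
        s.p_c["nano"] = 1e-3
        s.p_c["diatom"] = 1e-3
        g = zm.grazing_fluxes(s, p, 20.0)
        assert g["diatom"] == 0.0 and g["poc"] == 0.0 and g["nano"] > 0


class TestZooBudget:
    def test_balanced_diet_assimilates_demand(self, params):
        ep = params.elements["Fe"]
        g = {"nano": 1e-3, "diatom": 0.0, "poc": 0.0}
        q = {"nano": ep.q_zoo, "diatom": 0.0, "poc": 0.0}  # food quality 1
        b = zm.zoo_budget(g, q, params, ep)
        demand = params.ae_c * 1e-3 * ep.q_zoo
        assert b.assimilated_m == pytest.approx(demand)
        assert b.dissolved_draw == pytest.approx(0.0, abs=1e-30)

    def test_metal_free_diet(self, params):
        ep = params.elements["Fe"]
        b = zm.zoo_budget([1e-3, 0, 0], [0.0, 0.0, 0.0], params, ep)
        assert b.assimilated_m == 0.0
        assert b.recycle_m == 0.0
        assert b.ingested_m == 0.0

    def test_hand_evaluated_min_budget(self, params):
        # prey quota 30e-6 against zoo quota 10e-6 at AE = 0.3
        ep = dataclasses.replace(params.elements["Fe"], ae_max=0.9, ae_shape=1.0)
        b = zm.zoo_budget([1e-3, 0, 0], [30e-6, 0.0, 0.0], params, ep)
        assert b.ingested_m == pytest.approx(3e-8)
        assert b.assimilated_m == pytest.approx(6e-9)  # capped at demand
        unassimilated = b.ingested_m - b.assimilated_m
        assert unassimilated == pytest.approx(2.4e-8)
        assert b.recycle_m + b.egest_m == pytest.approx(unassimilated)

    def test_zero_ingestion_all_zero(self, params):
        b = zm.zoo_budget([0, 0, 0], [1e-6, 1e-6, 1e-6], params, params.elements["Fe"])
        assert b.growth_c == b.recycle_c == b.recycle_m == 0.0

    def test_carbon_fully_partitioned(self, params):
        b = zm.zoo_budget([2e-3, 1e-3, 0.5e-3], [10e-6, 20e-6, 5e-6], params,
                          params.elements["Fe"])
        assert b.growth_c + b.recycle_c + b.egest_c == pytest.approx(3.5e-3)


class TestStep:
    def test_biology_free_closed_box_is_fixed_point(self, closed_box_params):
        s = biology_free_state(closed_box_params)
        s2, diag = zm.step(s, closed_box_params, zm.Forcing(), dt=0.25)
        assert s2.n == s.n
        assert s2.d == s.d
        assert diag.recycle_c == 0.0

    def test_sinking_only_exponential_decay(self, params):
        p = dataclasses.replace(
            params, lam_rem=0.0, kappa0=0.0, s_n=0.0,
            s_m={e: 0.0 for e in ELEMENTS},
        )
        s = biology_free_state(p)
        s.poc = 1e-3
        dt = 0.25
        s2, _ = zm.step(s, p, zm.Forcing(), dt=dt)
        exact = 1e-3 * np.exp(-p.lam_sink * dt)
        assert s2.poc == pytest.approx(exact, abs=1e-3 * (p.lam_sink * dt) ** 5)

    def test_diagnostics_match_python_reference(self, params, attractor_state):
        s = zm.ecosystem.state_from_vector(attractor_state)
        _, diag = zm.step(s, params, zm.Forcing(seasonal_amp=0.0), dt=0.25)
        g = zm.grazing_fluxes(s, params, 18.0)
        quotas = {
            e: {
                "nano": s.p_m[("nano", e)] / s.p_c["nano"],
                "diatom": s.p_m[("diatom", e)] / s.p_c["diatom"],
                "poc": s.pom[e] / s.poc,
            }
            for e in ELEMENTS
        }
        i_c = sum(g.values())
        assert diag.grazing_c == pytest.approx(i_c, rel=1e-12)
        assert diag.recycle_c == pytest.approx(
            params.sigma_diss * (1 - params.ae_c) * i_c, rel=1e-12
        )
        for e in ELEMENTS:
            b = zm.zoo_budget(g, quotas[e], params, params.elements[e])
            assert diag.recycle_m[e] == pytest.approx(b.recycle_m, rel=1e-9)

    def test_recycling_scales_linearly_with_zooplankton(self, params, attractor_state):
        s = zm.ecosystem.state_from_vector(attractor_state)
        _, d1 = zm.step(s, params, zm.Forcing(), dt=0.25)
        s.z_c *= 2.0
        _, d2 = zm.step(s, params, zm.Forcing(), dt=0.25)
        assert d2.recycle_c == pytest.approx(2 * d1.recycle_c, rel=1e-12)
        for e in ELEMENTS:
            assert d2.recycle_m[e] == pytest.approx(2 * d1.recycle_m[e], rel=1e-12)

    def test_invalid_state_raises_integration_error(self, params):
        y0 = np.zeros(31)
        y0[0] = np.nan
        with pytest.raises(zm.IntegrationError, match="pool n"):
            zm.run(params, zm.Forcing(), t_end=1.0, dt=0.25, state0=y0)


class TestRunAndBudget:
    def test_bitwise_determinism(self, params, forcing):
        t1 = zm.run(params, forcing, t_end=100.0, dt=0.25)
        t2 = zm.run(params, forcing, t_end=100.0, dt=0.25)
        assert np.array_equal(t1.recycle_m.values, t2.recycle_m.values)
        assert np.array_equal(t1.dissolved.values, t2.dissolved.values)

    def test_closed_box_conserves_inventories(self, closed_box_params, forcing):
        traj = zm.run(closed_box_params, forcing, t_end=20 * 365.0, dt=0.25)
        res = zm.budget_check(traj, closed_box_params)
        assert max(res.values()) < 1e-8

    def test_open_run_budget_closes(self, short_trajectory, params):
        res = zm.budget_check(short_trajectory, params)
        assert max(res.values()) < 1e-6

    def test_constant_source_linear_accumulation(self, closed_box_params, forcing):
        src = 1e-10
        p = dataclasses.replace(
            closed_box_params, s_m={e: (src if e == "Fe" else 0.0) for e in ELEMENTS}
        )
        traj = zm.run(p, forcing, t_end=365.0, dt=0.25)
        i = list(ELEMENTS).index("Fe")
        inv = (
            traj.dissolved.values[:, i]
            + traj.phyto_m.values[:, :, i].sum(axis=1)
            + traj.zoo_c.values * p.elements["Fe"].q_zoo
            + traj.pom.values[:, i]
        )
        assert inv[-1] - inv[0] == pytest.approx(src * 365.0, rel=1e-9)

    def test_quotas_never_exceed_maximum(self, short_trajectory, params):
        for gi, g in enumerate(("nano", "diatom")):
            pc = short_trajectory.phyto_c.values[:, gi]
            mask = pc > 1e-12
            for i, e in enumerate(ELEMENTS):
                q_max = (
                    params.elements[e].q_max_nano
                    if gi == 0
                    else params.elements[e].q_max_diatom
                )
                q = short_trajectory.phyto_m.values[mask, gi, i] / pc[mask]
                assert np.all(q <= q_max * (1 + 1e-9))

    def test_steady_state_independent_of_initial_condition(self, params):
        fc = zm.Forcing(seasonal_amp=0.0)
        a = zm.initial_state(params)
        b = zm.initial_state(params)
        b.n *= 2
        b.z_c *= 0.3
        for g in b.p_c:
            b.p_c[g] *= 2.5
        for k in b.p_m:
            b.p_m[k] *= 2.5
        ta = zm.run(params, fc, t_end=150 * 365.0, dt=0.25, save_every_days=365.0, state0=a)
        tb = zm.run(params, fc, t_end=150 * 365.0, dt=0.25, save_every_days=365.0, state0=b)
        va = trajectory_state_vector(ta, -1)[:25]
        vb = trajectory_state_vector(tb, -1)[:25]
        assert np.all(np.abs(va - vb) <= 1e-6 * np.maximum(np.abs(va), 1e-12))
        # and the steady state is genuinely steady year over year
        v_prev = trajectory_state_vector(ta, -2)[:25]
        assert np.all(np.abs(va - v_prev) <= 1e-10 * np.maximum(np.abs(va), 1e-12))

    def test_rk4_convergence_order(self):
        p, s0 = order_check_setup()
        f = zm.Forcing()
        spin = zm.run(p, f, t_end=10 * 365.0, dt=0.25, save_every_days=365.0, state0=s0)
        y0 = trajectory_state_vector(spin, -1)
        t0 = 10 * 365.0

        def final(dt):
            tr = zm.run(p, f, t_end=t0 + 365.0, t_start=t0, dt=dt,
                        save_every_days=365.0, state0=y0)
            return trajectory_state_vector(tr, -1)[:25]

        ref = final(0.125)
        e1 = np.linalg.norm(final(1.0) - ref)
        e2 = np.linalg.norm(final(0.5) - ref)
        assert 10.0 < e1 / e2 < 24.0  # ~16x per halving for RK4


class TestValidation:
    def test_negative_pool_rejected(self, params):
        s = zm.initial_state(params)
        s.n = -1.0
        with pytest.raises(ValueError, match=">= 0"):
            s.validate(params)

    def test_excess_quota_rejected(self, params):
        s = zm.initial_state(params)
        s.p_m[("nano", "Fe")] = 2 * params.elements["Fe"].q_max_nano * s.p_c["nano"]
        with pytest.raises(ValueError, match="quota"):
            s.validate(params)

    @pytest.mark.parametrize("kw", [
        {"ae_c": 1.5}, {"sigma_diss": 0.0}, {"preferences": (0.0, 0.0, 0.0)},
        {"g_max": -1.0}, {"fe_q_min": 1e-3},
    ])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            zm.EcosystemParams(**kw)
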