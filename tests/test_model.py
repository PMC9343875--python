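"""Core model: fluxes, mass balance, calibration, simulation, steady states."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from steatosim import (
    FA_PER_TG,
    MW_TG,
    BasalFluxAnchors,
    InterventionSpec,
    ModelState,
    calibrate_parameters,
    compute_fluxes,
    compute_observables,
    derive_basal_rate_constants,
    rhs,
    simulate,
    solve_steady_state,
)
from steatosim.model import OX_KM_FRAC, U_DNL_FLOOR, _flux_array, _rhs_array
from steatosim.registry import (
    DEFAULT_CALIBRATION_INPUTS,
    inputs_from_parameters,
    parameters_from_inputs,
)

FIRST_ORDER_CONSTANTS = (
    "k_est_cyt", "k_lip_cyt", "k_trans", "k_est_er", "k_lip_er",
    "k_clear", "k_reuptake",
)


def default_anchors(**overrides):
    d = {k: DEFAULT_CALIBRATION_INPUTS[k] for k in
         ("j_nefa", "j_dnl", "j_chylo", "v_lip_cyt", "v_lip_er",
          "v_vldl", "v_reuptake", "km_vldl")}
    d.update(overrides)
    return BasalFluxAnchors(**d)


def default_pools():
    return {k: DEFAULT_CALIBRATION_INPUTS[k] for k in
            ("fa_cyt_0", "tg_cyt_0", "fa_er_0", "tg_er_0", "tg_pl_0")}


class TestFluxes:
    def test_basal_fluxes_reproduce_every_anchor(self, base_params):
        """At the basal state with no intervention, each flux equals its anchor."""
        v = compute_fluxes(base_params.basal_state, base_params)
        anchors = inputs_from_parameters(base_params)
        assert v.v_uptake == pytest.approx(base_params.j_nefa, rel=1e-12)
        assert v.v_dnl == pytest.approx(base_params.j_dnl, rel=1e-12)
        assert v.v_chylo == pytest.approx(base_params.j_chylo, rel=1e-12)
        assert v.v_lip_cyt == pytest.approx(anchors["v_lip_cyt"], rel=1e-12)
        assert v.v_lip_er == pytest.approx(anchors["v_lip_er"], rel=1e-12)
        assert v.v_vldl == pytest.approx(anchors["v_vldl"], rel=1e-12)
        assert v.v_reuptake == pytest.approx(anchors["v_reuptake"], rel=1e-12)

    def test_vldl_half_saturation(self, base_params):
        state = base_params.basal_state
        state = ModelState(state.fa_cyt, state.tg_cyt, state.fa_er,
                           base_params.km_vldl, state.tg_pl)
        v = compute_fluxes(state, base_params)
        assert v.v_vldl == pytest.approx(base_params.vmax_vldl / 2, rel=1e-12)

    def test_nefa_uptake_scales_with_intervention(self, base_params):
        """A −28 % NEFA step cuts basal uptake to 0.72 of the input flux."""
        v = compute_fluxes(
            base_params.basal_state, base_params, InterventionSpec(u_nefa=0.72)
        )
        assert v.v_uptake == pytest.approx(0.72 * base_params.j_nefa, rel=1e-12)

    def test_invalid_state_rejected(self, base_params):
        bad = ModelState(-1.0, 1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError, match="invalid state"):
            compute_fluxes(bad, base_params)

    def test_full_dnl_inhibition_keeps_oxidation_finite(self, base_params):
        """The DNL scaling is floored inside the oxidation feedback term."""
        v0 = compute_fluxes(base_params.basal_state, base_params,
                            InterventionSpec(u_dnl=U_DNL_FLOOR))
        v = compute_fluxes(base_params.basal_state, base_params,
                           InterventionSpec(u_dnl=0.0))
        assert np.isfinite(v.v_ox)
        assert v.v_ox == pytest.approx(v0.v_ox, rel=1e-12)

    def test_feedback_directions(self, base_params):
        """More cytosolic FA suppresses uptake; more DNL suppresses oxidation."""
        s0 = base_params.basal_state
        s_hi = ModelState(2 * s0.fa_cyt, s0.tg_cyt, s0.fa_er, s0.tg_er, s0.tg_pl)
        assert (compute_fluxes(s_hi, base_params).v_uptake
                < compute_fluxes(s0, base_params).v_uptake)
        v_lo = compute_fluxes(s0, base_params, InterventionSpec(u_dnl=0.5))
        v_hi = compute_fluxes(s0, base_params, InterventionSpec(u_dnl=2.0))
        assert v_hi.v_ox < v_lo.v_ox

    def test_oxidation_shuts_off_with_substrate(self, base_params):
        """Demand-set oxidation is attenuated when cytosolic FA is scarce."""
        s0 = base_params.basal_state
        v0 = compute_fluxes(s0, base_params).v_ox
        s_lo = ModelState(OX_KM_FRAC * s0.fa_cyt / 10, s0.tg_cyt, s0.fa_er,
                          s0.tg_er, s0.tg_pl)
        assert compute_fluxes(s_lo, base_params).v_ox < 0.15 * v0


class TestMassBalance:
    def test_basal_state_is_steady(self, base_params):
        dy = rhs(base_params.basal_state, base_params)
        assert np.max(np.abs(dy)) / base_params.j_nefa < 1e-8

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        scales=st.tuples(*[st.floats(0.05, 20.0) for _ in range(5)]),
        u_vals=st.tuples(*[st.floats(0.0, 5.0) for _ in range(5)]),
    )
    def test_fa_equivalent_conservation(self, scales, u_vals):
        """FA-equivalent accumulation equals boundary influx minus outflux.

        3·(d tg_cyt + d tg_er + d tg_pl) + d fa_cyt + d fa_er must equal
        (v_uptake + v_dnl + 3 v_chylo) − (v_ox + 3 v_clear) at any state and
        any scalings: the internal esterification/lipolysis/transfer cycles
        conserve fatty-acid equivalents.
        """
        p = parameters_from_inputs(DEFAULT_CALIBRATION_INPUTS)
        y = p.basal_state.as_array() * np.asarray(scales)
        u = InterventionSpec(*(float(x) for x in u_vals), duration_days=1.0)
        dy = _rhs_array(y, p, u)
        v = dict(zip(
            ("v_uptake", "v_dnl", "v_ox", "v_est_cyt", "v_lip_cyt", "v_trans",
             "v_est_er", "v_lip_er", "v_vldl", "v_chylo", "v_clear", "v_reuptake"),
            _flux_array(y, p, u),
        ))
        lhs = FA_PER_TG * (dy[1] + dy[3] + dy[4]) + dy[0] + dy[2]
        boundary = (v["v_uptake"] + v["v_dnl"] + FA_PER_TG * v["v_chylo"]
                    - v["v_ox"] - FA_PER_TG * v["v_clear"])
        scale = max(abs(boundary), p.j_nefa)
        assert abs(lhs - boundary) < 1e-9 * scale

    def test_nefa_step_initially_drains_cytosolic_fa(self, base_params):
        dy = rhs(base_params.basal_state, base_params, InterventionSpec(u_nefa=0.72))
        assert dy[0] < 0.0


class TestCalibration:
    def test_round_trip_basal_fluxes(self):
        params = calibrate_parameters(
            default_pools(), default_anchors(), m_liver=1800.0, v_pl=30.0,
            gamma_up=0.2, gamma_ox=0.35,
        )
        v = compute_fluxes(params.basal_state, params)
        a = default_anchors()
        assert v.v_lip_cyt == pytest.approx(a.v_lip_cyt, rel=1e-12)
        assert v.v_lip_er == pytest.approx(a.v_lip_er, rel=1e-12)
        assert v.v_vldl == pytest.approx(a.v_vldl, rel=1e-12)
        assert v.v_reuptake == pytest.approx(a.v_reuptake, rel=1e-12)
        # implied oxidation balances the basal FA budget
        assert v.v_ox == pytest.approx(
            a.j_nefa + a.j_dnl + 3 * (a.v_reuptake - a.v_vldl), rel=1e-12
        )

    def test_inconsistent_oxidation_anchor_rejected(self):
        bad = default_anchors(v_ox=1.0)
        with pytest.raises(ValueError, match="inconsistent basal fluxes"):
            derive_basal_rate_constants(default_pools(), bad)

    def test_consistent_oxidation_anchor_accepted(self):
        a = default_anchors()
        v_ox = a.j_nefa + a.j_dnl + 3 * (a.v_reuptake - a.v_vldl)
        constants = derive_basal_rate_constants(
            default_pools(), default_anchors(v_ox=v_ox)
        )
        assert constants["k_ox"] == pytest.approx(v_ox, rel=1e-12)

    def test_negative_implied_clearance_rejected(self):
        a = default_anchors()
        bad = default_anchors(v_reuptake=a.v_vldl + a.j_chylo + 1.0)
        with pytest.raises(ValueError, match="not positive"):
            derive_basal_rate_constants(default_pools(), bad)

    def test_doubling_pools_halves_first_order_constants(self):
        k1 = derive_basal_rate_constants(default_pools(), default_anchors())
        pools2 = {k: 2 * v for k, v in default_pools().items()}
        k2 = derive_basal_rate_constants(pools2, default_anchors())
        for name in FIRST_ORDER_CONSTANTS:
            assert k2[name] == pytest.approx(k1[name] / 2, rel=1e-12)
        # the demand-set oxidation flux is pool-independent
        assert k2["k_ox"] == pytest.approx(k1["k_ox"], rel=1e-12)


class TestSimulation:
    def test_steady_state_holds_for_a_year(self, base_params):
        traj = simulate(base_params, t_end_days=365.0)
        drift = np.abs(traj.states / base_params.basal_state.as_array() - 1.0)
        assert drift.max() < 1e-6

    def test_rejects_nonpositive_horizon(self, base_params):
        with pytest.raises(ValueError):
            simulate(base_params, t_end_days=0.0)

    def test_long_integration_matches_root_solver(self, base_params):
        u = InterventionSpec(u_nefa=0.72)
        ss = solve_steady_state(base_params, u)
        traj = simulate(base_params, u, t_end_days=2000.0, t_eval=[0.0, 2000.0])
        assert np.max(np.abs(traj.states[-1] / ss.as_array() - 1.0)) < 1e-6

    def test_trajectory_frame_schema(self, base_params):
        df = simulate(base_params, t_end_days=10.0).to_dataframe()
        assert list(df.columns) == [
            "time_days", "fa_cyt", "tg_cyt", "fa_er", "tg_er", "tg_pl",
            "liver_fat_pct", "plasma_tg",
        ]


class TestSteadyState:
    def test_null_intervention_returns_basal(self, base_params):
        ss = solve_steady_state(base_params)
        assert np.allclose(
            ss.as_array(), base_params.basal_state.as_array(), rtol=1e-8
        )

    def test_gains_off_closed_form(self):
        """With both feedbacks off, the FA balance reduces to a quadratic.

        Substituting the plasma-TG balance into the cytosolic FA balance under
        u_dnl = 0.45 gives A + B·fa = k_ox·(1+κ)·fa/(κ·fa0 + fa) + k_trans·fa,
        a quadratic in fa solved independently here.
        """
        inputs = dict(DEFAULT_CALIBRATION_INPUTS, gamma_up=0.0, gamma_ox=0.0)
        p = parameters_from_inputs(inputs)
        u = InterventionSpec(u_dnl=0.45)
        kappa, fa0 = OX_KM_FRAC, p.fa_cyt_0
        A = (p.j_nefa + 0.45 * p.j_dnl
             + 3 * p.k_reuptake * p.j_chylo / (p.k_clear + p.k_reuptake))
        B = p.k_reuptake * p.k_trans / (p.k_clear + p.k_reuptake) - p.k_trans
        # (A + B·fa)(κ·fa0 + fa) − k_ox(1+κ)fa = 0
        coeffs = [B, A + B * kappa * fa0 - p.k_ox * (1 + kappa), A * kappa * fa0]
        roots = np.roots(coeffs)
        fa_expected = float(max(r.real for r in roots if abs(r.imag) < 1e-9 and r.real > 0))
        ss = solve_steady_state(p, u)
        assert ss.fa_cyt == pytest.approx(fa_expected, rel=1e-7)

    def test_vldl_activation_drains_er_with_bounded_export(self, base_params):
        u = InterventionSpec(u_vldl=20.0)
        ss = solve_steady_state(base_params, u)
        assert ss.tg_er < base_params.tg_er_0
        v = compute_fluxes(ss, base_params, u)
        assert v.v_vldl <= 20.0 * base_params.vmax_vldl
        assert ss.tg_pl < 2.0 * base_params.tg_pl_0


class TestObservables:
    def test_nafld_threshold_pool(self, base_params):
        """Liver TG equal to 5 % of liver mass reads exactly 5 % liver fat."""
        total_tg = 0.05 * base_params.m_liver / (MW_TG * 1e-6)
        s = ModelState(1.0, total_tg / 2, 1.0, total_tg / 2, 1.0)
        obs = compute_observables(s, base_params)
        assert obs.liver_fat_pct == pytest.approx(5.0, rel=1e-12)

    def test_plasma_volume_scaling(self, base_params):
        s = base_params.basal_state
        doubled = base_params.replace(v_pl=2 * base_params.v_pl)
        assert compute_observables(s, doubled).plasma_tg == pytest.approx(
            compute_observables(s, base_params).plasma_tg / 2, rel=1e-12
        )

    def test_liver_fat_vanishes_with_tg_pools(self, base_params):
        s = ModelState(1.0, 1e-9, 1.0, 1e-9, 1.0)
        assert compute_observables(s, base_params).liver_fat_pct < 1e-10
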