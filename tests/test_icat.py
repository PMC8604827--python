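import numpy as np
import pytest
from scipy.integrate import solve_ivp

from iapbpk import (
    DoseEvent,
    SimulationSettings,
    build_volumes,
    compute_metrics,
    healthy_knee_preset,
    mtx_pk_preset,
    mtx_preset,
    ra_knee_preset,
    simulate,
)
from iapbpk.icat import (
    cartilage_diffusion_rhs,
    dissolution_precipitation_rate,
    sf_cart_flux,
    synovial_blood_flow,
    synovium_fluxes,
    systemic_uptake_rate,
)


class TestVolumes:
    def test_vehicle_mixes_into_sf(self):
        dose = DoseEvent(route="IA", amount=5.0, vehicle_volume=2.0)
        assert build_volumes(healthy_knee_preset(), dose)["synovial_fluid"] == pytest.approx(4.21)
        ra = build_volumes(ra_knee_preset(), dose)
        assert ra["synovial_fluid"] == pytest.approx(32.0)
        assert 5.0 / ra["synovial_fluid"] * 1e3 == pytest.approx(156.25)  # µg/mL

    def test_no_vehicle_limit(self):
        dose = DoseEvent(route="IA", amount=5.0, vehicle_volume=0.0)
        assert build_volumes(healthy_knee_preset(), dose)["synovial_fluid"] == pytest.approx(2.21)

    def test_membrane_and_cartilage_volumes(self):
        v = build_volumes(healthy_knee_preset(), None)
        assert v["intima"] == pytest.approx(277 * 0.0018)
        assert v["subintima"] == pytest.approx(277 * 0.0282)
        assert v["cartilage_total"] == pytest.approx(148 * 0.25)
        assert v["cartilage_sublayer"] == pytest.approx(148 * 0.025)


class TestDissolutionPrecipitation:
    def test_case_study_solution_stays_inert(self):
        # 5 mg in 32 mL = 0.156 mg/mL, below the 0.16 mg/mL reference
        rate = dissolution_precipitation_rate(mtx_preset(), 0.0, 5.0, 32.0, 7.7)
        assert rate == 0.0

    def test_equilibrium_is_stationary(self):
        m = mtx_preset()
        sol = m.reference_solubility
        assert dissolution_precipitation_rate(m, 0.0, sol * 10.0, 10.0, 7.7) == 0.0

    def test_precipitation_rate_first_order_above_solubility(self):
        m = mtx_preset()
        s, v = m.reference_solubility, 10.0
        rate = dissolution_precipitation_rate(m, 0.0, 2 * s * v, v, 7.7)
        assert rate == pytest.approx(-s * v / 0.25)  # 900 s = 0.25 h

    def test_dissolution_positive_below_solubility(self):
        rate = dissolution_precipitation_rate(mtx_preset(), 4.0, 0.0, 10.0, 7.7)
        assert rate > 0


class TestFluxes:
    def test_sf_cart_flux_hand_product(self):
        # 1 µg/mL gradient, k = 9.6e-4 cm/s, SA = 148 cm^2 -> 0.511 mg/h
        assert sf_cart_flux(1e-3, 0.0, 9.6e-4, 148.0) == pytest.approx(0.5115, rel=1e-3)

    def test_flux_antisymmetry(self):
        a = sf_cart_flux(2.0e-3, 0.5e-3, 9.6e-4, 148.0)
        b = sf_cart_flux(0.5e-3, 2.0e-3, 9.6e-4, 148.0)
        assert a == pytest.approx(-b)
        assert sf_cart_flux(1e-3, 1e-3, 9.6e-4, 148.0) == 0.0

    def test_synovium_fluxes_hand_product_and_linearity(self):
        j1, j2 = synovium_fluxes(0.0, 1e-3, 0.0, 1.4e-3, 0.62e-5, 0.0282, 277.0)
        assert j2 == pytest.approx(0.2192, rel=1e-3)  # mg/h == 0.0609 µg/s
        j1d, j2d = synovium_fluxes(0.0, 1e-3, 0.0, 1.4e-3, 0.62e-5, 0.0282, 554.0)
        assert (j1d, j2d) == (pytest.approx(2 * j1), pytest.approx(2 * j2))
        assert synovium_fluxes(1e-3, 1e-3, 1e-3, 1.4e-3, 0.62e-5, 0.0282, 277.0) == (0.0, 0.0)

    def test_systemic_uptake_partition_zero_point(self):
        assert systemic_uptake_rate(0.66e-6, 1e-6, 314.0, 0.79, 0.66) == pytest.approx(0.0)
        q = synovial_blood_flow(healthy_knee_preset())
        assert q == pytest.approx(314.1, rel=1e-3)  # 0.63 mL/min/mL x 8.31 mL
        assert systemic_uptake_rate(0.66e-6, 0.0, q, 0.79, 0.66) == pytest.approx(
            q * 0.79 * 1e-6
        )

    def test_blood_flow_conventions(self):
        phys = healthy_knee_preset()
        q_sub = synovial_blood_flow(phys, "subintima")
        assert q_sub == pytest.approx(0.63 * 277 * 0.0282 * 60)
        assert q_sub < synovial_blood_flow(phys, "total")


class TestCartilageStencil:
    def test_uniform_profile_is_stationary(self):
        rates = cartilage_diffusion_rhs(np.full(10, 0.37), 0.37, 0.025, 148.0, 0.62e-5, 0.66)
        assert np.allclose(rates, 0.0, atol=1e-15)

    def test_stencil_conserves_mass(self):
        rng = np.random.default_rng(42)
        masses = rng.uniform(0, 1, 10)
        rates = cartilage_diffusion_rhs(masses, 0.37, 0.025, 148.0, 0.62e-5, 0.66,
                                        upstream_flux_mg_h=0.123)
        assert rates.sum() == pytest.approx(0.123, rel=1e-12)

    def test_step_profile_matches_analytic_slab_solution(self):
        """Discrete stencil vs the cosine-series solution of an insulated slab.

        Half-loaded initial profile, no-flux at both faces, 50 sublayers;
        the sublayer-centre concentrations must track the Fourier series
        within 1% of the initial step height.
        """
        n, total_h, d, area = 50, 0.25, 0.62e-5, 148.0
        h = total_h / n
        vol = area * h
        c0 = 1.0  # mg/mL in the loaded half
        masses0 = np.zeros(n)
        masses0[: n // 2] = c0 * vol

        def rhs(t, m):
            return cartilage_diffusion_rhs(m, vol, h, area, d, 1.0)

        t_probe = [0.2, 0.5, 1.0]  # h; mid-relaxation (D*t/L^2 ~ 0.07-0.36)
        sol = solve_ivp(rhs, (0, t_probe[-1]), masses0, t_eval=t_probe,
                        method="BDF", rtol=1e-10, atol=1e-14)
        x = (np.arange(n) + 0.5) * h
        d_h = d * 3600.0
        for i, t in enumerate(t_probe):
            series = np.full(n, c0 / 2)
            for m in range(1, 400):
                a_m = 2 * c0 * np.sin(m * np.pi / 2) / (m * np.pi)
                series += a_m * np.cos(m * np.pi * x / total_h) * np.exp(
                    -d_h * (m * np.pi / total_h) ** 2 * t
                )
            numeric = sol.y[:, i] / vol
            assert np.max(np.abs(numeric - series)) < 0.01 * c0

        # relaxation is monotone toward uniform
        spread0 = masses0.max() - masses0.min()
        spreads = [sol.y[:, i].max() - sol.y[:, i].min() for i in range(len(t_probe))]
        assert spread0 > spreads[0] > spreads[1] > spreads[2] >= 0


class TestSimulate:
    def test_initial_condition_equals_dose(self, healthy_result):
        total0 = sum(m[0] for m in healthy_result.masses.values())
        assert total0 == pytest.approx(5.0, rel=1e-9)

    @pytest.mark.parametrize("which", ["healthy_result", "ra_result"])
    def test_mass_balance_within_tolerance(self, which, request):
        res = request.getfixturevalue(which)
        assert np.abs(res.mass_balance_residual).max() < 1e-6 * 5.0

    @pytest.mark.parametrize("which", ["healthy_result", "ra_result"])
    def test_traces_non_negative(self, which, request):
        res = request.getfixturevalue(which)
        for name, trace in res.traces.items():
            assert trace.min() >= 0.0, name

    def test_grid_convergence_of_metrics(self, mtx, pk70, ia_dose):
        loose = simulate(ra_knee_preset(), mtx, pk70, ia_dose, SimulationSettings())
        tight = simulate(
            ra_knee_preset(), mtx, pk70, ia_dose,
            SimulationSettings(rtol=5e-9, atol=5e-13),
        )
        for comp in ("plasma", "synovial_fluid"):
            m1 = compute_metrics(loose.time, loose.trace(comp), 25.0)
            m2 = compute_metrics(tight.time, tight.trace(comp), 25.0)
            assert m1.cmax == pytest.approx(m2.cmax, rel=1e-3)
            assert m1.auc_0_t == pytest.approx(m2.auc_0_t, rel=1e-3)

    def test_determinism(self, mtx, pk70, ia_dose, ra_result):
        again = simulate(ra_knee_preset(), mtx, pk70, ia_dose, SimulationSettings())
        assert np.array_equal(again.trace("plasma"), ra_result.trace("plasma"))

    def test_zero_clearance_reaches_partition_equilibrium(self, mtx, ia_dose):
        """Without elimination, unbound concentrations equalise across the
        joint and plasma total = unbound/fup at the partition zero point."""
        pk = mtx_pk_preset(70.0).copy_with(cl_renal=1e-9)
        settings = SimulationSettings(duration=3000.0, output_step=10.0)
        res = simulate(healthy_knee_preset(), mtx, pk, ia_dose, settings)
        total = sum(m[-1] for m in res.masses.values())
        assert total == pytest.approx(5.0, rel=1e-6)
        cu = {
            name: 0.66 * res.trace(name)[-1]
            for name in ("synovial_fluid", "intima", "subintima", "cartilage_mean")
        }
        ref = cu["synovial_fluid"]
        for name, value in cu.items():
            assert value == pytest.approx(ref, rel=1e-4), name
        cp_ng = res.trace("plasma")[-1]  # ng/mL
        assert cp_ng == pytest.approx(ref * 1e3 / 0.66, rel=1e-4)  # Cu(µg/mL)/fup

    def test_vanishing_perfusion_blocks_systemic_exposure(self, mtx, pk70, ia_dose):
        phys = healthy_knee_preset().copy_with(blood_flow_density=1e-12)
        res = simulate(phys, mtx, pk70, ia_dose, SimulationSettings())
        assert res.trace("plasma").max() < 1e-6  # ng/mL
        joint = (
            res.masses["synovial_fluid"][-1]
            + res.masses["intima"][-1]
            + res.masses["subintima"][-1]
            + res.masses["cartilage"][-1]
            + res.masses["undissolved"][-1]
        )
        assert joint == pytest.approx(5.0, rel=1e-6)

    def test_iv_bolus_route_matches_systemic_model(self, mtx, pk70):
        # with the joint perfusion switched off the full model must collapse
        # onto the pure three-compartment disposition solution
        from iapbpk import simulate_iv_bolus

        phys = healthy_knee_preset().copy_with(blood_flow_density=1e-12)
        dose = DoseEvent(route="IV_bolus", amount=5.0)
        res = simulate(phys, mtx, pk70, dose, SimulationSettings(duration=10.0))
        _, ref = simulate_iv_bolus(pk70, 5.0, 10.0, times_h=res.time)
        assert np.allclose(res.trace("plasma"), ref, rtol=1e-5, atol=1e-3)

    def test_iv_bolus_back_distributes_into_joint(self, mtx, pk70):
        # with perfusion on, a small fraction of an IV dose enters the joint
        dose = DoseEvent(route="IV_bolus", amount=5.0)
        res = simulate(healthy_knee_preset(), mtx, pk70, dose, SimulationSettings(duration=10.0))
        joint = res.masses["subintima"][-1] + res.masses["synovial_fluid"][-1]
        assert joint > 0.0
        assert joint < 0.05 * 5.0

    def test_delayed_dose_shifts_traces(self, mtx, pk70):
        dose = DoseEvent(route="IA", amount=5.0, vehicle_volume=2.0, time=1.0)
        res = simulate(ra_knee_preset(), mtx, pk70, dose, SimulationSettings(duration=5.0))
        before = res.trace("plasma")[res.time < 0.99]
        assert np.all(before == 0.0)

    def test_suspension_dose_dissolves(self, pk70):
        # low dose so the saturation gap stays positive and the depot empties
        cmpd = mtx_preset()
        dose = DoseEvent(route="IA", amount=1.0, vehicle_volume=2.0, form="suspension")
        res = simulate(ra_knee_preset(), cmpd, pk70, dose, SimulationSettings(duration=25.0))
        und = res.trace("undissolved")
        assert und[0] == pytest.approx(1.0)
        assert np.all(np.diff(und) <= 1e-9)
        assert und[-1] < 0.05
        assert np.abs(res.mass_balance_residual).max() < 1e-6


class TestDoseValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"route": "PO", "amount": 5.0},
            {"route": "IA", "amount": 0.0},
            {"route": "IA", "amount": 5.0, "vehicle_volume": -1.0},
            {"route": "IA", "amount": 5.0, "form": "gas"},
        ],
    )
    def test_rejects_invalid_dose(self, kwargs):
        with pytest.raises(ValueError):
            DoseEvent(**kwargs)
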