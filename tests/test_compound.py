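import pytest
from hypothesis import given, settings, strategies as st

from iapbpk import (
    diffusivity_logd_qspr,
    diffusivity_stokes_einstein,
    load_compound,
    mtx_preset,
    save_compound,
    solubility_at_ph,
)
from iapbpk.compound import JOINT_TISSUES, molecular_radius_from_daq


class TestMtxPreset:
    def test_printed_values(self):
        m = mtx_preset()
        assert m.log_p == -1.85
        assert m.d_aqueous == 0.62e-5
        assert (m.reference_solubility, m.reference_solubility_ph) == (0.16, 4.2)
        assert (m.fup, m.rbp) == (0.66, 0.79)
        assert m.particle_radius == 25.0
        assert m.precipitate_radius == 1.0
        assert m.particle_density == 1.2
        assert m.mean_precipitation_time == 900.0

    def test_joint_tissue_binding_and_diffusivity(self):
        m = mtx_preset()
        for tissue in JOINT_TISSUES:
            assert m.fu_tissue[tissue] == 0.66
            assert m.diffusivity_mode[tissue] == "water"
            # water mode: every joint tissue sees the aqueous diffusivity
            assert m.tissue_diffusivity(tissue) == m.d_aqueous

    def test_config_round_trip(self, tmp_path):
        m = mtx_preset()
        path = tmp_path / "cmpd.yaml"
        save_compound(m, path)
        assert load_compound(path) == m


class TestStokesEinstein:
    def test_hand_value(self):
        # 0.4 nm solute in water at 37 C
        assert diffusivity_stokes_einstein(0.4, 0.69, 310.15) == pytest.approx(
            8.2309e-6, rel=1e-4
        )

    def test_scaling_laws(self):
        base = diffusivity_stokes_einstein(0.4, 0.69, 310.15)
        assert diffusivity_stokes_einstein(0.4, 1.38, 310.15) == pytest.approx(base / 2)
        assert diffusivity_stokes_einstein(0.8, 0.69, 310.15) == pytest.approx(base / 2)
        assert diffusivity_stokes_einstein(0.4, 0.69, 620.30) == pytest.approx(base * 2)

    def test_synovial_vs_water_viscosity_nearly_three_decades(self):
        ratio = diffusivity_stokes_einstein(0.4, 389.5, 310.15) / diffusivity_stokes_einstein(
            0.4, 0.69, 310.15
        )
        assert ratio == pytest.approx(0.69 / 389.5)
        assert 1 / ratio == pytest.approx(565, rel=0.01)

    @pytest.mark.parametrize("args", [(0, 1, 1), (1, 0, 1), (1, 1, 0), (-1, 1, 1)])
    def test_rejects_nonpositive(self, args):
        with pytest.raises(ValueError):
            diffusivity_stokes_einstein(*args)

    def test_radius_inversion_round_trip(self):
        # the default solute radius makes SE-at-water reproduce d_aqueous
        r = molecular_radius_from_daq(0.62e-5)
        assert diffusivity_stokes_einstein(r, 0.69, 310.15) == pytest.approx(0.62e-5)
        assert r == pytest.approx(0.531, rel=1e-3)  # nm, plausible for a ~450 Da solute


class TestLogDQspr:
    def test_plateau_above_logd_3(self):
        assert diffusivity_logd_qspr(4.0) == pytest.approx(10 ** -5.9514)
        assert diffusivity_logd_qspr(3.1) == diffusivity_logd_qspr(10.0)

    def test_hand_value_at_zero(self):
        assert diffusivity_logd_qspr(0.0) == pytest.approx(1.8552e-7, rel=1e-4)

    def test_branch_point_nearly_continuous(self):
        below, above = diffusivity_logd_qspr(3.0), diffusivity_logd_qspr(3.0 + 1e-12)
        assert abs(below - above) / above < 0.003


class TestSolubility:
    def test_pass_through_without_ionisation_data(self):
        assert solubility_at_ph(mtx_preset(), 7.7) == 0.16

    def test_identity_at_reference_ph(self):
        acid = mtx_preset().copy_with(pka_list=[(4.0, "acid")])
        assert solubility_at_ph(acid, 4.2) == pytest.approx(0.16)

    def test_monoprotic_acid_hh_factor(self):
        # ref pH 3 (~intrinsic), target pH 5, pKa 4 -> (1+10)/(1+0.1) = 10x
        acid = mtx_preset().copy_with(
            pka_list=[(4.0, "acid")], reference_solubility_ph=3.0
        )
        assert solubility_at_ph(acid, 5.0) == pytest.approx(10.0 * 0.16)

    @settings(deadline=None, max_examples=30)
    @given(ph=st.floats(2.0, 10.0))
    def test_acid_solubility_monotone_in_ph(self, ph):
        acid = mtx_preset().copy_with(pka_list=[(4.0, "acid")])
        assert solubility_at_ph(acid, ph + 0.5) >= solubility_at_ph(acid, ph)


@pytest.mark.parametrize(
    "changes",
    [
        {"fup": 0.0},
        {"fup": 1.5},
        {"rbp": -1.0},
        {"particle_radius": 0.0},
        {"fu_tissue": {t: 0.66 for t in JOINT_TISSUES[:-1]}},
        {"diffusivity_mode": {"cartilage": "teleport"}},
        {"pka_list": [(4.0, "zwitterion")]},
    ],
)
def test_validation_rejects_bad_compound(changes):
    with pytest.raises(ValueError):
        mtx_preset().copy_with(**changes)
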