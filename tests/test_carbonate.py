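"""Carbonate-engine tests: constants against published check values,
speciation identities, the pH<->DIC inverse pair, scale conversion and Gran
titration recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phoskit import carbonate as cb
from phoskit.errors import (
    BracketError,
    DomainError,
    InsufficientDataError,
)
from phoskit.simulate import simulate_titration

# Published check values at S=35, T=298.15 K (total scale):
# Lueker et al. 2000 carbonic-acid constants; Dickson 1990 boric acid.
PK1_CHECK = 5.8472
PK2_CHECK = 8.9660
PKB_CHECK = 8.5975


class TestEquilibriumConstants:
    def test_lueker_check_values(self, asw_chem, constants):
        assert -np.log10(constants.K1) == pytest.approx(PK1_CHECK, abs=5e-4)
        assert -np.log10(constants.K2) == pytest.approx(PK2_CHECK, abs=5e-4)
        assert -np.log10(constants.KB) == pytest.approx(PKB_CHECK, abs=5e-4)

    def test_ordering(self, constants):
        assert constants.K1 > constants.K2 > 0

    def test_pk1_decreases_with_warming(self):
        cold = cb.equilibrium_constants(cb.MediumChemistry(35, 288.15, 2300))
        warm = cb.equilibrium_constants(cb.MediumChemistry(35, 298.15, 2300))
        assert -np.log10(cold.K1) > -np.log10(warm.K1)

    def test_pk_smooth_in_temperature(self):
        pks = []
        for t in np.arange(273.15, 308.15, 2.5):
            k = cb.equilibrium_constants(cb.MediumChemistry(35, t, 2300))
            pks.append(-np.log10(k.K1))
        assert np.all(np.diff(pks) < 0)  # monotone over 0-35 C

    def test_out_of_range_inputs_named(self):
        with pytest.raises(DomainError, match="salinity"):
            cb.MediumChemistry(salinity=60, temperature=298.15, total_alkalinity=2300)
        with pytest.raises(DomainError, match="temperature"):
            cb.MediumChemistry(salinity=35, temperature=350.0, total_alkalinity=2300)

    def test_unknown_constant_set(self, asw_chem):
        with pytest.raises(DomainError, match="unknown constant set"):
            cb.equilibrium_constants(asw_chem, "mehrbach_wrong")


class TestCarbonateAlkalinity:
    def test_pure_carbonate_medium_keeps_alkalinity(self):
        """With no borate/phosphate/silicate and pH 7, non-carbonate terms
        are negligible and A_c ~ A_T."""
        chem = cb.MediumChemistry(
            35, 298.15, 2000.0, total_borate=0.0, total_phosphate=0.0,
            total_silicate=0.0,
        )
        k = cb.equilibrium_constants(chem)
        ac = cb.carbonate_alkalinity(chem, 7.0, k)
        assert abs(ac - 2000.0) < 1.0

    def test_borate_lowers_ac(self, asw_chem, constants):
        ac = cb.carbonate_alkalinity(asw_chem, 8.05, constants)
        assert ac < asw_chem.total_alkalinity

    def test_against_independent_reference(self, asw_chem, constants):
        """Cross-check against an independent inline computation using
        published check-value constants at S=35, 25 C."""
        pH = 8.05
        H = 10.0**-pH
        K_B = 10.0**-PKB_CHECK
        KW = 10.0**-13.2173  # DOE handbook check value
        BT = 415.7e-6
        ref = (
            asw_chem.total_alkalinity * 1e-6 - BT * K_B / (K_B + H) - KW / H
        ) * 1e6
        ac = cb.carbonate_alkalinity(
            cb.MediumChemistry(35, 298.15, 1980.1), pH, constants
        )
        assert ac == pytest.approx(ref, rel=5e-4)

    def test_out_of_range_ph(self, asw_chem, constants):
        with pytest.raises(DomainError):
            cb.carbonate_alkalinity(asw_chem, 11.0, constants)


class TestSpeciation:
    def test_limiting_case_hand_computed(self):
        """K2 << H: all carbonate alkalinity is bicarbonate and
        CO2 = A_c H / K1."""
        k = cb.EquilibriumConstants(
            K1=1e-6, K2=1e-15, KB=1e-9, KW=1e-14, K1P=1e-2, K2P=1e-6,
            K3P=1e-9, KSi=1e-10,
        )
        s = cb.speciate_from_ph(8.0, 2000.0, k)  # H = 1e-8
        assert s.HCO3 == pytest.approx(2000.0, rel=1e-6)
        assert s.CO3 == pytest.approx(0.0, abs=1e-3)
        assert s.CO2 == pytest.approx(2000.0 * 1e-16 / 1e-14, rel=1e-6)  # 20
        assert s.DIC == pytest.approx(2020.0, rel=1e-5)

    @settings(max_examples=200, derandomize=True)
    @given(
        ph=st.floats(6.0, 10.0),
        ac=st.floats(10.0, 4000.0),
        pk1=st.floats(5.0, 6.5),
        dpk=st.floats(2.0, 4.0),
    )
    def test_alkalinity_identity(self, ph, ac, pk1, dpk):
        """HCO3 + 2 CO3 = A_c is an algebraic identity of the speciation."""
        k = cb.EquilibriumConstants(
            K1=10.0**-pk1, K2=10.0 ** -(pk1 + dpk), KB=1e-9, KW=1e-14,
            K1P=1e-2, K2P=1e-6, K3P=1e-9, KSi=1e-10,
        )
        s = cb.speciate_from_ph(ph, ac, k)
        assert abs(s.HCO3 + 2 * s.CO3 - ac) / ac < 1e-10
        assert s.CO2 >= 0 and s.HCO3 >= 0 and s.CO3 >= 0

    def test_dic_against_independent_reference(self):
        """Package DIC at (S=35, 25 C, A_T=2300, pH_T=8.1) vs an independent
        computation from published check-value constants: within 0.5%."""
        H = 10.0**-8.1
        K1, K2 = 10.0**-PK1_CHECK, 10.0**-PK2_CHECK
        K_B, KW = 10.0**-PKB_CHECK, 10.0**-13.2173
        BT = 415.7e-6
        ac = 2300e-6 - BT * K_B / (K_B + H) - KW / H
        dic_ref = (
            ac * H**2 / (K1 * (H + 2 * K2))
            + ac * H / (H + 2 * K2)
            + ac * K2 / (H + 2 * K2)
        ) * 1e6
        chem = cb.MediumChemistry(35, 298.15, 2300.0)
        dic = cb.dic_from_ph(8.1, chem, cb.equilibrium_constants(chem)).DIC
        assert dic == pytest.approx(dic_ref, rel=5e-3)

    def test_nonpositive_ac_rejected(self, constants):
        with pytest.raises(DomainError):
            cb.speciate_from_ph(8.0, -5.0, constants)


class TestPhDicInverse:
    def test_composition_consistency(self, asw_chem, constants):
        s = cb.dic_from_ph(8.05, asw_chem, constants)
        assert s.A_c == pytest.approx(
            cb.carbonate_alkalinity(asw_chem, 8.05, constants), rel=1e-12
        )

    def test_dic_monotone_decreasing_in_ph(self, asw_chem, constants):
        phs = np.linspace(7.5, 8.5, 101)
        dic = cb.dic_from_ph(phs, asw_chem, constants).DIC
        assert np.all(np.diff(dic) < 0)

    @pytest.mark.parametrize("ph", [6.6, 7.2, 8.05, 9.0, 9.4])
    def test_round_trip(self, asw_chem, constants, ph):
        dic = cb.dic_from_ph(ph, asw_chem, constants).DIC
        assert cb.ph_from_dic(dic, asw_chem, constants) == pytest.approx(
            ph, abs=1e-8
        )

    def test_low_dic_converges_near_upper_bracket(self, asw_chem, constants):
        # a target just above the pH-10 floor of the achievable DIC range
        target = 1.02 * cb.dic_from_ph(10.0, asw_chem, constants).DIC
        ph = cb.ph_from_dic(target, asw_chem, constants)
        assert ph > 9.5
        assert cb.dic_from_ph(ph, asw_chem, constants).DIC == pytest.approx(
            target, abs=1e-4
        )

    def test_unreachable_target_raises(self, asw_chem, constants):
        too_high = cb.dic_from_ph(6.0, asw_chem, constants).DIC * 1.5
        with pytest.raises(BracketError):
            cb.ph_from_dic(too_high, asw_chem, constants)


class TestTrisAndScaleConversion:
    def test_tris_reference_value(self):
        # Synthetic-seawater Tris buffer at S=35, 25 C
        assert cb.tris_ph(35.0, 298.15) == pytest.approx(8.0936, abs=1e-4)

    def test_tris_at_15C(self):
        # direct evaluation of the published polynomial, frozen
        assert cb.tris_ph(35.0, 288.15) == pytest.approx(8.41414, abs=1e-5)

    def test_tris_temperature_slope_negative(self):
        t = np.arange(278.15, 308.15, 1.0)
        ph = np.array([cb.tris_ph(35.0, ti) for ti in t])
        assert np.all(np.diff(ph) < 0)

    def test_tris_domain(self):
        with pytest.raises(DomainError):
            cb.tris_ph(10.0, 298.15)

    def test_zero_offset_identity(self):
        assert cb.nbs_to_total(8.123, 8.0936, 8.0936) == pytest.approx(8.123)

    def test_offset_arithmetic(self):
        assert cb.nbs_to_total(8.1230, 8.2000, 8.0936) == pytest.approx(8.0166)

    def test_large_offset_flagged_but_computed(self):
        from phoskit.errors import SuspectCalibrationWarning

        with pytest.warns(SuspectCalibrationWarning):
            out = cb.nbs_to_total(8.0, 8.7, 8.0936)
        assert out == pytest.approx(8.0 - (8.7 - 8.0936))


class TestGranTitration:
    def test_recovery_noise_free(self):
        rec = simulate_titration(2000.0, noise_ph=0.0, seed=0)
        g = cb.gran_alkalinity(rec)
        assert abs(g.A_T / 2000.0 - 1.0) < 2e-4
        assert g.r2 > 0.9999

    def test_recovery_with_electrode_noise(self):
        rec = simulate_titration(2000.0, noise_ph=0.002, seed=0)
        g = cb.gran_alkalinity(rec)
        assert abs(g.A_T / 2000.0 - 1.0) < 2e-3

    def test_degassing_invariance(self):
        """A_T is conserved under CO2 loss: titrating a partially degassed
        sample returns the same alkalinity."""
        rec = simulate_titration(2000.0, initial_ph=8.0, seed=0)
        degassed = simulate_titration(2000.0, initial_ph=8.35, seed=0)
        # higher initial pH at the same A_T corresponds to lower DIC (CO2 lost)
        g1, g2 = cb.gran_alkalinity(rec), cb.gran_alkalinity(degassed)
        assert abs(g1.A_T - g2.A_T) / 2000.0 < 5e-4

    def test_too_few_acid_excess_points(self):
        rec = simulate_titration(2000.0, n_points=8, acid_span=1.2, seed=0)
        n_low = sum(1 for _, p in rec.points if p < 3.8)
        assert n_low < 4
        with pytest.raises(InsufficientDataError):
            cb.gran_alkalinity(rec)

    def test_record_validation(self):
        with pytest.raises(InsufficientDataError):
            cb.TitrationRecord(50.0, 0.1, points=((0.1, 8.0), (0.2, 7.5)))
        with pytest.raises(DomainError):
            cb.TitrationRecord(
                50.0, 0.1,
                points=((0.1, 8.0), (0.2, 7.5), (0.3, 7.6), (0.4, 7.0), (0.5, 6.5)),
            )
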