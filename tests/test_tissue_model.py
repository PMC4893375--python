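"""Optical-coefficient formulas, extinction table and tissue sampling."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcti.tissue_model import (LayerProperties, TissueSample,
                               absorption_coefficient, frame_to_samples,
                               load_extinction_table, load_parameter_ranges,
                               reduced_scattering, sample_tissue,
                               samples_to_frame, scattering_coefficient,
                               to_optical_properties)
from mcti.tissue_model import RangeError


class TestAbsorption:
    def test_no_absorber_gives_zero(self, table):
        assert absorption_coefficient(0.0, 0.3, 520.0, table) == 0.0

    def test_endpoints_select_single_chromophore(self, table):
        # s=1 weighs only HbO2, s=0 only Hb
        eo, ed = table.extinction(560.0)
        mu_oxy = absorption_coefficient(0.02, 1.0, 560.0, table)
        mu_deoxy = absorption_coefficient(0.02, 0.0, 560.0, table)
        assert mu_oxy == pytest.approx(
            0.02 * table.c_hb_molar * eo * np.log(10.0))
        assert mu_deoxy == pytest.approx(
            0.02 * table.c_hb_molar * ed * np.log(10.0))

    def test_hand_computed_value_at_500nm(self, table):
        # independent spreadsheet-style evaluation from the bundled table row
        # at 500 nm (eps 20932.0 / 20862.0), c_hb = 120 g/L, M = 64500 g/mol
        mu = absorption_coefficient(0.05, 0.5, 500.0, table)
        assert mu == pytest.approx(4.476011226818287, rel=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(v=st.floats(0.0, 0.5), s=st.floats(0.0, 1.0),
           lam=st.floats(460.0, 700.0))
    def test_linear_in_blood_volume(self, table, v, s, lam):
        mu1 = absorption_coefficient(v, s, lam, table)
        mu2 = absorption_coefficient(2.0 * v, s, lam, table)
        assert mu2 == pytest.approx(2.0 * mu1, abs=1e-9)

    def test_rejects_out_of_range_wavelength(self, table):
        with pytest.raises(RangeError):
            absorption_coefficient(0.05, 0.5, 900.0, table)

    def test_rejects_invalid_fractions(self, table):
        with pytest.raises(ValueError):
            absorption_coefficient(-0.1, 0.5, 500.0, table)


class TestScattering:
    def test_reference_wavelength_returns_amplitude(self):
        assert reduced_scattering(18.9, 1.286, 500.0) == pytest.approx(18.9)

    def test_zero_power_is_flat(self):
        lam = np.array([450.0, 550.0, 700.0])
        assert reduced_scattering(7.0, 0.0, lam) == pytest.approx([7.0] * 3)

    def test_power_law_value_at_720nm(self):
        # independent arbitrary-precision evaluation of 18.9*(720/500)^-1.286
        assert reduced_scattering(18.9, 1.286, 720.0) == pytest.approx(
            11.82517670955055, rel=1e-12)

    def test_monotone_decreasing_for_positive_power(self):
        lam = np.arange(450.0, 721.0, 2.0)
        mu = reduced_scattering(18.9, 1.286, lam)
        assert (np.diff(mu) < 0).all()

    def test_anisotropy_scaling(self):
        assert scattering_coefficient(10.0, 0.0) == 10.0
        assert scattering_coefficient(10.0, 0.9) == pytest.approx(100.0)
        assert scattering_coefficient(18.9, 0.875) == pytest.approx(151.2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            reduced_scattering(-1.0, 1.286, 500.0)
        with pytest.raises(ValueError):
            scattering_coefficient(10.0, 1.0)


class TestComposition:
    def test_matches_individual_operations(self, table):
        layer = LayerProperties(v_hb=0.07, s=0.4, a_mie=22.0, b=1.286,
                                g=0.88, n_refr=1.36, d=800.0)
        opt = to_optical_properties(layer, 540.0, table)
        assert opt.mu_a == pytest.approx(
            float(absorption_coefficient(0.07, 0.4, 540.0, table)))
        assert opt.mu_s == pytest.approx(
            scattering_coefficient(reduced_scattering(22.0, 1.286, 540.0),
                                   0.88))
        assert opt.d == pytest.approx(800.0 * 1e-4)   # um -> cm

    def test_bloodless_isotropic_limit(self, table):
        layer = LayerProperties(v_hb=0.0, s=0.5, a_mie=15.0, b=0.0, g=0.0,
                                n_refr=1.0, d=1000.0)
        opt = to_optical_properties(layer, 600.0, table)
        assert opt.mu_a == 0.0
        assert opt.mu_s == pytest.approx(15.0)


class TestExtinctionTable:
    def test_tabulated_wavelength_exact(self, table):
        j = 30
        lam = table.wavelength_nm[j]
        eo, ed = table.extinction(lam)
        assert eo == table.eps_hbo2[j] and ed == table.eps_hb[j]

    def test_midpoint_is_arithmetic_mean(self, table):
        lam = 0.5 * (table.wavelength_nm[10] + table.wavelength_nm[11])
        eo, _ = table.extinction(lam)
        assert eo == pytest.approx(
            0.5 * (table.eps_hbo2[10] + table.eps_hbo2[11]))

    def test_deoxy_dominates_at_560nm(self, table):
        eo, ed = table.extinction(560.0)
        assert ed > eo

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("wavelength_nm,eps_hbo2\n500,100\n510,100\n")
        with pytest.raises(ValueError):
            load_extinction_table(p)


class TestParameterRanges:
    def test_colon_config_matches_published_ranges(self, colon_ranges):
        assert colon_ranges.n_layers == 3
        l1 = colon_ranges.layers[0]
        assert (l1["v_hb"].lo, l1["v_hb"].hi) == (0.0, 0.1)
        assert (l1["a_mie"].lo, l1["a_mie"].hi) == pytest.approx((8.7, 29.1))
        assert l1["b"].fixed and l1["b"].lo == 1.286
        assert (l1["d"].lo, l1["d"].hi) == (600.0, 1010.0)
        assert colon_ranges.layers[2]["n_refr"].lo == 1.38
        assert colon_ranges.total_thickness_um_max is None

    def test_generic_config_has_thickness_cap(self, generic_ranges):
        assert generic_ranges.total_thickness_um_max == 2000.0
        assert generic_ranges.layers[0]["v_hb"].hi == 1.0
        assert (generic_ranges.layers[1]["n_refr"].lo,
                generic_ranges.layers[1]["n_refr"].hi) == (1.33, 1.54)

    def test_roundtrip_through_yaml(self, colon_ranges, tmp_path):
        import yaml
        from mcti.tissue_model import ranges_to_dict
        p = tmp_path / "model.yaml"
        p.write_text(yaml.safe_dump(ranges_to_dict(colon_ranges)))
        again = load_parameter_ranges(p)
        assert again.layers == colon_ranges.layers
        assert again.c_hb_gram_per_liter == colon_ranges.c_hb_gram_per_liter


class TestSampling:
    def test_draws_stay_inside_ranges_and_share_s(self, colon_ranges):
        samples = sample_tissue(colon_ranges, 500, seed=11)
        for smp in samples:
            ss = {layer.s for layer in smp.layers}
            assert len(ss) == 1
            for layer, rng_ in zip(smp.layers, colon_ranges.layers):
                for p in ("v_hb", "a_mie", "g", "d"):
                    v = getattr(layer, p)
                    assert rng_[p].lo - 1e-12 <= v <= rng_[p].hi + 1e-12
                assert layer.b == 1.286

    def test_deterministic_given_seed(self, colon_ranges):
        a = sample_tissue(colon_ranges, 20, seed=5)
        b = sample_tissue(colon_ranges, 20, seed=5)
        assert a == b

    def test_uniform_draws_fill_the_range(self, colon_ranges):
        # law-of-large-numbers: empirical extremes within 1% of endpoints
        samples = sample_tissue(colon_ranges, 100_000, seed=1)
        v = np.array([s.layers[0].v_hb for s in samples])
        assert v.min() < 0.001 and v.max() > 0.099
        s = np.array([s.s for s in samples])
        assert s.min() < 0.01 and s.max() > 0.99

    def test_disjoint_seeds_are_independent(self, colon_ranges):
        from scipy.stats import ks_2samp
        a = sample_tissue(colon_ranges, 10_000, seed=100)
        b = sample_tissue(colon_ranges, 10_000, seed=200)
        sa = np.array([x.s for x in a])
        sb = np.array([x.s for x in b])
        assert ks_2samp(sa, sb).pvalue > 0.01

    def test_generic_thickness_renormalized(self, generic_ranges):
        samples = sample_tissue(generic_ranges, 300, seed=9)
        for smp in samples:
            assert sum(layer.d for layer in smp.layers) <= 2000.0 + 1e-6

    def test_dataframe_roundtrip(self, colon_ranges):
        samples = sample_tissue(colon_ranges, 10, seed=2)
        df = samples_to_frame(samples)
        assert list(df.columns)[0] == "s"
        assert frame_to_samples(df) == samples


class TestValidation:
    def test_layer_invariants_enforced(self):
        with pytest.raises(ValueError):
            LayerProperties(v_hb=1.5, s=0.5, a_mie=18.9, b=1.286, g=0.9,
                            n_refr=1.36, d=100.0)
        with pytest.raises(ValueError):
            LayerProperties(v_hb=0.05, s=0.5, a_mie=18.9, b=1.286, g=1.0,
                            n_refr=1.36, d=100.0)

    def test_sample_requires_shared_oxygenation(self):
        l1 = LayerProperties(0.05, 0.5, 18.9, 1.286, 0.9, 1.36, 100.0)
        l2 = LayerProperties(0.05, 0.7, 18.9, 1.286, 0.9, 1.36, 100.0)
        with pytest.raises(ValueError):
            TissueSample((l1, l2))
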