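"""Forward optics: factor mapping, diffusion reflectance, LUT inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sfdigan.optics import (DiffusionValidityError, DomainError, MaterialFactors,
                            OpticalProperties, ReflectanceLUT, build_inversion_lut,
                            diffuse_reflectance, factors_to_properties,
                            internal_reflection_parameter, invert_reflectance)

unit = st.floats(0.0, 1.0)


class TestFactorMapping:
    @pytest.mark.parametrize("factors, expected", [
        ((1.0, 1.0, 1.0), (0.0, 2.5)),
        ((0.0, 0.0, 1.0), (0.25, 0.0)),
        ((0.5, 0.5, 1.0), (0.0625, 1.25)),
    ])
    def test_known_points(self, factors, expected):
        props = factors_to_properties(MaterialFactors(*factors))
        assert props.mu_a == pytest.approx(expected[0], abs=1e-12)
        assert props.mu_s_prime == pytest.approx(expected[1], abs=1e-12)

    def test_out_of_range_factor_names_field(self):
        with pytest.raises(DomainError, match="absorption_factor"):
            MaterialFactors(0.5, 1.2, 0.5)
        with pytest.raises(DomainError, match="final_factor"):
            MaterialFactors(-0.1, 0.5, 0.5)

    @settings(derandomize=True, max_examples=50)
    @given(f=unit, a=unit, s=unit, df=st.floats(0.0, 0.5))
    def test_monotonicity(self, f, a, s, df):
        p0 = factors_to_properties(MaterialFactors(f, a, s))
        p1 = factors_to_properties(MaterialFactors(min(f + df, 1.0), a, s))
        assert p1.mu_a <= p0.mu_a + 1e-12
        assert p1.mu_s_prime >= p0.mu_s_prime - 1e-12

    def test_spans_property_rectangle(self):
        # boundary-to-boundary surjectivity of the bilinear map
        corners = [factors_to_properties(MaterialFactors(f, a, s))
                   for f in (0, 1) for a in (0, 1) for s in (0, 1)]
        mu_as = {c.mu_a for c in corners}
        mu_ss = {c.mu_s_prime for c in corners}
        assert {0.0, 0.25} <= mu_as and {0.0, 2.5} <= mu_ss

    def test_negative_property_rejected(self):
        with pytest.raises(DomainError):
            OpticalProperties(-0.01, 1.0)


def _mc_reflectance(mu_a, mu_s, n_rel, n_photons=40000, seed=7):
    """Random-walk photon oracle for planar (fx=0) diffuse reflectance.

    Isotropic scattering in the similarity (reduced) description of a
    semi-infinite slab: exponential steps at the transport length, albedo
    weighting per event, effective internal reflection at the surface.
    """
    rng = np.random.default_rng(seed)
    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t
    r_eff = 0.0636 * n_rel + 0.668 + 0.710 / n_rel - 1.440 / n_rel**2
    escaped = 0.0
    for _ in range(n_photons):
        z, uz, w = 0.0, 1.0, 1.0
        for _ in range(600):
            z += uz * rng.exponential(1.0 / mu_t)
            if z <= 0.0:
                if rng.random() < r_eff:      # internally reflected, walks on
                    z, uz = -z, -uz
                    continue
                escaped += w
                break
            w *= albedo
            if w < 1e-4:
                break
            uz = rng.uniform(-1.0, 1.0)
    return escaped / n_photons


class TestDiffuseReflectance:
    def test_hand_evaluated_value(self):
        # closed form evaluated independently by hand:
        # A = 0.14464, mu_tr = 1.02, a' = 0.98039, mu_eff' = 1.28076,
        # Rd = 0.43391*0.98039 / (2.25565 * 1.68956) = 0.11162
        assert diffuse_reflectance(0.02, 1.0, 0.2, 1.43) == pytest.approx(0.11162, abs=2e-4)

    def test_internal_reflection_parameter(self):
        # Groenhuis polynomial at n=1.43: R_eff=0.55131, A=(1-R)/(2(1+R))
        assert internal_reflection_parameter(1.43) == pytest.approx(0.14464, abs=2e-4)

    def test_monte_carlo_cross_check(self):
        # independent photon-walk oracle; diffusion theory agrees to ~15%
        # in the high-albedo regime
        rd_da = diffuse_reflectance(0.02, 1.0, 0.0, 1.43)
        rd_mc = _mc_reflectance(0.02, 1.0, 1.43)
        assert rd_mc == pytest.approx(rd_da, rel=0.25)

    def test_absorbing_limit(self):
        assert diffuse_reflectance(50.0, 1.0, 0.0) < 0.01

    def test_monotone_in_fx_mu_a_mu_s(self):
        # restricted to the diffusive regime mu_s' >= 0.7: below that the
        # (2 pi fx)^2 term dominates mu_eff' and Rd folds slightly upward in
        # mu_a at the working frequencies
        mu_a = np.linspace(0.01, 0.25, 7)[:, None, None]
        mu_s = np.linspace(0.7, 2.5, 7)[None, :, None]
        fx = np.array([0.0, 0.18, 0.22])[None, None, :]
        rd = diffuse_reflectance(mu_a, mu_s, fx)
        assert np.all(rd >= 0) and np.all(rd <= 1)
        assert np.all(np.diff(rd, axis=2) < 0)   # decreasing in fx
        assert np.all(np.diff(rd, axis=0) < 0)   # decreasing in mu_a
        assert np.all(np.diff(rd, axis=1) > 0)   # increasing in mu_s'

    def test_domain_errors(self):
        with pytest.raises(DiffusionValidityError):
            diffuse_reflectance(0.01, 0.0, 0.2)
        with pytest.raises(DomainError):
            diffuse_reflectance(0.01, 1.0, -0.1)


class TestInversionLut:
    def test_nodes_match_forward_model_and_ordering(self, lut, calib):
        i, j = 30, 40
        mu_a, mu_s = lut.mu_a_grid[i], lut.mu_s_grid[j]
        assert lut.rd_dc[i, j] == pytest.approx(
            diffuse_reflectance(mu_a, mu_s, 0.0, calib.n_rel), abs=1e-12)
        assert lut.rd_ac[i, j] == pytest.approx(
            diffuse_reflectance(mu_a, mu_s, calib.fx, calib.n_rel), abs=1e-12)
        assert np.all(lut.rd_ac <= lut.rd_dc + 1e-12)

    def test_grid_node_round_trip(self, calib):
        lut = build_inversion_lut(0.2, calib, n_mu_a=21, n_mu_s=21,
                                  mu_a_range=(0.01, 0.25), mu_s_range=(0.1, 2.5))
        a2, s2 = np.meshgrid(lut.mu_a_grid[1:-1], lut.mu_s_grid[1:-1], indexing="ij")
        mu_a, mu_s, oog = invert_reflectance(
            lut, diffuse_reflectance(a2, s2, 0.0), diffuse_reflectance(a2, s2, 0.2))
        assert not oog.any()
        assert np.max(np.abs(mu_a - a2) / a2) < 0.01
        assert np.max(np.abs(mu_s - s2) / s2) < 0.01

    def test_random_pair_round_trip(self, lut):
        rng = np.random.default_rng(11)
        mu_a = rng.uniform(0.01, 0.25, 100)
        mu_s = rng.uniform(0.1, 2.5, 100)
        got_a, got_s, oog = invert_reflectance(
            lut, diffuse_reflectance(mu_a, mu_s, 0.0),
            diffuse_reflectance(mu_a, mu_s, 0.2))
        assert not oog.any()
        assert np.max(np.abs(got_a - mu_a) / mu_a) < 0.02
        assert np.max(np.abs(got_s - mu_s) / mu_s) < 0.02

    def test_inversion_monotone_in_rd_dc(self, lut):
        # more DC reflectance at fixed AC -> weakly lower absorption
        rd_ac = 0.12
        rd_dcs = np.linspace(0.28, 0.40, 12)
        mu_a, _, oog = invert_reflectance(lut, rd_dcs, np.full_like(rd_dcs, rd_ac))
        good = ~oog
        assert good.sum() >= 8
        assert np.all(np.diff(mu_a[good]) < 1e-6)

    def test_off_node_query_lies_between_nodes(self, calib):
        lut = build_inversion_lut(0.2, calib, n_mu_a=21, n_mu_s=21,
                                  mu_a_range=(0.01, 0.25), mu_s_range=(0.1, 2.5))
        i, j = 10, 10
        a_pair = lut.mu_a_grid[i:i + 2]
        rd_dc = lut.rd_dc[i:i + 2, j].mean()
        rd_ac = lut.rd_ac[i:i + 2, j].mean()
        mu_a, mu_s, oog = invert_reflectance(lut, rd_dc, rd_ac)
        assert not oog
        assert a_pair[0] - 1e-9 <= mu_a <= a_pair[1] + 1e-9

    def test_out_of_gamut_flagged_with_nearest_fallback(self, lut):
        mu_a, mu_s, oog = invert_reflectance(lut, 0.99, 0.98)
        assert oog
        assert 0 <= mu_a <= 0.25 and 0 <= mu_s <= 2.5

    def test_text_round_trip(self, tmp_path, calib):
        lut = build_inversion_lut(0.2, calib, n_mu_a=11, n_mu_s=9)
        path = tmp_path / "lut.txt"
        lut.save(path)
        back = ReflectanceLUT.load(path)
        assert back.fx_ac == lut.fx_ac
        np.testing.assert_allclose(back.rd_dc, lut.rd_dc, rtol=1e-9)
        np.testing.assert_allclose(back.mu_s_grid, lut.mu_s_grid, rtol=1e-9)

    def test_nonpositive_fx_rejected(self):
        with pytest.raises(DomainError):
            build_inversion_lut(0.0)
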