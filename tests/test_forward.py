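"""Spherical-conductor dipole fields and lead-field assembly.

The closed-form field is checked against two independent oracles: the
radial-field identity (the radial component outside a spherical conductor
equals that of the primary current dipole alone, a textbook result that
shares no code with the implementation) and MNE-Python's Sarvas kernel.
"""

import numpy as np
import pytest

from opmarray.forward import (
    Dipole,
    GeometryError,
    build_leadfield,
    dipole_field,
    rank_spectrum,
)

MU0_4PI = 1e-7


def _random_tangential_dipole(rng, radius=60.0, moment=10.0):
    pos = rng.standard_normal(3)
    pos *= radius / np.linalg.norm(pos)
    ori = rng.standard_normal(3)
    ori -= (ori @ pos) * pos / (pos @ pos)
    ori /= np.linalg.norm(ori)
    return Dipole(position=pos, orientation=ori, moment=moment)


class TestDipoleField:
    def test_radial_dipole_is_silent(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pos = rng.standard_normal(3)
            pos *= 60.0 / np.linalg.norm(pos)
            d = Dipole(position=pos, orientation=pos / np.linalg.norm(pos), moment=10.0)
            sens = rng.standard_normal(3)
            sens *= 100.0 / np.linalg.norm(sens)
            ori = rng.standard_normal(3)
            ori /= np.linalg.norm(ori)
            assert abs(dipole_field(d, sens, ori)) < 1e-9

    def test_linearity_in_moment(self):
        rng = np.random.default_rng(1)
        d1 = _random_tangential_dipole(rng, moment=7.0)
        d2 = Dipole(d1.position, d1.orientation, moment=14.0)
        sens, ori = np.array([10.0, 20.0, 95.0]), np.array([0.0, 0.0, 1.0])
        assert dipole_field(d2, sens, ori) == pytest.approx(2 * dipole_field(d1, sens, ori))

    def test_radial_component_equals_primary_dipole_field(self):
        # independent closed form: B_r = mu0/4pi (Q x (r - r0)) . r_hat / |r - r0|^3
        rng = np.random.default_rng(2)
        for _ in range(10):
            d = _random_tangential_dipole(rng)
            sens = rng.standard_normal(3)
            sens *= 100.0 / np.linalg.norm(sens)
            rhat = sens / np.linalg.norm(sens)
            got = dipole_field(d, sens, rhat)
            Q = d.orientation * d.moment * 1e-9
            a = (sens - d.position) * 1e-3
            expect = MU0_4PI * np.cross(Q, a) @ rhat / np.linalg.norm(a) ** 3 * 1e15
            assert got == pytest.approx(expect, rel=5e-3)

    def test_matches_mne_sphere_model(self):
        from mne.forward._compute_forward_numba import _do_sphere_field

        rrs = np.array([[0.012, 0.021, 0.05]])
        sens = np.array([[0.03, -0.02, 0.095], [0.01, 0.08, 0.05], [-0.06, 0.0, 0.07]])
        cos = sens / np.linalg.norm(sens, axis=1, keepdims=True)
        B_mne = _do_sphere_field(
            rrs, sens, cos, np.ones(len(sens)), np.arange(len(sens)), np.zeros(3)
        )  # (3 dipole components, n_sens), T per A*m
        for j, ori in enumerate(np.eye(3)):
            d = Dipole(position=rrs[0] * 1000, orientation=ori, moment=1.0)
            mine = np.array(
                [dipole_field(d, sens[i] * 1000, cos[i]) for i in range(len(sens))]
            )
            assert np.allclose(mine * 1e-15 / 1e-9, B_mne[j], rtol=1e-10, atol=1e-25)

    def test_rotational_symmetry(self):
        rng = np.random.default_rng(3)
        d = _random_tangential_dipole(rng)
        sens = np.array([20.0, -30.0, 90.0])
        ori = np.array([0.0, 1.0, 0.0])
        b0 = dipole_field(d, sens, ori)
        theta = 1.234
        R = np.array(
            [[np.cos(theta), 0, np.sin(theta)], [0, 1, 0], [-np.sin(theta), 0, np.cos(theta)]]
        )
        d_rot = Dipole(R @ d.position, R @ d.orientation, d.moment)
        b1 = dipole_field(d_rot, R @ sens, R @ ori)
        assert b1 == pytest.approx(b0, rel=1e-9)

    def test_field_decays_along_ray(self):
        d = Dipole(position=[0.0, 0.0, 70.0], orientation=[1.0, 0.0, 0.0], moment=10.0)
        ray = np.array([0.3, 0.5, 0.81])
        ray /= np.linalg.norm(ray)
        ori = np.array([0.0, 0.0, 1.0])
        fields = [abs(dipole_field(d, ray * r, ori)) for r in (95.0, 110.0, 130.0, 160.0)]
        assert all(a > b for a, b in zip(fields, fields[1:]))

    def test_geometry_errors(self):
        d = Dipole(position=[0, 0, 70.0], orientation=[1.0, 0, 0], moment=1.0)
        with pytest.raises(GeometryError):
            dipole_field(d, [0, 0, 50.0], [0, 0, 1.0])  # sensor below dipole radius
        with pytest.raises(GeometryError):
            dipole_field(d, [0, 0, 80.0], [0, 0, 1.0], conductor_radius_mm=85.0)
        bad = Dipole(position=[0, 0, 95.0], orientation=[1.0, 0, 0], moment=1.0)
        with pytest.raises(GeometryError):
            dipole_field(bad, [0, 0, 120.0], [0, 0, 1.0], conductor_radius_mm=90.0)


class TestLeadField:
    def test_shape_and_column_permutation(self, space, array30):
        idx = np.array([10, 200, 3000])
        lf = build_leadfield(space, array30, source_indices=idx)
        assert lf.matrix.shape == (array30.n_channels, 3)
        perm = np.array([2, 0, 1])
        lf_perm = build_leadfield(space, array30, source_indices=idx[perm])
        assert np.allclose(lf_perm.matrix, lf.matrix[:, perm])

    def test_entries_match_scalar_oracle(self, space, array30):
        idx = np.array([50, 1500])
        lf = build_leadfield(space, array30, source_indices=idx)
        rng = np.random.default_rng(0)
        for _ in range(10):
            i = rng.integers(array30.n_channels)
            j = rng.integers(2)
            d = Dipole(
                position=space.mesh.vertices[idx[j]],
                orientation=space.mesh.vertex_normals[idx[j]],
                moment=1.0,
            )
            expect = dipole_field(d, array30.positions[i], array30.orientations[i])
            assert lf.matrix[i, j] == pytest.approx(expect, rel=1e-12)

    def test_dense_config_in_plausible_range(self, dense_lf):
        med = np.median(np.abs(dense_lf.matrix))
        assert 0.1 < med < 100.0
        assert np.all(np.isfinite(dense_lf.matrix))

    def test_sensor_inside_conductor_rejected(self, space):
        class FakeArray:
            positions = np.array([[0.0, 0.0, 50.0]])
            orientations = np.array([[0.0, 0.0, 1.0]])

        with pytest.raises(GeometryError):
            build_leadfield(space, FakeArray(), source_indices=np.array([0]))

    def test_hdf5_round_trip(self, tmp_path, space, array30):
        from opmarray.forward import LeadField

        lf = build_leadfield(space, array30, source_indices=np.array([5, 6]))
        lf.save(tmp_path / "lf.h5")
        back = LeadField.load(tmp_path / "lf.h5")
        assert np.array_equal(back.matrix, lf.matrix)
        assert np.array_equal(back.source_vertex_indices, lf.source_vertex_indices)


class TestRankSpectrum:
    def test_rank_one_matrix(self):
        L = np.outer(np.arange(1.0, 6.0), np.ones(8))
        rs = rank_spectrum(L)
        assert rs.cumulative_ve[0] == pytest.approx(1.0)
        assert rs.rank_95 == 1 and rs.rank_99 == 1

    def test_orthogonal_equal_norm_columns_linear_ve(self):
        rs = rank_spectrum(np.eye(6) * 3.0)
        assert np.allclose(rs.cumulative_ve, np.arange(1, 7) / 6)

    def test_monotone_and_normalised(self, dense_lf):
        rs = rank_spectrum(dense_lf)
        assert np.all(np.diff(rs.cumulative_ve) >= -1e-12)
        assert rs.cumulative_ve[-1] == pytest.approx(1.0, abs=1e-9)

    def test_covariance_psd(self, dense_lf):
        C = dense_lf.matrix @ dense_lf.matrix.T
        assert np.allclose(C, C.T)
        w = np.linalg.eigvalsh(C)
        assert w.min() > -1e-6 * w.max()

    def test_zero_leadfield_rejected(self):
        with pytest.raises(ValueError):
            rank_spectrum(np.zeros((4, 5)))
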