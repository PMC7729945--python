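"""EBB prior, ReML covariance-component fitting and free-energy behaviour."""

import numpy as np
import pytest

from opmarray.discrimination import base_model
from opmarray.forward import build_leadfield
from opmarray.inversion import CandidateModel, ebb_prior, invert, reml_fit
from opmarray.simulate import SimulationConfig, simulate_recording


@pytest.fixture(scope="module")
def sup_setup(space, array30, sources):
    """Lead field over the base neighbourhood of the most superficial source."""
    src = int(sources.superficial[0])
    pos = space.mesh.vertices
    near = np.nonzero(np.linalg.norm(pos - pos[src], axis=1) <= 20.0)[0]
    lf = build_leadfield(space, array30, source_indices=near)
    return src, near, lf


class TestEbbPrior:
    def test_orthonormal_columns_identity_covariance_equal_q(self):
        L = np.linalg.qr(np.random.default_rng(0).standard_normal((20, 5)))[0]
        q = ebb_prior(L, np.eye(20))
        assert np.allclose(q, q[0])

    def test_homogeneous_in_covariance_scale(self):
        rng = np.random.default_rng(1)
        L = rng.standard_normal((15, 6))
        A = rng.standard_normal((15, 30))
        C = A @ A.T / 30
        q1 = ebb_prior(L, C)
        q4 = ebb_prior(L, 4 * C)
        assert np.allclose(q4, 4 * q1, rtol=1e-9)

    def test_beamformer_peak_at_true_source(self, space, sup_setup):
        src, near, lf = sup_setup
        rec = simulate_recording(
            lf, int(np.searchsorted(near, src)), SimulationConfig(amplitude=100.0, seed=0)
        )
        S = rec.data @ rec.data.T / rec.n_samples
        q = ebb_prior(lf.matrix, S)
        peak_vertex = near[int(np.argmax(q))]
        dist = np.linalg.norm(space.mesh.vertices[peak_vertex] - space.mesh.vertices[src])
        assert dist <= space.mesh.mean_vertex_spacing() * 1.5  # true vertex or 1-ring

    def test_zero_column_rejected(self):
        L = np.zeros((10, 2))
        L[:, 0] = 1.0
        with pytest.raises(ValueError):
            ebb_prior(L, np.eye(10))


class TestRemlFit:
    def test_recovers_known_noise_scale(self):
        rng = np.random.default_rng(0)
        n, nc = 10_000, 12
        Y = np.sqrt(2.0) * rng.standard_normal((nc, n))
        S = Y @ Y.T / n
        A = rng.standard_normal((nc, 4))
        Q2 = A @ A.T / 4
        res = reml_fit(S, [np.eye(nc), Q2], n_samples=n)
        assert np.exp(res.hyperparameters[0]) == pytest.approx(2.0, rel=0.10)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        S = np.cov(rng.standard_normal((8, 500)))
        Q2 = np.outer(np.arange(1.0, 9.0), np.arange(1.0, 9.0))
        a = reml_fit(S, [np.eye(8), Q2], n_samples=500)
        b = reml_fit(S, [np.eye(8), Q2], n_samples=500)
        assert a.free_energy == b.free_energy
        assert np.array_equal(a.hyperparameters, b.hyperparameters)

    def test_objective_non_decreasing_in_iterations(self):
        # oracle: penalised F evaluated on a dense lambda grid of a
        # 2-component toy problem; Fisher scoring must climb to the grid top
        rng = np.random.default_rng(2)
        nc, n = 6, 400
        Q2 = np.diag(np.linspace(0.5, 3.0, nc))
        true = 1.5 * np.eye(nc) + 0.8 * Q2
        Y = np.linalg.cholesky(true) @ rng.standard_normal((nc, n))
        S = Y @ Y.T / n
        fits = [
            reml_fit(S, [np.eye(nc), Q2], n_samples=n, max_iter=k, compute_laplace=False)
            for k in range(1, 12)
        ]
        Fs = [f.free_energy for f in fits]
        assert np.all(np.diff(Fs) >= -1e-9)

        from opmarray.inversion import _free_energy

        grid = np.linspace(-4, 4, 81)
        best = max(
            _free_energy(np.array([a, b]), [np.eye(nc), Q2], S, n, -4.0, 1 / 256)[0]
            for a in grid
            for b in grid
        )
        final = reml_fit(S, [np.eye(nc), Q2], n_samples=n, compute_laplace=False)
        assert final.free_energy >= best - 0.01

    def test_requires_two_components(self):
        with pytest.raises(ValueError):
            reml_fit(np.eye(3), [np.eye(3)], n_samples=10)


class TestInvert:
    def test_same_inputs_same_free_energy(self, sup_setup):
        src, near, lf = sup_setup
        rec = simulate_recording(
            lf, int(np.searchsorted(near, src)), SimulationConfig(amplitude=100.0, seed=1)
        )
        model = CandidateModel(near, lf.matrix)
        assert invert(rec, model).free_energy == invert(rec, model).free_energy

    def test_removing_true_source_lowers_evidence_at_high_snr(self, sup_setup):
        src, near, lf = sup_setup
        col = int(np.searchsorted(near, src))
        rec = simulate_recording(lf, col, SimulationConfig(amplitude=100.0, seed=2))
        base = CandidateModel(near, lf.matrix)
        keep = np.arange(len(near)) != col
        reduced = CandidateModel(near[keep], lf.matrix[:, keep])
        assert invert(rec, base).free_energy > invert(rec, reduced).free_energy

    def test_pure_noise_gives_no_evidence_either_way(self, space, sup_setup):
        src, near, lf = sup_setup
        col = int(np.searchsorted(near, src))
        base = base_model(space, lf, src)
        from opmarray.discrimination import void_model

        diffs = []
        for seed in range(20):
            rec = simulate_recording(lf, col, SimulationConfig(amplitude=0.0, seed=seed))
            vm = void_model(base, space, src, 10.0)
            diffs.append(invert(rec, vm).free_energy - invert(rec, base).free_energy)
        assert abs(np.mean(diffs)) < 3.0

    def test_duplicated_columns_gain_no_free_lunch(self, sup_setup):
        src, near, lf = sup_setup
        col = int(np.searchsorted(near, src))
        rec = simulate_recording(lf, col, SimulationConfig(amplitude=100.0, seed=3))
        base = CandidateModel(near, lf.matrix)
        dup = CandidateModel(
            np.concatenate([near, near + 100_000]),  # synthetic distinct ids
            np.hstack([lf.matrix, lf.matrix]),
        )
        assert invert(rec, dup).free_energy <= invert(rec, base).free_energy + 1.0

    def test_empty_model_rejected(self, sup_setup):
        src, near, lf = sup_setup
        rec = simulate_recording(lf, 0, SimulationConfig(seed=0))
        with pytest.raises(ValueError):
            invert(rec, CandidateModel(np.empty(0, np.int64), np.empty((lf.n_channels, 0))))


def test_delta_f_three_is_twenty_to_one():
    """A free-energy difference of 3 nats is an evidence ratio of ~20."""
    assert round(np.exp(3.0)) == 20
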