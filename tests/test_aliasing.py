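"""Nearest-neighbour lead-field reconstruction, variance explained, the
VE-to-SNR conversion, greedy subset optimisation and source smoothing."""

import numpy as np
import pytest

from opmarray.aliasing import (
    _IncrementalVE,
    aliasing_snr_db,
    greedy_optimize,
    nn_reconstruct,
    smooth_sources,
    variance_explained,
)
from opmarray.forward import LeadField


def _toy_lf(positions, matrix):
    positions = np.asarray(positions, float)
    n = len(positions)
    return LeadField(
        matrix=np.asarray(matrix, float),
        channel_positions=positions,
        channel_orientations=np.tile([0.0, 0.0, 1.0], (n, 1)),
        source_vertex_indices=np.arange(matrix.shape[1]),
        source_positions=np.zeros((matrix.shape[1], 3)),
        source_orientations=np.tile([0.0, 0.0, 1.0], (matrix.shape[1], 1)),
    )


class TestNnReconstruct:
    def test_full_subset_is_identity(self, small_dense_lf):
        rec = nn_reconstruct(small_dense_lf, np.arange(small_dense_lf.n_channels))
        assert np.array_equal(rec.matrix, small_dense_lf.matrix)

    def test_single_sensor_floods_all_rows(self, small_dense_lf):
        rec = nn_reconstruct(small_dense_lf, np.array([7]))
        assert np.all(rec.matrix == small_dense_lf.matrix[7])

    def test_tie_broken_toward_lowest_index(self):
        # two subset sensors exactly equidistant from the probe row
        pos = [[-1.0, 0, 0], [1.0, 0, 0], [0.0, 0, 0]]
        mat = np.array([[1.0, 2.0], [3.0, 4.0], [0.0, 0.0]])
        lf = _toy_lf(pos, mat)
        rec = nn_reconstruct(lf, np.array([0, 1]))
        assert np.array_equal(rec.matrix[2], mat[0])

    def test_empty_subset_rejected(self, small_dense_lf):
        with pytest.raises(ValueError):
            nn_reconstruct(small_dense_lf, np.array([], dtype=int))


class TestVarianceExplained:
    def test_identical_inputs_give_one(self, small_dense_lf):
        ve = variance_explained(small_dense_lf, small_dense_lf, per_source=False)
        assert ve == pytest.approx(1.0)

    def test_constant_reconstruction_gives_zero(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 4))
        Y = np.tile(X.mean(axis=0), (30, 1))
        ve = variance_explained(X, Y)
        assert np.allclose(ve, 0.0)

    def test_matches_pearson_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((25, 6))
        Y = X + 0.5 * rng.standard_normal((25, 6))
        ve = variance_explained(X, Y)
        expect = np.array([np.corrcoef(X[:, j], Y[:, j])[0, 1] ** 2 for j in range(6)])
        assert np.allclose(ve, expect, atol=1e-12)

    def test_zero_variance_true_column_excluded_with_warning(self):
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10.0)
        with pytest.warns(UserWarning):
            ve = variance_explained(X, X.copy())
        assert np.isnan(ve[0]) and ve[1] == pytest.approx(1.0)


class TestAliasingSnr:
    def test_half_explained_is_zero_db(self):
        assert aliasing_snr_db(0.5) == pytest.approx(0.0)

    def test_ve_095_matches_printed_amplitude_snr(self):
        db = aliasing_snr_db(0.95)
        assert db == pytest.approx(12.79, abs=0.01)
        assert np.sqrt(0.95 / 0.05) == pytest.approx(4.36, abs=0.01)

    def test_ve_096_amplitude_snr(self):
        assert np.sqrt(0.96 / 0.04) == pytest.approx(4.90, abs=0.01)

    def test_strictly_increasing_in_ve(self):
        ve = np.linspace(0.05, 0.99, 40)
        vals = [aliasing_snr_db(v) for v in ve]
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_degenerate_ve_rejected(self, bad):
        with pytest.raises(ValueError):
            aliasing_snr_db(bad)


class TestGreedyOptimize:
    def test_full_subset_trivial(self, small_dense_lf):
        subset, rep, trace = greedy_optimize(small_dense_lf, small_dense_lf.n_channels, seed=0)
        assert rep.ve == 1.0 and len(trace) == 1

    def test_trace_monotone_and_beats_random_init(self, small_dense_lf):
        subset, rep, trace = greedy_optimize(small_dense_lf, 60, seed=3, max_sweeps=5)
        assert np.all(np.diff(trace) > 0)
        assert rep.ve >= trace[0]
        assert rep.aliased_pct == pytest.approx(100 * (1 - rep.ve), abs=1e-9)

    def test_incremental_ve_matches_full_recompute(self, small_dense_lf):
        rng = np.random.default_rng(4)
        subset = rng.choice(small_dense_lf.n_channels, 40, replace=False)
        tracker = _IncrementalVE(
            small_dense_lf.matrix, small_dense_lf.channel_positions, subset
        )
        for _ in range(5):
            free = [
                i for i in range(small_dense_lf.n_channels) if i not in set(tracker.subset)
            ]
            old = int(rng.choice(tracker.subset))
            new = int(rng.choice(free))
            ve_new, state = tracker.propose_move(old, new)
            tracker.commit(state)
        rec = nn_reconstruct(small_dense_lf, tracker.subset)
        full = variance_explained(small_dense_lf, rec, per_source=False)
        assert ve_new == pytest.approx(full, abs=1e-10)

    def test_mean_ve_non_decreasing_in_channel_count(self, small_dense_lf):
        counts = (25, 50, 100, 200)
        means = []
        for n in counts:
            ves = [
                greedy_optimize(small_dense_lf, n, seed=s, max_sweeps=3)[1].ve
                for s in range(3)
            ]
            means.append(np.mean(ves))
        assert np.all(np.diff(means) > 0)

    def test_too_many_channels_rejected(self, small_dense_lf):
        with pytest.raises(ValueError):
            greedy_optimize(small_dense_lf, small_dense_lf.n_channels + 1)


class TestSmoothSources:
    def test_zero_fwhm_is_identity(self, small_dense_lf, space):
        out = smooth_sources(small_dense_lf, space, 0.0)
        assert out is small_dense_lf

    def test_huge_fwhm_approaches_global_mean(self, small_dense_lf, space):
        out = smooth_sources(small_dense_lf, space, 1e5)
        spread = out.matrix.std(axis=1).max() / np.abs(out.matrix).max()
        assert spread < 1e-3

    def test_smoothing_reduces_aliasing_for_coherent_patches(self, scalp):
        """Extended generators alias less than point sources when the patch
        dipoles are orientation-coherent. (With rapidly varying orientations
        the signed fields of a wide patch cancel and the property breaks —
        a cancellation effect of folded geometry, so this check uses a
        cortex without the fine orientation folds, over the physiological
        smoothing range.)"""
        from opmarray.arrays import offset_array, pack_sensors
        from opmarray.forward import build_leadfield

        from opmarray.geometry import make_cortex

        sp = make_cortex(scalp, fine_fold_amplitude_mm=0.0, target_spacing_mm=5.0, seed=2)
        z_floor = float(sp.mesh.vertices[:, 2].min())
        arr = offset_array(pack_sensors(scalp, 20.0, z_floor_mm=z_floor, seed=6), 6.5)
        lf = build_leadfield(sp, arr)
        rng = np.random.default_rng(5)
        subset = rng.choice(lf.n_channels, 100, replace=False)
        aliased = []
        for fwhm in (0.0, 10.0, 20.0):
            sm = smooth_sources(lf, sp, fwhm)
            rec = nn_reconstruct(sm, subset)
            ve = variance_explained(sm, rec, per_source=False)
            aliased.append(100 * (1 - ve))
        assert np.all(np.diff(aliased) < 0)
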