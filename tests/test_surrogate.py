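"""Network engine, surrogate architectures, dataset builders."""

import numpy as np
import pytest
from scipy import ndimage

from spinodal import CHParams, GridSpec, PhaseField, UniformInitSpec, ValidationError
from spinodal.fields import init_uniform
from spinodal.surrogate import (DEFAULT_EXTRACTION_STEPS, EvolutionSurrogate,
                                EvolutionSurrogateSpec, PropertySurrogate,
                                PropertySurrogateSpec, TrainingConfig,
                                build_pair_dataset, build_property_dataset,
                                circular_pad_check, pair_counts,
                                property_counts, rollout,
                                train_evolution_surrogate,
                                train_property_surrogate)
from spinodal.surrogate import nn
from spinodal.surrogate.datasets import PropertyDataset


class TestConvEngine:
    def test_circular_conv_matches_ndimage_wrap(self):
        rng = np.random.default_rng(0)
        conv = nn.Conv3d(2, 3, 3, rng=rng, dtype=np.float64)
        x = rng.standard_normal((1, 2, 10, 10, 10))
        y = conv.forward(x)
        for o in range(3):
            want = conv.bias[o] * np.ones((10, 10, 10))
            for i in range(2):
                want = want + ndimage.correlate(x[0, i], conv.weight[o, i],
                                                mode="wrap")
            assert np.allclose(y[0, o], want, atol=1e-10)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(1)
        model = EvolutionSurrogate(EvolutionSurrogateSpec(depth=2, base_channels=2),
                                   seed=3, dtype=np.float64)
        model.head.weight += 0.1 * rng.standard_normal(model.head.weight.shape)
        model._mark_dirty()
        x = rng.standard_normal((2, 1, 8, 8, 8))
        y = rng.standard_normal((2, 1, 8, 8, 8))
        for _, g in model.params:
            g[...] = 0
        _, grad = nn.mse_loss(model._net_forward(x), y)
        model._net_backward(grad)
        for p, g in model.params:
            flat = p.ravel()
            for _ in range(2):
                i = rng.integers(flat.size)
                h = 1e-6
                old = flat[i]
                flat[i] = old + h
                model._mark_dirty()
                lp = nn.mse_loss(model._net_forward(x), y)[0]
                flat[i] = old - h
                model._mark_dirty()
                lm = nn.mse_loss(model._net_forward(x), y)[0]
                flat[i] = old
                model._mark_dirty()
                num = (lp - lm) / (2 * h)
                assert num == pytest.approx(g.ravel()[i], abs=1e-7, rel=1e-5)

    def test_property_gradients_match_finite_differences(self):
        rng = np.random.default_rng(2)
        model = PropertySurrogate(PropertySurrogateSpec(conv_stages=2,
                                                        base_channels=2),
                                  seed=3, dtype=np.float64)
        x = np.where(rng.random((2, 1, 8, 8, 8)) > 0.5, 1.0, -1.0)
        y = rng.standard_normal((2, 9))
        for _, g in model.params:
            g[...] = 0
        _, grad = nn.mae_loss(model._net_forward(x), y)
        model._net_backward(grad)
        for p, g in model.params:
            flat = p.ravel()
            i = rng.integers(flat.size)
            h = 1e-6
            old = flat[i]
            flat[i] = old + h
            model._mark_dirty()
            lp = nn.mae_loss(model._net_forward(x), y)[0]
            flat[i] = old - h
            model._mark_dirty()
            lm = nn.mae_loss(model._net_forward(x), y)[0]
            flat[i] = old
            model._mark_dirty()
            assert (lp - lm) / (2 * h) == pytest.approx(g.ravel()[i],
                                                        abs=1e-6, rel=1e-4)

    def test_pool_upsample_adjoint(self):
        rng = np.random.default_rng(3)
        pool = nn.AvgPool()
        x = rng.standard_normal((2, 3, 8, 8, 8))
        y = pool.forward(x)
        g = rng.standard_normal(y.shape)
        gx = pool.backward(g)
        # <pool(x), g> == <x, pool^T(g)>
        assert np.sum(y * g) == pytest.approx(np.sum(x * gx), rel=1e-10)


def _randomized(model, scale=0.1, seed=0):
    """Give the zero-initialized head real weights so the net does work."""
    rng = np.random.default_rng(seed)
    model.head.weight += (scale * rng.standard_normal(model.head.weight.shape)
                          ).astype(model.head.weight.dtype)
    model._mark_dirty()
    return model


class TestEvolutionSurrogate:
    def test_shift_equivariance_for_commensurate_shifts(self):
        model = _randomized(EvolutionSurrogate(
            EvolutionSurrogateSpec(depth=2, base_channels=4), seed=0))
        grid = GridSpec((16, 16, 16))
        field = PhaseField(np.random.default_rng(4).standard_normal(grid.shape)
                           * 0.5, grid)
        assert circular_pad_check(model, field) <= 1e-5

    def test_tile_then_crop_equivalence(self):
        """Predicting a periodic tiling equals tiling the prediction."""
        model = _randomized(EvolutionSurrogate(
            EvolutionSurrogateSpec(depth=1, base_channels=4), seed=1))
        x = np.random.default_rng(5).standard_normal((8, 8, 8)).astype(np.float32)
        tiled = np.tile(x, (2, 2, 2))
        a = model.predict(tiled)
        b = np.tile(model.predict(x), (2, 2, 2))
        assert np.max(np.abs(a - b)) <= 1e-5

    def test_reflect_padding_breaks_equivariance(self):
        circ = _randomized(EvolutionSurrogate(
            EvolutionSurrogateSpec(depth=1, base_channels=4), seed=2), seed=2)
        refl = _randomized(EvolutionSurrogate(
            EvolutionSurrogateSpec(depth=1, base_channels=4,
                                   padding_mode="reflect"), seed=2), seed=2)
        grid = GridSpec((16, 16, 16))
        field = PhaseField(np.random.default_rng(6).standard_normal(grid.shape),
                           grid)
        res_circ = circular_pad_check(circ, field)
        res_refl = circular_pad_check(refl, field)
        assert res_refl > 100 * max(res_circ, 1e-12)

    def test_untrained_model_is_identity(self):
        model = EvolutionSurrogate(EvolutionSurrogateSpec(depth=1,
                                                          base_channels=2))
        x = np.random.default_rng(7).uniform(-1, 1, (8, 8, 8)).astype(np.float32)
        assert np.allclose(model.predict(x), x, atol=1e-5)

    def test_identity_pairs_trainable_to_tiny_mse(self):
        rng = np.random.default_rng(8)
        fields = ndimage.gaussian_filter(
            rng.standard_normal((24, 1, 8, 8, 8)), sigma=(0, 0, 1, 1, 1))
        from spinodal.surrogate.datasets import PairDataset
        data = PairDataset(x=fields.astype(np.float32),
                           y=fields.astype(np.float32),
                           train_idx=np.arange(20), val_idx=np.arange(20, 24))
        spec = EvolutionSurrogateSpec(depth=1, base_channels=2)
        model, curves = train_evolution_surrogate(
            data, spec, TrainingConfig(epochs=5, batch_size=8, lr=1e-3, seed=0))
        assert curves["val_mse"][-1] < 1e-6

    def test_rollout_shape_rule_and_structure(self):
        model = EvolutionSurrogate(EvolutionSurrogateSpec(depth=2,
                                                          base_channels=2))
        grid = GridSpec((16, 16, 16))
        init = init_uniform(grid, UniformInitSpec(mu=0.0, seed=9))
        traj = rollout(model, init, 4)
        assert len(traj) == 5
        assert [f.time_index for f in traj.saves] == list(range(5))
        bad_grid = GridSpec((18, 18, 18))
        bad = init_uniform(bad_grid, UniformInitSpec(mu=0.0, seed=9))
        with pytest.raises(ValidationError, match="divisible"):
            rollout(model, bad, 2)


class TestPropertySurrogate:
    def test_shift_invariance_of_predictions(self):
        model = PropertySurrogate(PropertySurrogateSpec(conv_stages=2,
                                                        base_channels=4), seed=1)
        rng = np.random.default_rng(10)
        solid = (rng.random((16, 16, 16)) > 0.5).astype(np.float32)
        base = model.predict(solid)
        for shift in [(4, 0, 0), (0, 8, 4), (4, 4, 4)]:
            shifted = model.predict(np.roll(solid, shift, axis=(0, 1, 2)))
            assert np.max(np.abs(shifted - base)) <= 1e-4

    def test_constant_dataset_drives_mae_to_zero(self):
        rng = np.random.default_rng(11)
        solid = (rng.random((1, 1, 8, 8, 8)) > 0.5).astype(np.float32)
        structures = np.repeat(solid, 24, axis=0)
        labels = np.tile(np.linspace(1, 9, 9), (24, 1))
        data = PropertyDataset(structures=structures, labels=labels,
                               train_idx=np.arange(18),
                               val_idx=np.arange(18, 21),
                               test_idx=np.arange(21, 24),
                               extraction_steps=(1, 2, 3))
        spec = PropertySurrogateSpec(conv_stages=1, base_channels=2)
        model, metrics = train_property_surrogate(
            data, spec, TrainingConfig(epochs=60, batch_size=8, lr=3e-2, seed=0))
        assert metrics["test"]["mae"] < 0.05

    def test_learns_porosity_dependence_beats_mean_predictor(self):
        """Labels built from porosity: the net must beat predicting the mean."""
        rng = np.random.default_rng(12)
        n = 48
        structures = np.empty((n, 1, 16, 16, 16), np.float32)
        porosities = rng.uniform(0.3, 0.7, n)
        for k in range(n):
            noise = ndimage.gaussian_filter(rng.standard_normal((16, 16, 16)),
                                            1.5, mode="wrap")
            thr = np.quantile(noise, porosities[k])
            structures[k, 0] = noise > thr
        solid_frac = structures.mean(axis=(1, 2, 3, 4))
        weights = np.linspace(1.0, 3.0, 9)
        labels = solid_frac[:, None] * weights[None, :] * 10.0
        data = PropertyDataset(structures=structures, labels=labels,
                               train_idx=np.arange(36),
                               val_idx=np.arange(36, 42),
                               test_idx=np.arange(42, 48),
                               extraction_steps=(1, 2, 3))
        spec = PropertySurrogateSpec(conv_stages=2, base_channels=4)
        model, metrics = train_property_surrogate(
            data, spec, TrainingConfig(epochs=120, batch_size=8, lr=1e-2, seed=0))
        mean_pred = labels[data.train_idx].mean(axis=0)
        baseline = np.abs(labels[data.test_idx] - mean_pred).mean()
        assert metrics["test"]["mae"] < baseline


class TestDatasets:
    def test_pair_counting_identities(self):
        assert pair_counts(15, 100) == {"total": 1500, "train": 1200,
                                        "validation": 300}
        assert pair_counts(2, 10) == {"total": 20, "train": 16, "validation": 4}

    def test_property_counting_identities(self):
        assert property_counts(1800, 12) == {"total": 21600, "train": 16800,
                                             "validation": 2400, "test": 2400}
        assert property_counts(10, 12) == {"total": 120, "train": 94,
                                           "validation": 13, "test": 13}
        assert len(DEFAULT_EXTRACTION_STEPS) == 12
        assert DEFAULT_EXTRACTION_STEPS == (9, 11, 14, 18, 23, 29, 36, 44,
                                            53, 63, 74, 86)

    def test_build_pair_dataset_small_scale(self):
        params = CHParams(n_saves=6)
        data = build_pair_dataset(2, mus=(-0.2, 0.2), params=params, seed=5,
                                  grid_shape=(16, 16, 16))
        assert len(data.x) == 12 and data.splits == (10, 2)
        # pairs chain within a simulation: target k equals input k+1
        assert np.array_equal(data.y[0], data.x[1])
        assert np.array_equal(data.y[6], data.x[7])
        again = build_pair_dataset(2, mus=(-0.2, 0.2), params=params, seed=5,
                                   grid_shape=(16, 16, 16))
        assert np.array_equal(data.x, again.x)
        assert np.array_equal(data.train_idx, again.train_idx)

    def test_build_property_dataset_dry_run_and_materialized(self):
        from spinodal.design import ScreeningSampler
        from spinodal.mechanics import FFTSolverConfig

        sampler = ScreeningSampler(seed=3)
        counts = build_property_dataset(9, sampler, extraction_steps=(3, 5, 7),
                                        dry_run=True)
        assert counts == {"total": 27, "train": 21, "validation": 3, "test": 3}

        params = CHParams(n_saves=7)
        data = build_property_dataset(
            2, sampler, extraction_steps=(3, 5, 7), params=params,
            grid_shape=(16, 16, 16), seed=3,
            homogenize_kwargs={"config": FFTSolverConfig(tolerance=1e-3)})
        assert len(data.structures) == 6
        assert sorted(np.concatenate([data.train_idx, data.val_idx,
                                      data.test_idx]).tolist()) == list(range(6))
        assert np.all(np.isfinite(data.labels))
        assert data.labels.shape == (6, 9)
        # labels are genuine stiffnesses: positive diagonals, below the solid
        assert np.all(data.labels[:, [0, 3, 5, 6, 7, 8]] > 0)

    def test_nonmonotone_extraction_steps_rejected(self):
        from spinodal.design import ScreeningSampler
        with pytest.raises(ValidationError):
            build_property_dataset(2, ScreeningSampler(seed=0),
                                   extraction_steps=(5, 3), dry_run=True)
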