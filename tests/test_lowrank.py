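"""CP filter algebra, factorized prediction, loss, fitting, influence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tensortrf.cp import (
    CPFilter,
    CPTensorRegression,
    TrainConfig,
    cp_loss,
    leave_one_out_influence,
    match_components,
    predict_lowrank,
)
from tensortrf.data import zscore
from tensortrf.design import SparseEmbeddingSeries
from tensortrf.evaluation import RepeatSet, ccmax, ccnorm
from tensortrf.fullrank import FullFilter, predict_full
from tensortrf.synthetic import (
    SimConfig,
    generate_ground_truth,
    generate_word_stream,
    simulate_dataset,
)

from .conftest import dense_predict_oracle, expand_oracle, random_cp, random_series


class TestExpand:
    def test_rank1_basis_vectors_give_single_entry(self):
        f = CPFilter(
            np.eye(4)[1][None], np.eye(3)[2][None], np.eye(2)[0][None],
            np.array([1.0]),
        )
        F = f.expand()
        assert F[1, 2, 0] == 1.0
        assert np.sum(np.abs(F)) == 1.0

    def test_zero_scales_give_zero_tensor(self, rng):
        f = random_cp(rng, 3, 4, 5, 2)
        f.scales[:] = 0.0
        assert np.all(f.expand() == 0)

    def test_matches_per_entry_summation_oracle(self, rng):
        f = random_cp(rng, 3, 4, 3, 5)
        assert np.allclose(f.expand(), expand_oracle(f), atol=1e-12)


class TestPredictLowrank:
    def test_zero_scales_zero_prediction(self, rng):
        f = random_cp(rng, 2, 3, 4, 5)
        f.scales[:] = 0.0
        assert np.all(predict_lowrank(f, random_series(rng, 20, 4, 5)) == 0)

    def test_orthogonal_embedding_gives_zero(self, rng):
        f = CPFilter(
            rng.normal(size=(1, 3)), np.array([[1.0, 0.0, 0.0]]),
            rng.normal(size=(1, 2)), np.array([1.0]),
        )
        s = SparseEmbeddingSeries(10, np.array([2]), np.array([[0.0, 1.0, -1.0]]))
        assert np.allclose(predict_lowrank(f, s), 0.0, atol=1e-15)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_factorized_equals_dense_oracle(self, seed):
        """Factorized prediction equals expand-then-direct-convolution."""
        rng = np.random.default_rng(seed)
        T = int(rng.integers(5, 80))
        R = int(rng.integers(1, 4))
        D = int(rng.integers(1, min(6, T) + 1))
        N, C = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        f = random_cp(rng, R, D, N, C)
        s = random_series(rng, T, N, int(rng.integers(1, min(T, 15))))
        pred = predict_lowrank(f, s)
        oracle = dense_predict_oracle(f.expand(), s.to_dense())
        assert np.allclose(pred, oracle, rtol=1e-8, atol=1e-10)


class TestNormalize:
    def test_idempotent(self, rng):
        f = random_cp(rng, 3, 4, 5, 6).normalize()
        g = f.normalize()
        assert np.allclose(f.expand(), g.expand(), atol=1e-12)
        assert np.allclose(f.scales, g.scales, atol=1e-12)

    def test_scaling_a_row_multiplies_alpha(self, rng):
        f = random_cp(rng, 2, 4, 5, 6).normalize()
        g = CPFilter(
            f.delay_factors * np.array([[7.0], [1.0]]),
            f.embed_factors,
            f.channel_factors,
            f.scales,
        ).normalize()
        assert np.allclose(g.scales[0], 7.0 * f.scales[0], atol=1e-10)
        assert np.allclose(g.expand(), CPFilter(
            f.delay_factors * np.array([[7.0], [1.0]]), f.embed_factors,
            f.channel_factors, f.scales).expand(), atol=1e-10)

    def test_expansion_invariant_and_unit_rows(self, rng):
        f = random_cp(rng, 3, 5, 4, 6)
        g = f.normalize()
        assert np.allclose(f.expand(), g.expand(), atol=1e-10)
        for M in (g.delay_factors, g.embed_factors, g.channel_factors):
            assert np.allclose(np.linalg.norm(M, axis=1), 1.0, atol=1e-8)
        assert np.all(g.scales >= 0)

    def test_negative_scale_sign_absorbed_into_channel_factor(self, rng):
        f = random_cp(rng, 1, 3, 3, 3)
        f.scales[0] = -2.0
        g = f.normalize()
        assert g.scales[0] > 0
        assert np.allclose(f.expand(), g.expand(), atol=1e-12)

    def test_sign_flip_of_two_factor_rows_preserves_expansion(self, rng):
        f = random_cp(rng, 2, 3, 4, 5)
        g = CPFilter(
            f.delay_factors * np.array([[-1.0], [1.0]]),
            f.embed_factors * np.array([[-1.0], [1.0]]),
            f.channel_factors,
            f.scales,
        )
        assert np.allclose(f.expand(), g.expand(), atol=1e-12)

    def test_zero_row_fails(self, rng):
        f = random_cp(rng, 2, 3, 4, 5)
        f.embed_factors[1] = 0.0
        with pytest.raises(ValueError, match="zero"):
            f.normalize()


class TestLoss:
    def test_perfect_prediction_zero_penalty(self, rng):
        f = random_cp(rng, 2, 3, 4, 3)
        s = random_series(rng, 30, 4, 8)
        M = predict_lowrank(f, s)
        assert cp_loss(f, [s], [M], ridge_penalty=0.0) == pytest.approx(0.0, abs=1e-15)

    def test_zero_filter_on_zscored_data_gives_unit_loss(self, rng):
        f = random_cp(rng, 2, 3, 4, 3)
        f.scales[:] = 0.0
        s = random_series(rng, 500, 4, 30)
        M = zscore(rng.normal(size=(500, 3)))
        assert cp_loss(f, [s], [M], 0.0) == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_two_term_oracle(self, rng):
        f = random_cp(rng, 3, 4, 5, 2)
        s = random_series(rng, 40, 5, 10)
        M = rng.normal(size=(40, 2))
        lam = 0.3
        pred = dense_predict_oracle(f.expand(), s.to_dense())
        D, N, C = 4, 5, 2
        oracle = float(np.mean((pred - M) ** 2)) + lam / (C * D * N) * float(
            np.sum(f.expand() ** 2)
        )
        assert cp_loss(f, [s], [M], lam) == pytest.approx(oracle, rel=1e-10)


class TestFit:
    def test_same_seed_identical_loss_traces(self, rng):
        cfg = SimConfig(n_stories=1, samples_per_story=1500, n_channels=4,
                        embed_dim=5, n_delays=4, rank=2, noise_sd=0.3, seed=3)
        ds, _ = simulate_dataset(cfg)
        model = CPTensorRegression(ds.recordings(), ds.series_list(), 2, 4)
        t1 = model.fit(seed=9, max_epochs=60, min_epochs=1).loss_trace
        t2 = model.fit(seed=9, max_epochs=60, min_epochs=1).loss_trace
        assert np.array_equal(t1, t2)
        t3 = model.fit(seed=10, max_epochs=60, min_epochs=1).loss_trace
        assert not np.array_equal(t1, t3)

    def test_rank1_noiseless_recovery(self):
        """Noiseless rank-1 data: held-out per-channel correlation > 0.99."""
        cfg = SimConfig(n_stories=2, samples_per_story=4000, n_channels=5,
                        embed_dim=6, n_delays=5, rank=1, noise_sd=0.0, seed=21)
        ds, truth = simulate_dataset(cfg)
        model = CPTensorRegression(ds.recordings(), ds.series_list(), 1, 5)
        res = model.fit(seed=0)
        pred = res.predict(ds.test_story.series())
        target = ds.test_repeats.mean()
        for c in range(5):
            r = np.corrcoef(pred[:, c], target[:, c])[0, 1]
            assert r > 0.99

    def test_fit_on_pure_noise_has_no_heldout_skill(self):
        cfg = SimConfig(n_stories=1, samples_per_story=4000, n_channels=6,
                        embed_dim=5, n_delays=4, rank=2, noise_sd=1.0, seed=5)
        truth = generate_ground_truth(cfg)
        truth.filter.scales[:] = 0.0  # recordings are pure noise
        ds, _ = simulate_dataset(cfg, truth=truth)
        model = CPTensorRegression(ds.recordings(), ds.series_list(), 2, 4)
        res = model.fit(seed=1, max_epochs=300)
        pred = res.predict(ds.test_story.series())
        reps = ds.test_repeats
        cmax = ccmax(reps)
        obs = float(np.mean(ccnorm(pred, reps, cmax)))
        # null scale from circular shifts of the prediction
        null = []
        rng = np.random.default_rng(0)
        for _ in range(200):
            off = int(rng.integers(100, 3900))
            null.append(float(np.mean(ccnorm(np.roll(pred, off, 0), reps, cmax))))
        assert abs(obs) < 2 * np.std(null) + 2 * np.abs(np.mean(null))

    def test_mini_batches_cover_all_samples(self, rng):
        cfg = SimConfig(n_stories=2, samples_per_story=1000, n_channels=3,
                        embed_dim=4, n_delays=3, rank=1, noise_sd=0.2, seed=8)
        ds, _ = simulate_dataset(cfg)
        model = CPTensorRegression(ds.recordings(), ds.series_list(), 1, 3)
        chunks = model._batches(300, np.random.default_rng(0))
        seen = {i: np.zeros(1000, bool) for i in range(2)}
        for i, t0, t1 in chunks:
            assert not seen[i][t0:t1].any()
            seen[i][t0:t1] = True
        assert all(m.all() for m in seen.values())

    def test_minibatch_fit_still_recovers(self):
        """Batches smaller than a story: gradients remain correct."""
        cfg = SimConfig(n_stories=1, samples_per_story=6000, n_channels=5,
                        embed_dim=6, n_delays=5, rank=2, noise_sd=0.1, seed=13)
        truth = generate_ground_truth(cfg, scales=np.array([2.0, 1.0]))
        ds, _ = simulate_dataset(cfg, truth=truth)
        model = CPTensorRegression(ds.recordings(), ds.series_list(), 2, 5)
        res = model.fit(seed=2, batch_size=1500, max_epochs=400)
        _, corrs, _ = match_components(truth.filter, res.filter)
        assert corrs.min() > 0.95


class TestInfluence:
    def _eval_setup(self, seed=17):
        cfg = SimConfig(n_stories=1, samples_per_story=3000, n_channels=6,
                        embed_dim=5, n_delays=4, rank=3, noise_sd=0.3, seed=seed)
        truth = generate_ground_truth(cfg)
        ds, _ = simulate_dataset(cfg, truth=truth)
        return truth.filter, ds.test_story.series(), ds.test_repeats

    def test_matches_recompute_from_scratch(self):
        filt, series, reps = self._eval_setup()
        inf = leave_one_out_influence(filt, series, reps)
        cmax = ccmax(reps)
        full = np.mean(ccnorm(predict_lowrank(filt, series), reps, cmax))
        for r in range(3):
            # independent recomputation via the dense full-rank path
            reduced = filt.drop_component(r)
            pred = predict_full(FullFilter(reduced.expand()), series)
            expected = full - np.mean(ccnorm(pred, reps, cmax))
            assert inf[r] == pytest.approx(expected, abs=1e-10)

    def test_zero_scale_component_has_zero_influence(self):
        filt, series, reps = self._eval_setup()
        filt.scales[1] = 0.0
        inf = leave_one_out_influence(filt, series, reps)
        assert inf[1] == 0.0

    def test_duplicated_split_component_symmetric(self):
        filt, series, reps = self._eval_setup()
        half = filt.scales[0] / 2
        dup = CPFilter(
            np.vstack([filt.delay_factors[:1], filt.delay_factors]),
            np.vstack([filt.embed_factors[:1], filt.embed_factors]),
            np.vstack([filt.channel_factors[:1], filt.channel_factors]),
            np.concatenate([[half, half], filt.scales[1:]]),
            normalized=True,
        )
        inf = leave_one_out_influence(dup, series, reps)
        assert inf[0] == pytest.approx(inf[1], abs=1e-12)

    def test_single_component_removal_defines_zero_correlation(self):
        filt, series, reps = self._eval_setup()
        f1 = CPFilter(
            filt.delay_factors[:1], filt.embed_factors[:1],
            filt.channel_factors[:1], filt.scales[:1], normalized=True,
        )
        inf = leave_one_out_influence(f1, series, reps)
        cmax = ccmax(reps)
        full = np.mean(ccnorm(predict_lowrank(f1, series), reps, cmax))
        assert inf[0] == pytest.approx(full, abs=1e-12)
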