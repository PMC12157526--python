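"""Noise ceiling, CCnorm, excess-window analysis, significance tests."""

import numpy as np
import pytest

from tensortrf.evaluation import (
    RepeatSet,
    bootstrap_model_comparison,
    ccmax,
    ccnorm,
    evaluate_prediction,
    excess_ccmax,
    excess_pca,
    permutation_chance_test,
)


def _signal_noise_repeats(rng, T=2000, C=4, n=5, sig_sd=1.0, noise_sd=1.0):
    sig = sig_sd * rng.normal(size=(T, C))
    return sig, RepeatSet(sig[None] + noise_sd * rng.normal(size=(n, T, C)))


class TestCCmax:
    def test_identical_repeats_have_unit_ceiling(self, rng):
        sig = rng.normal(size=(200, 3))
        reps = RepeatSet(np.stack([sig, sig, sig]))
        assert np.allclose(ccmax(reps), 1.0, atol=1e-10)

    def test_pure_noise_clamps_to_floor(self, rng):
        reps = RepeatSet(rng.normal(size=(5, 20_000, 4)))
        assert np.all(ccmax(reps) == 0.2)

    def test_matches_closed_form_at_snr_one(self, rng):
        """Signal sd 1, noise sd 1, 5 repeats: CCmax -> sqrt(1/(1+1/5))."""
        _, reps = _signal_noise_repeats(rng, T=20_000)
        expected = np.sqrt(1.0 / (1.0 + 1.0 / 5.0))
        assert np.all(np.abs(ccmax(reps) - expected) < 0.02)

    def test_constant_channel_clamps_with_warning(self, rng):
        reps = rng.normal(size=(3, 100, 2))
        reps[:, :, 0] = 1.0
        with pytest.warns(UserWarning, match="clamped"):
            out = ccmax(RepeatSet(reps))
        assert out[0] == 0.2
        assert np.all(np.isfinite(out))


class TestCCnorm:
    def test_perfect_prediction_noiseless_gives_one(self, rng):
        sig = rng.normal(size=(300, 3))
        reps = RepeatSet(np.stack([sig, sig]))
        cm = ccmax(reps)
        assert np.allclose(ccnorm(sig, reps, cm), 1.0, atol=1e-10)

    def test_antisymmetry_under_sign_flip(self, rng):
        sig, reps = _signal_noise_repeats(rng, T=500)
        cm = ccmax(reps)
        target = reps.mean()
        assert np.allclose(
            ccnorm(-target, reps, cm), -ccnorm(target, reps, cm), atol=1e-12
        )
        assert np.allclose(ccnorm(-target, reps, cm), -1.0 / cm, atol=1e-10)

    def test_true_filter_ccnorm_approaches_one_at_low_noise(self):
        from tensortrf.cp import predict_lowrank
        from tensortrf.synthetic import (
            SimConfig, generate_ground_truth, generate_word_stream,
            simulate_repeats,
        )

        cfg = SimConfig(n_stories=1, samples_per_story=8000, n_channels=5,
                        embed_dim=6, n_delays=5, rank=2, noise_sd=0.02, seed=2)
        truth = generate_ground_truth(cfg)
        stream, emb = generate_word_stream(cfg, 0)
        reps = simulate_repeats(stream, emb, truth, cfg)
        from tensortrf.design import build_series

        pred = predict_lowrank(truth.filter,
                               build_series(stream, emb, cfg.samples_per_story))
        report = evaluate_prediction(pred, reps)
        assert 0.97 < report.mean_ccnorm < 1.03

    def test_zero_variance_prediction_defined_zero(self, rng):
        _, reps = _signal_noise_repeats(rng, T=200)
        pred = np.zeros((200, 4))
        assert np.all(ccnorm(pred, reps, ccmax(reps)) == 0.0)


class TestExcessCCmax:
    def test_stationary_noise_free_repeats_have_zero_excess(self, rng):
        sig = rng.normal(size=(4000, 3))
        reps = RepeatSet(np.stack([sig, sig]))
        onsets = np.arange(50, 3500, 37)
        ex = excess_ccmax(reps, onsets)
        assert ex.shape == (8, 3)
        assert np.allclose(ex, 0.0, atol=1e-9)

    def test_detects_injected_latency_window(self, rng):
        """Signal only 100-200 ms post onset peaks in the second window."""
        T, C = 8000, 4
        onsets = np.sort(rng.choice(np.arange(T - 50), 250, replace=False))
        sig = np.zeros((T, C))
        pat = rng.normal(size=(5, C))
        for t in onsets:
            sig[t + 5 : t + 10] += pat  # samples 5..9 post onset at 50 Hz
        reps = RepeatSet(sig[None] + rng.normal(size=(5, T, C)))
        ex = excess_ccmax(reps, onsets)
        assert ex.mean(axis=1).argmax() == 1

    def test_windows_cover_eligible_samples_once_for_sparse_onsets(self):
        T = 5000
        onsets = np.arange(100, 4000, 900)  # >800 ms apart
        sig = np.random.default_rng(0).normal(size=(T, 2))
        reps = RepeatSet(np.stack([sig, sig]))
        w = 5
        all_idx = []
        for k in range(8):
            idx = np.unique(
                (onsets[:, None] + np.arange(k * w, (k + 1) * w)).ravel()
            )
            all_idx.append(idx[(idx >= 0) & (idx < T)])
        union = np.concatenate(all_idx)
        assert union.size == np.unique(union).size  # no double counting
        assert union.size == onsets.size * 40

    def test_empty_window_fails_with_window_named(self, rng):
        sig = rng.normal(size=(30, 2))
        reps = RepeatSet(np.stack([sig, sig]))
        with pytest.raises(ValueError, match="window"):
            excess_ccmax(reps, np.array([28]))  # window 1+ has no valid samples

    def test_nearest_assignment_partitions_samples(self, rng):
        sig = rng.normal(size=(2000, 2))
        reps = RepeatSet(np.stack([sig, sig]))
        onsets = np.arange(10, 1900, 23)
        ex = excess_ccmax(reps, onsets, assignment="nearest")
        assert ex.shape == (8, 2)


class TestExcessPCA:
    def test_rank_one_matrix_single_component(self, rng):
        excess = np.outer(rng.normal(size=8), rng.normal(size=5))  # windows x C
        _, _, evr = excess_pca(excess)
        assert evr[0] == pytest.approx(1.0, abs=1e-10)

    def test_two_orthogonal_patterns_recovered_up_to_sign(self, rng):
        w = 8
        p1 = np.zeros(w); p1[1] = 1.0
        p2 = np.zeros(w); p2[5] = 1.0
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        excess = (np.outer(p1, a) + np.outer(p2, b))  # windows x channels
        tc, load, evr = excess_pca(excess)
        span = np.vstack([p1, p2])
        for comp in tc:
            # each PC lies in the span of the two injected patterns
            proj = span.T @ np.linalg.lstsq(span.T, comp, rcond=None)[0]
            assert np.allclose(proj, comp, atol=1e-8)
        assert evr.sum() <= 1.0 + 1e-12

    def test_variance_ratios_bounded(self, rng):
        _, _, evr = excess_pca(rng.normal(size=(8, 30)))
        assert np.all(evr >= 0) and evr.sum() <= 1.0 + 1e-12


class TestBootstrap:
    def test_identical_vectors_give_half(self, rng):
        a = rng.normal(size=50)
        assert bootstrap_model_comparison(a, a.copy(), seed=1) == pytest.approx(0.5)

    def test_uniform_improvement_gives_zero(self, rng):
        b = rng.normal(size=40)
        assert bootstrap_model_comparison(b + 1.0, b, seed=1) == 0.0

    def test_matches_enumeration_on_tiny_vector(self, rng):
        """Large-n_boot estimate agrees with exhaustive resample enumeration."""
        from itertools import product

        diff = np.array([0.5, 0.3, -0.4, -0.1, 0.2])
        exact = 0.0
        for combo in product(range(5), repeat=5):
            m = diff[list(combo)].mean()
            exact += (m < 0) + 0.5 * (m == 0)
        exact /= 5**5
        est = bootstrap_model_comparison(diff, np.zeros(5), n_boot=200_000, seed=3)
        assert est == pytest.approx(exact, abs=0.005)

    def test_small_n_boot_warns(self, rng):
        with pytest.warns(UserWarning):
            bootstrap_model_comparison(np.ones(5), np.zeros(5), n_boot=10, seed=0)


class TestPermutationTest:
    def test_perfect_prediction_attains_minimum_p(self, rng):
        sig, reps = _signal_noise_repeats(rng, T=1500)
        p = permutation_chance_test(reps.mean(), reps, n_perm=99, block_len=50,
                                    seed=4)
        assert p == pytest.approx(1.0 / 100.0)

    def test_offsets_respect_block_length(self, rng):
        """Null shifts are never smaller than block_len (zero shift excluded)."""
        T = 1000
        block = 50
        offs = np.random.default_rng(7).integers(block, T - block + 1, size=5000)
        assert offs.min() >= block
        assert offs.max() <= T - block

    def test_too_short_series_fails(self, rng):
        _, reps = _signal_noise_repeats(rng, T=80)
        with pytest.raises(ValueError, match="short"):
            permutation_chance_test(reps.mean(), reps, block_len=50)
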