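import numpy as np
import pytest

from dualseq.sequences import SEQUENCE_ORDERS
from dualseq.synthdata import (SimConfig, generate_dataset, half_sine,
                               make_topographies, render_epochs,
                               sample_trial_onsets)


class TestTopographies:
    def test_unit_norm_and_separation(self):
        topo = make_topographies(6, 32, seed=1)
        assert topo.shape == (6, 32)
        norms = np.linalg.norm(topo, axis=1)
        assert np.allclose(norms, 1.0)
        cos = topo @ topo.T - np.eye(6)
        assert np.abs(cos).max() <= 0.3

    def test_two_channels_forced_orthogonal(self):
        topo = make_topographies(2, 2, seed=5)
        assert abs(topo[0] @ topo[1]) < 1e-10

    def test_deterministic(self):
        assert np.array_equal(make_topographies(6, 32, 1),
                              make_topographies(6, 32, 1))

    def test_impossible_separation(self):
        with pytest.raises(ValueError):
            make_topographies(8, 4, seed=0)


class TestTrialOnsets:
    def test_long_condition_is_serial_and_bounded(self, rng):
        cfg = SimConfig()
        for _ in range(50):
            tr = sample_trial_onsets(cfg, 0, "Long", rng)
            assert tr.sequence_label == "A"
            assert max(tr.onsets[op] for op in ("E1", "C1", "R1")) < cfg.soa_long_ms
            ons = [tr.onsets[op] for op in SEQUENCE_ORDERS["A"]]
            assert ons == sorted(ons)

    def test_gamma_stage_means(self):
        # gamma(shape 2, scale mean/2) has the configured mean
        cfg = SimConfig(stage_mean_ms=((100.0, 100.0, 100.0),) * 2)
        rng = np.random.default_rng(0)
        e1 = [sample_trial_onsets(cfg, 0, "Long", rng).onsets["E1"]
              for _ in range(1000)]
        se = 100.0 / np.sqrt(2) / np.sqrt(1000)
        assert abs(np.mean(e1) - 100.0) < 3 * se

    @pytest.mark.parametrize("label", list("ABCDEF"))
    def test_short_labels_order_by_construction(self, label, rng):
        mix = tuple(1.0 if l == label else 0.0 for l in "ABCDEF")
        cfg = SimConfig(strategy_mixture=mix)
        for _ in range(20):
            tr = sample_trial_onsets(cfg, 0, "Short", rng)
            assert tr.sequence_label == label
            ons = [tr.onsets[op] for op in SEQUENCE_ORDERS[label]]
            assert ons == sorted(ons)
            # Task 2 onsets causal w.r.t. the Task 2 stimulus
            assert tr.onsets["E2"] > cfg.soa_short_ms

    def test_rt_respects_response_onset(self, rng):
        cfg = SimConfig()
        tr = sample_trial_onsets(cfg, 0, "Short", rng)
        assert tr.rt1_ms >= tr.onsets["R1"]
        assert tr.rt2_ms >= tr.onsets["R2"] - tr.soa_ms

    def test_unknown_condition(self, rng):
        with pytest.raises(ValueError):
            sample_trial_onsets(SimConfig(), 0, "Medium", rng)


class TestRenderEpochs:
    def test_noise_free_single_event_matches_template(self):
        cfg = SimConfig(noise_sd=0.0, n_channels=8)
        rng = np.random.default_rng(0)
        tr = sample_trial_onsets(cfg, 0, "Long", rng)
        topo = make_topographies(6, 8, seed=2)
        ep, _ = render_epochs([tr], topo, cfg, rng, task=1)
        fs = cfg.fs
        W = int(round(cfg.event_width_ms / 1000 * fs))
        wave = half_sine(W)
        c = ep.stim_sample[0] + int(round(tr.onsets["E1"] / 1000 * fs))
        seg = ep.data[0, :, c - W // 2:c - W // 2 + W]
        expect = np.outer(topo[0], wave)
        assert np.allclose(seg, expect, atol=1e-5)

    def test_zero_amplitude_gives_zero_mean_noise(self):
        cfg = SimConfig(amplitude=0.0, noise_sd=1.0, n_channels=8)
        rng = np.random.default_rng(1)
        tr = sample_trial_onsets(cfg, 0, "Long", rng)
        ep, _ = render_epochs([tr], make_topographies(6, 8, 1), cfg, rng, task=1)
        x = ep.data[0, :, :ep.valid_samples[0]]
        assert abs(x.mean()) < 5.0 / np.sqrt(x.size)

    def test_deterministic_given_seed(self, small_config):
        a, _ = generate_dataset(small_config)
        b, _ = generate_dataset(small_config)
        for task in (1, 2):
            assert np.array_equal(a[task].data, b[task].data)


class TestGenerateDataset:
    def test_trial_count_arithmetic(self, small_dataset, small_config):
        epochs, truth = small_dataset
        n = (small_config.n_participants * small_config.trials_per_condition * 2)
        assert epochs[1].n_trials == n
        assert epochs[2].n_trials == n
        assert len(truth) == n

    def test_long_condition_always_label_A(self, small_dataset):
        _, truth = small_dataset
        assert (truth.loc[truth.condition == "Long", "sequence_label"] == "A").all()

    def test_uniform_mixture_frequencies(self):
        cfg = SimConfig(n_participants=3, trials_per_condition=100,
                        strategy_mixture=(1 / 6,) * 6, seed=21)
        _, truth = generate_dataset(cfg)
        short = truth[truth.condition == "Short"]
        n = len(short)
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        freq = short["sequence_label"].value_counts(normalize=True)
        for lab in "ABCDEF":
            assert abs(freq.get(lab, 0.0) - 1 / 6) < 3 * se + 1e-12

    def test_truth_ordering_invariant(self, small_dataset):
        _, truth = small_dataset
        for task_ops in (("E1", "C1", "R1"), ("E2", "C2", "R2")):
            a, b, c = (truth[f"onset_{op}"] for op in task_ops)
            assert ((a < b) & (b < c)).all()

    def test_signal_energy_at_onsets_exceeds_baseline(self):
        # stated regime: noise_sd below half the event amplitude
        cfg = SimConfig(n_participants=2, trials_per_condition=20,
                        noise_sd=0.2, seed=5)
        epochs, truth = generate_dataset(cfg)
        ep = epochs[1]
        fs = cfg.fs
        W = int(round(cfg.event_width_ms / 1000 * fs))
        wave = half_sine(W)
        wave /= np.linalg.norm(wave)
        long_idx = np.flatnonzero((ep.metadata.condition == "Long").to_numpy())[:40]
        at_onset, baseline = [], []
        for i in long_idx:
            x = ep.data[i, :, :ep.valid_samples[i]].astype(float)
            m = np.array([np.convolve(ch, wave[::-1], mode="same") for ch in x])
            energy = np.linalg.norm(m, axis=0)
            row = truth.set_index("trial").loc[ep.metadata.trial.iloc[i]]
            for op in ("E1", "C1", "R1"):
                c = ep.stim_sample[i] + int(round(row[f"onset_{op}"] / 1000 * fs))
                at_onset.append(energy[c])
            baseline.append(np.median(energy[:ep.stim_sample[i]]))
        assert np.median(at_onset) > 2 * np.median(baseline)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"fs": 0.0},
        {"n_channels": 1},
        {"strategy_mixture": (0.5, 0.5, 0.0, 0.0, 0.0, 0.1)},
        {"stage_mean_ms": ((0.0, 100.0, 100.0), (80.0, 160.0, 160.0))},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs).validate()
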