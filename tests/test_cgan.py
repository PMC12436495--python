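"""Conditional GAN: losses, filtering, sampling, augmentation, training
contracts and the leakage guard."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import butter, freqz

from ergan import cgan, dataio
from ergan import fixtures as fx
from ergan.grid import DEFAULT_GRID

TINY = dict(epochs=64, scale_factor=1 / 32)  # 2 effective epochs


def tiny_gan(train, seed=0, **over):
    cfg = cgan.CGANTrainConfig(seed=seed, **{**TINY, **over})
    return cgan.train_cgan(train, cfg)


class TestGanLosses:
    def test_perfect_discriminator_limit(self):
        d, g = cgan.gan_losses(1 - 1e-9, 1e-9, eps=1e-12)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_uninformative_scores_give_log2_losses(self):
        d, g = cgan.gan_losses(0.5, 0.5)
        assert d == pytest.approx(2 * np.log(2), abs=1e-12)
        assert g == pytest.approx(np.log(2), abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.floats(1e-6, 1 - 1e-6), st.floats(1e-6, 1 - 1e-6)
    )
    def test_matches_scalar_bce_oracle(self, dr, df):
        d, g = cgan.gan_losses(dr, df, eps=1e-12)
        # independent scalar binary cross-entropy computation
        bce_d = -(np.log(dr) + np.log(1 - df))
        assert abs(d - bce_d) < 1e-12
        assert abs(g - (-np.log(df))) < 1e-12

    def test_saturating_form_available(self):
        _, g = cgan.gan_losses(0.5, 0.25, non_saturating=False)
        assert g == pytest.approx(np.log(0.75), abs=1e-12)

    def test_boundary_scores_clamped_and_logged(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="ergan.cgan"):
            d, g = cgan.gan_losses(1.0, 0.0, eps=1e-7)
        assert np.isfinite(d) and np.isfinite(g)
        assert any("clamped" in r.message for r in caplog.records)


class TestButterworth:
    def test_constant_signal_unchanged(self):
        x = np.full(235, 3.7)
        y = cgan.lowpass_butterworth(x)
        assert np.abs(y - x).max() < 1e-9

    def test_minus_3db_at_cutoff(self):
        # single-pass magnitude response at the 300 Hz cutoff
        b, a = butter(4, 300.0, btype="low", fs=DEFAULT_GRID.fs)
        w, h = freqz(b, a, worN=[300.0], fs=DEFAULT_GRID.fs)
        assert 20 * np.log10(abs(h[0])) == pytest.approx(-3.01, abs=0.05)

    def test_attenuation_at_double_cutoff_matches_closed_form(self):
        """|H| at 600 Hz >= 24 dB down, consistent with the analytic
        Butterworth magnitude 1/sqrt(1 + (f/fc)^(2n))."""
        n, fc = 4, 300.0
        analytic_db = -10 * np.log10(1 + (600.0 / fc) ** (2 * n))
        b, a = butter(n, fc, btype="low", fs=DEFAULT_GRID.fs)
        _, h = freqz(b, a, worN=[600.0], fs=DEFAULT_GRID.fs)
        got_db = 20 * np.log10(abs(h[0]))
        assert got_db <= -24.0
        # the digital design warps frequencies toward Nyquist, so it
        # attenuates at least as much as the analog prototype
        assert got_db <= analytic_db + 0.5

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            cgan.lowpass_butterworth(np.zeros(235), cutoff_hz=1200.0)

    def test_filter_suppresses_high_frequency_ripple(self, grid, rng):
        t = grid.times * 1e-3
        clean = np.sin(2 * np.pi * 50 * t)
        noisy = clean + 0.5 * np.sin(2 * np.pi * 800 * t)
        filtered = cgan.lowpass_butterworth(noisy)
        assert np.abs(filtered - clean).max() < 0.1


@pytest.fixture(scope="module")
def trained_tiny(tiny_train_module):
    return tiny_gan(tiny_train_module, seed=11)


@pytest.fixture(scope="module")
def tiny_train_module():
    pop = fx.PopulationConfig(counts={1.204: (12, 12)}, seed=5)
    ds = fx.generate_dataset(pop)
    split = dataio.split_train_test(ds, 0.25, seed=5)
    return dataio.normalize(split.train)


class TestTraining:
    def test_completes_and_scores_stay_in_unit_interval(self, trained_tiny, tiny_train_module):
        m = trained_tiny
        assert len(m.history) == m.config.effective_epochs * 2
        assert np.isfinite(m.history[["d_loss", "g_loss"]].to_numpy()).all()
        y = np.zeros(4, dtype=int)
        onehot = np.eye(2)[y]
        scores = m.discriminator(tiny_train_module.X[:4], onehot).data
        assert np.all((scores > 0) & (scores < 1))

    def test_fixed_seed_reproduces_loss_history(self, tiny_train_module):
        a = tiny_gan(tiny_train_module, seed=3)
        b = tiny_gan(tiny_train_module, seed=3)
        assert a.history.equals(b.history)

    def test_rejects_untagged_dataset(self, tiny_dataset):
        ds = dataio.normalize(tiny_dataset)
        with pytest.raises(cgan.LeakageError):
            cgan.train_cgan(ds, cgan.CGANTrainConfig(**TINY))

    def test_rejects_test_partition(self, tiny_dataset):
        split = dataio.split_train_test(tiny_dataset, 0.25, seed=0)
        te = dataio.normalize(split.test)
        with pytest.raises(cgan.LeakageError):
            cgan.train_cgan(te, cgan.CGANTrainConfig(**TINY))

    def test_rejects_unnormalized_by_default(self, tiny_dataset):
        split = dataio.split_train_test(tiny_dataset, 0.25, seed=0)
        with pytest.raises(ValueError, match="normalis"):
            cgan.train_cgan(split.train, cgan.CGANTrainConfig(**TINY))

    def test_recovers_constant_target(self, grid):
        """Trained on a single-class constant dataset, the generator mean
        converges to the constant within 10%."""
        import pandas as pd

        n, level = 24, 0.5
        meta = pd.DataFrame(
            {"id": [f"r{i}" for i in range(n)], "subject": "s", "eye": "L",
             "group": 0, "strength": 1.204, "replicate": 1, "synthetic": False}
        )
        ds = dataio.LabeledDataset(X=np.full((n, 235), level), meta=meta, grid=grid)
        ds.partition = "train"
        cfg = cgan.CGANTrainConfig(
            epochs=2400, scale_factor=1 / 32, seed=0, require_normalized=False
        )
        model = cgan.train_cgan(ds, cfg)
        out = cgan.sample_synthetic(model, 0, 16, seed=1, filter_hz=None)
        assert out.X.mean() == pytest.approx(level, rel=0.10)


def test_converged_synthetic_means_track_real_class_means():
    """After a longer desk-scale run the per-class mean synthetic waveform
    correlates strongly (r >= 0.8) with the per-class mean real waveform."""
    from ergan import benchmarks

    row = benchmarks.conditional_fidelity(seeds=[3], effective_epochs=100)[0]
    assert row["r0"] >= 0.8
    assert row["r1"] >= 0.8


class TestSampling:
    def test_empty_request(self, trained_tiny):
        out = cgan.sample_synthetic(trained_tiny, 1, 0)
        assert len(out) == 0

    def test_output_length_labels_and_flags(self, trained_tiny):
        out = cgan.sample_synthetic(trained_tiny, 1, 5, seed=2)
        assert out.X.shape == (5, 235)
        assert np.all(out.y == 1)
        assert out.meta["synthetic"].all()
        assert out.normalization is None  # back in data units

    def test_seeded_sampling_reproducible(self, trained_tiny):
        a = cgan.sample_synthetic(trained_tiny, 0, 4, seed=9)
        b = cgan.sample_synthetic(trained_tiny, 0, 4, seed=9)
        np.testing.assert_array_equal(a.X, b.X)

    def test_amplitudes_inverse_normalized(self, trained_tiny):
        # tanh output lives in [-1, 1]; data units must reflect the stored
        # normalisation constants instead
        norm = trained_tiny.normalization
        out = cgan.sample_synthetic(trained_tiny, 0, 8, seed=2, filter_hz=None)
        assert out.X.min() >= norm.c0 - 1e-6
        assert out.X.max() <= norm.c1 + 1e-6

    def test_checkpoint_round_trip(self, trained_tiny, tmp_path):
        trained_tiny.save(tmp_path / "ckpt")
        loaded = cgan.TrainedCGAN.load(tmp_path / "ckpt")
        a = cgan.sample_synthetic(trained_tiny, 1, 3, seed=4)
        b = cgan.sample_synthetic(loaded, 1, 3, seed=4)
        np.testing.assert_array_equal(a.X, b.X)


class TestAugment:
    def test_two_to_one_ratio_counts(self, trained_tiny, tiny_train_module):
        out = cgan.augment(tiny_train_module, trained_tiny, 2.0)
        for cls in (0, 1):
            n_real = int(np.sum(tiny_train_module.y == cls))
            n_synth = int(
                np.sum(out.meta["synthetic"] & (out.y == cls))
            )
            assert n_synth == round(n_real / 2.0)

    def test_additions_proportional_to_class_counts(self, trained_tiny):
        pop = fx.PopulationConfig(counts={1.204: (20, 10)}, seed=1)
        ds = fx.generate_dataset(pop)
        split = dataio.split_train_test(ds, 0.25, seed=1)
        tr = dataio.normalize(split.train)
        out = cgan.augment(tr, trained_tiny, 2.0)
        per_class_real = {c: int(np.sum(tr.y == c)) for c in (0, 1)}
        for c in (0, 1):
            got = int(np.sum(out.meta["synthetic"] & (out.y == c)))
            assert got == round(per_class_real[c] / 2.0)

    def test_infinite_or_nonpositive_ratio_rejected(self, trained_tiny, tiny_train_module):
        for bad in (np.inf, 0.0, -2.0, np.nan):
            with pytest.raises(ValueError):
                cgan.augment(tiny_train_module, trained_tiny, bad)
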