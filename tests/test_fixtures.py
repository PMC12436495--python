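"""Synthetic-ERG generator: morphology, baseline, growth and separability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ergan import fixtures as fx
from ergan.grid import TimeGrid


def lobe_sum_oracle(shape: fx.ErgShapeParams, t: np.ndarray) -> np.ndarray:
    """Independent closed-form evaluation of the noise-free a/b lobe sum."""
    ramp = np.where(
        t <= 0, 0.0, 0.5 * (1 - np.cos(np.pi * np.minimum(t / 5.0, 1.0)))
    )
    a = -shape.a_amp * np.exp(-((t - shape.a_time) ** 2) / (2 * shape.a_width**2))
    b = shape.b_amp * np.exp(-((t - shape.b_time) ** 2) / (2 * shape.b_width**2))
    return ramp * (a + b)


class TestWaveform:
    def test_default_grid_length(self, grid, rng):
        w = fx.generate_waveform(fx.ErgShapeParams(), grid, rng)
        assert w.shape == (235,)

    def test_zero_parameters_give_zero_waveform(self, grid, rng):
        shape = fx.ErgShapeParams(a_amp=0, b_amp=0, op_amp=0, noise_sd=0, drift_amp=0)
        assert np.all(fx.generate_waveform(shape, grid, rng) == 0.0)

    def test_prestimulus_baseline_exactly_zero_without_noise(self, grid, rng):
        shape = fx.ErgShapeParams(noise_sd=0, drift_amp=0)
        w = fx.generate_waveform(shape, grid, rng)
        pre = w[grid.times <= 0]
        assert pre.size >= 39
        assert np.all(pre == 0.0)

    def test_bwave_peak_matches_closed_form_lobe_sum(self, grid, rng):
        """With OPs removed the peak equals the direct lobe-sum evaluation."""
        shape = fx.ErgShapeParams(op_amp=0.0, noise_sd=0, drift_amp=0)
        w = fx.generate_waveform(shape, grid, rng)
        t = grid.times
        win = (t > shape.b_time - shape.b_width) & (t < shape.b_time + shape.b_width)
        expected = lobe_sum_oracle(shape, t)[win].max()
        assert w[win].max() == pytest.approx(expected, abs=1e-12)
        # and the peak approaches b_amp (a-lobe overlap is small)
        assert w[win].max() == pytest.approx(shape.b_amp, rel=0.02)

    def test_op_ripple_confined_to_window(self, grid, rng):
        quiet = fx.ErgShapeParams(op_amp=0, noise_sd=0, drift_amp=0)
        ripply = fx.ErgShapeParams(op_amp=8.0, noise_sd=0, drift_amp=0)
        d = fx.generate_waveform(ripply, grid, rng) - fx.generate_waveform(
            quiet, grid, rng
        )
        t = grid.times
        w0, w1 = ripply.op_window
        assert np.all(d[(t < w0) | (t > w1)] == 0.0)
        assert np.abs(d[(t >= w0) & (t <= w1)]).max() > 1.0

    @pytest.mark.parametrize(
        "field,value",
        [("a_width", 0.0), ("b_width", -1.0), ("op_window", (5.0, 90.0)),
         ("a_time", 40.0)],
    )
    def test_invalid_shape_parameters_name_the_field(self, field, value):
        with pytest.raises(ValueError):
            fx.ErgShapeParams(**{field: value})

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            TimeGrid(n_samples=1)
        with pytest.raises(ValueError):
            TimeGrid(t_start=10.0, t_end=-10.0)

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_baseline_is_zero_mean_on_average(self, seed):
        """Noise and drift are zero-mean, so the expected pre-stimulus
        value is zero for every configuration."""
        grid = TimeGrid()
        rng = np.random.default_rng(seed)
        shape = fx.ErgShapeParams()
        pre = np.concatenate(
            [fx.generate_waveform(shape, grid, rng)[grid.times < 0] for _ in range(40)]
        )
        assert abs(pre.mean()) < 5 * shape.noise_sd / np.sqrt(pre.size) + 0.2


class TestStrengthGain:
    def test_normalised_at_maximum_strength(self):
        assert fx.strength_gain(1.204) == pytest.approx(1.0)

    def test_strictly_increasing_over_protocol_strengths(self):
        g = fx.strength_gain(np.array(sorted(fx.FLASH_STRENGTHS)))
        assert np.all(np.diff(g) > 0)
        assert np.all((g > 0) & (g <= 1))


class TestDataset:
    def test_study_counts_totals_match_per_strength_table(self):
        ds = fx.generate_dataset(fx.PopulationConfig(seed=0))
        expect_case = sum(c[1] for c in fx.STUDY_COUNTS.values())
        expect_control = sum(c[0] for c in fx.STUDY_COUNTS.values())
        counts = ds.class_counts()
        assert counts[1] == expect_case
        assert counts[0] == expect_control
        assert ds.X.shape == (expect_case + expect_control, 235)

    def test_minimal_population_of_two(self):
        pop = fx.PopulationConfig(counts={0.5: (1, 1)}, seed=0)
        ds = fx.generate_dataset(pop)
        assert len(ds) == 2
        assert sorted(ds.y) == [0, 1]

    def test_fixed_seed_is_bit_reproducible(self):
        pop = fx.PopulationConfig(counts={1.204: (5, 5), 0.114: (4, 6)}, seed=42)
        a = fx.generate_dataset(pop)
        b = fx.generate_dataset(pop)
        assert np.array_equal(a.X, b.X)
        assert a.meta.equals(b.meta)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            fx.PopulationConfig(counts={})
        with pytest.raises(ValueError, match="empty"):
            fx.generate_dataset(fx.PopulationConfig(counts={1.204: (0, 0)}))

    def test_group_effect_bounds(self):
        with pytest.raises(ValueError):
            fx.PopulationConfig(group_effect=0.0)
        with pytest.raises(ValueError):
            fx.PopulationConfig(group_effect=1.5)

    def test_mean_peak_grows_monotonically_with_strength(self):
        """Deterministic records: b-wave peak strictly increasing over the
        nine protocol strengths under the saturating gain."""
        counts = {s: (3, 0) for s in fx.FLASH_STRENGTHS}
        pop = fx.PopulationConfig(
            counts=counts, subject_sd=0, amp_jitter_sd=0, latency_jitter_sd=0, seed=0
        )
        base = fx.ErgShapeParams(noise_sd=0, drift_amp=0)
        ds = fx.generate_dataset(pop, base)
        peaks = [
            ds.X[ds.strengths == s].max(axis=1).mean()
            for s in sorted(fx.FLASH_STRENGTHS)
        ]
        assert np.all(np.diff(peaks) > 0)

    def test_case_class_attenuated_and_null_exchangeable(self):
        n = 100
        for ge, separated in ((0.8, True), (1.0, False)):
            pop = fx.PopulationConfig(counts={1.204: (n, n)}, group_effect=ge, seed=5)
            ds = fx.generate_dataset(pop)
            pk = ds.X.max(axis=1)
            d0, d1 = pk[ds.y == 0], pk[ds.y == 1]
            se = np.sqrt(d0.var() / n + d1.var() / n)
            z = (d0.mean() - d1.mean()) / se
            if separated:
                assert z > 4.0  # control peaks clearly larger
            else:
                assert abs(z) < 4.0

    def test_pseudo_subject_structure(self, tiny_dataset):
        meta = tiny_dataset.meta
        assert meta["subject"].nunique() > 1
        # subjects never span groups
        assert (meta.groupby("subject")["group"].nunique() == 1).all()
        assert set(meta["eye"]) <= {"L", "R"}
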