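"""Volume-conduction simulator: activations, mixing, interference, sessions."""

import numpy as np
import pytest

from periemg.simulate import (
    ACTIONS,
    FaceGeometry,
    NoiseSpec,
    ProtocolSpec,
    build_mixing_matrix,
    default_geometry,
    generate_activation,
    independent_burst_sources,
    mix_sources,
    schedule_epochs,
    simulate_session,
)

RATE = 1000.0


class TestGenerateActivation:
    def test_forceful_rms_twice_normal_monte_carlo(self, short_protocol):
        """Intensity scale 2 doubles epoch RMS of the amplitude-modulated
        Gaussian source, up to sampling error (averaged over 100 seeds)."""
        ratios = []
        for seed in range(100):
            normal = generate_activation(
                "purse_lips", "normal", short_protocol, RATE, seed
            )
            forceful = generate_activation(
                "purse_lips", "forceful", short_protocol, RATE, seed
            )
            rms = lambda x: np.sqrt(np.mean(x[x != 0] ** 2))
            ratios.append(rms(forceful.samples) / rms(normal.samples))
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)

    def test_zero_amplitude_gives_all_zero_activation(self, short_protocol):
        act = generate_activation(
            "frown", "normal", short_protocol, RATE, seed=0, amplitude=0.0
        )
        assert not act.samples.any()

    def test_same_seed_is_bit_identical(self, short_protocol):
        a = generate_activation("close_eyes", "forceful", short_protocol, RATE, seed=7)
        b = generate_activation("close_eyes", "forceful", short_protocol, RATE, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_unknown_labels_rejected(self, short_protocol):
        with pytest.raises(ValueError):
            generate_activation("smirk", "normal", short_protocol, RATE, 0)
        with pytest.raises(ValueError):
            generate_activation("frown", "gentle", short_protocol, RATE, 0)

    def test_silent_outside_scheduled_windows(self, short_protocol):
        act = generate_activation("frown", "forceful", short_protocol, RATE, seed=3)
        epochs, total = schedule_epochs(short_protocol, RATE)
        mask = np.zeros(total, dtype=bool)
        for ep in epochs:
            if ep.action == "frown" and ep.intensity == "forceful":
                mask[ep.onset_sample : ep.end_sample] = True
        assert not act.samples[~mask].any()
        assert act.samples[mask].any()


class TestMixingMatrix:
    def test_inverse_distance_coefficient_ratio(self):
        geom = FaceGeometry(
            electrode_labels=("e1", "e2"),
            electrode_positions=np.array([[1.0, 0.0], [2.0, 0.0]]),
            source_labels=("s1",),
            source_positions=np.array([[0.0, 0.0]]),
        )
        model = build_mixing_matrix(geom)
        assert model.matrix[0, 0] / model.matrix[1, 0] == pytest.approx(2.0)

    def test_equidistant_sources_get_equal_coefficients(self):
        geom = FaceGeometry(
            electrode_labels=("e1",),
            electrode_positions=np.array([[0.0, 0.0]]),
            source_labels=("a", "b", "c"),
            source_positions=np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]]),
        )
        row = build_mixing_matrix(geom).matrix[0]
        assert np.allclose(row, row[0])

    def test_default_montage_is_16_by_8(self):
        model = build_mixing_matrix(default_geometry())
        assert model.matrix.shape == (16, 8)
        assert np.all(model.matrix >= 0)

    def test_coincident_electrode_and_source_rejected(self):
        geom = FaceGeometry(
            electrode_labels=("e1",),
            electrode_positions=np.array([[1.0, 1.0]]),
            source_labels=("s1",),
            source_positions=np.array([[1.0, 1.0]]),
        )
        with pytest.raises(ValueError):
            build_mixing_matrix(geom)

    def test_coefficient_decreases_with_distance(self):
        geom = FaceGeometry(
            electrode_labels=tuple(f"e{i}" for i in range(5)),
            electrode_positions=np.column_stack(
                [np.arange(1.0, 6.0), np.zeros(5)]
            ),
            source_labels=("s1",),
            source_positions=np.array([[0.0, 0.0]]),
        )
        col = build_mixing_matrix(geom, exponent=2.0).matrix[:, 0]
        assert np.all(np.diff(col) < 0)


class TestMixSources:
    def _sources(self, short_protocol, labels):
        return [
            generate_activation(
                "purse_lips", "forceful", short_protocol, RATE, seed=i, source_id=lab
            )
            for i, lab in enumerate(labels)
        ]

    def test_identity_matrix_passes_sources_through(self, short_protocol):
        srcs = self._sources(short_protocol, ["a", "b"])
        from periemg.simulate import MixingModel

        model = MixingModel(
            electrode_labels=["e1", "e2"],
            source_labels=["a", "b"],
            matrix=np.eye(2),
        )
        rec = mix_sources(srcs, model)
        np.testing.assert_array_equal(rec.samples[0], srcs[0].samples)
        np.testing.assert_array_equal(rec.samples[1], srcs[1].samples)

    def test_matches_brute_force_dot_product(self, short_protocol, rng):
        from periemg.simulate import MixingModel

        srcs = self._sources(short_protocol, ["a", "b", "c"])
        A = rng.uniform(0.1, 1.0, size=(4, 3))
        model = MixingModel(
            electrode_labels=list("wxyz"), source_labels=["a", "b", "c"], matrix=A
        )
        rec = mix_sources(srcs, model)
        S = np.vstack([s.samples for s in srcs])
        for i in range(4):
            for t in (0, 100, 500):
                assert rec.samples[i, t] == pytest.approx(
                    sum(A[i, j] * S[j, t] for j in range(3)), abs=1e-12
                )

    def test_scaling_sources_scales_mixture(self, short_protocol):
        from periemg.simulate import MixingModel, SourceActivation

        srcs = self._sources(short_protocol, ["a", "b"])
        scaled = [
            SourceActivation(s.source_id, s.action, s.intensity, 3.0 * s.samples, s.rate)
            for s in srcs
        ]
        model = MixingModel(
            electrode_labels=["e1", "e2"],
            source_labels=["a", "b"],
            matrix=np.array([[0.5, 0.25], [0.1, 0.9]]),
        )
        np.testing.assert_allclose(
            mix_sources(scaled, model).samples,
            3.0 * mix_sources(srcs, model).samples,
        )

    def test_label_order_mismatch_rejected(self, short_protocol):
        from periemg.simulate import MixingModel

        srcs = self._sources(short_protocol, ["b", "a"])
        model = MixingModel(
            electrode_labels=["e1", "e2"], source_labels=["a", "b"], matrix=np.eye(2)
        )
        with pytest.raises(ValueError, match="order mismatch"):
            mix_sources(srcs, model)


class TestAddInterference:
    def _recording(self, rng):
        from periemg.codec import Recording

        return Recording(samples=rng.standard_normal((2, 4000)), rate=RATE)

    def test_zero_noise_is_identity(self, rng):
        from periemg.simulate import add_interference

        rec = self._recording(rng)
        out = add_interference(
            rec, NoiseSpec(powerline_amplitude=0, dc_offset=0.0, white_noise_sd=0)
        )
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_powerline_peak_in_difference_spectrum(self, rng):
        from periemg.simulate import add_interference

        rec = self._recording(rng)
        out = add_interference(
            rec,
            NoiseSpec(powerline_amplitude=0.5, dc_offset=0.0, white_noise_sd=0, seed=1),
        )
        diff = out.samples[0] - rec.samples[0]
        spectrum = np.abs(np.fft.rfft(diff))
        freqs = np.fft.rfftfreq(diff.size, 1 / RATE)
        assert freqs[np.argmax(spectrum)] == pytest.approx(50.0, abs=0.5)

    def test_dc_offset_shifts_mean_exactly(self, rng):
        from periemg.simulate import add_interference

        rec = self._recording(rng)
        out = add_interference(
            rec, NoiseSpec(powerline_amplitude=0, dc_offset=0.7, white_noise_sd=0)
        )
        np.testing.assert_allclose(
            out.samples.mean(axis=1) - rec.samples.mean(axis=1), 0.7, atol=1e-12
        )

    def test_powerline_at_or_above_nyquist_rejected(self, rng):
        from periemg.simulate import add_interference

        rec = self._recording(rng)
        with pytest.raises(ValueError):
            add_interference(rec, NoiseSpec(powerline_freq=500.0))


class TestSimulateSession:
    def test_default_counts_give_150_epochs(self, short_protocol):
        # Full default label vocabulary at compressed timing: the epoch count
        # depends only on the protocol arithmetic 1 x 2 x 5 x 2 here.
        _, epochs = simulate_session(short_protocol, seed=0)
        assert len(epochs) == 1 * 2 * 5 * 2
        assert ProtocolSpec().n_epochs == 3 * 5 * 5 * 2 == 150

    def test_unit_protocol_single_epoch(self):
        proto = ProtocolSpec(
            actions=("frown",),
            intensities=("forceful",),
            reps_per_block=1,
            blocks=1,
            action_duration_s=0.4,
            rest_duration_s=0.1,
            cue_duration_s=0.1,
            interblock_rest_s=0.1,
        )
        rec, epochs = simulate_session(proto, seed=0)
        assert len(epochs) == 1
        assert epochs[0].duration_samples == int(0.4 * RATE)

    def test_same_seed_regenerates_identical_session(self, short_protocol):
        rec1, eps1 = simulate_session(short_protocol, seed=5)
        rec2, eps2 = simulate_session(short_protocol, seed=5)
        np.testing.assert_array_equal(rec1.samples, rec2.samples)
        assert eps1 == eps2

    def test_epochs_tile_without_overlap_inside_recording(self, short_protocol):
        rec, epochs = simulate_session(short_protocol, seed=2)
        spans = sorted((e.onset_sample, e.end_sample) for e in epochs)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        assert spans[-1][1] <= rec.n_samples


class TestIndependentBurstSources:
    def test_shape_and_mutual_independence(self):
        S = independent_burst_sources(4, 10.0, RATE, seed=0, bursts_per_source=2)
        assert S.shape == (4, 10000)
        corr = np.corrcoef(S)
        off_diag = corr[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off_diag) < 0.1)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            independent_burst_sources(8, 1.0, RATE, seed=0)
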