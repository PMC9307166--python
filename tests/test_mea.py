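"""MEA simulation, electrical images, artifact-axis fit, classification."""

import numpy as np
import pytest

from magstimcal import mea


@pytest.fixture(scope="module")
def small_layout():
    return mea.hex_layout(n_cols=8, n_rows=4)  # 32 electrodes


def _stim(seq, magnitude=50.0, duration_per_segment=0.05):
    return mea.MagStimulusSequence(vertex_indices=np.array(seq),
                                   magnitude=magnitude,
                                   segment_duration=duration_per_segment)


class TestIcosahedron:
    def test_unit_norms(self):
        v = mea.icosahedron_directions()
        assert v.shape == (12, 3)
        assert np.allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-12)

    def test_pairwise_dot_products(self):
        v = mea.icosahedron_directions()
        inv_sqrt5 = 1 / np.sqrt(5)
        for i in range(12):
            for j in range(12):
                if i == j:
                    continue
                d = v[i] @ v[j]
                assert min(abs(d - inv_sqrt5), abs(d + inv_sqrt5), abs(d + 1)) < 1e-9

    def test_antipodal_symmetry(self):
        v = mea.icosahedron_directions()
        for vec in v:
            assert np.min(np.linalg.norm(v + vec, axis=1)) < 1e-12


class TestStimulusSequence:
    def test_consecutive_segments_differ(self):
        stim = mea.random_vertex_sequence(500, seed=4)
        assert np.all(np.diff(stim.vertex_indices) != 0)

    def test_reproducible_and_transition_log(self):
        a = mea.random_vertex_sequence(50, seed=9)
        b = mea.random_vertex_sequence(50, seed=9)
        assert np.array_equal(a.vertex_indices, b.vertex_indices)
        assert len(a.transition_times) == 49
        assert a.transition_times[0] == pytest.approx(0.2)

    def test_antipodal_transition_has_largest_step(self):
        stim = mea.random_vertex_sequence(10, seed=0)
        v = stim.directions
        steps = [np.linalg.norm(stim.delta_b(i, j))
                 for i in range(12) for j in range(12) if i != j]
        assert max(steps) == pytest.approx(100.0)  # 2 x 50 uT


class TestLayout:
    def test_default_counts_and_extent(self):
        layout = mea.hex_layout()
        assert layout.n_electrodes == 512
        assert layout.positions[:, 0].min() >= 0
        assert layout.positions[:, 0].max() <= 1890
        assert layout.positions[:, 1].max() <= 900


class TestElectricalImage:
    def test_single_noiseless_event_recovers_template(self, small_layout):
        fs = small_layout.sampling_rate
        n = int(0.2 * fs)
        traces = np.zeros((small_layout.n_electrodes, n))
        t0 = 0.1
        window = np.arange(n) / fs
        kern = 25.0 * mea.spike_kernel(window - t0)
        traces[3] = kern
        img = mea.electrical_image(traces, fs, [t0], window_ms=(-1, 2))
        c = int(round(t0 * fs))
        i_lo = int(round(-1e-3 * fs))
        assert np.array_equal(img.waveforms[3], traces[3][c + i_lo:c + i_lo + img.waveforms.shape[1]])
        assert img.event_count == 1

    def test_noise_shrinks_with_event_count(self, small_layout, rng):
        fs = small_layout.sampling_rate
        stds = []
        for n_ev in (4, 16, 64):
            traces = rng.normal(0, 5.0, (4, int(fs * 10)))
            times = np.linspace(0.5, 9.5, n_ev)
            img = mea.electrical_image(traces, fs, times)
            stds.append(img.waveforms.std())
        assert stds[0] / stds[1] == pytest.approx(2.0, rel=0.25)
        assert stds[1] / stds[2] == pytest.approx(2.0, rel=0.25)

    def test_edge_events_dropped_and_counted(self, small_layout):
        fs = small_layout.sampling_rate
        traces = np.zeros((2, int(0.1 * fs)))
        img = mea.electrical_image(traces, fs, [0.0, 0.05], window_ms=(-1, 2))
        assert img.event_count == 1 and img.dropped_events == 1
        with pytest.raises(ValueError):
            mea.electrical_image(traces, fs, [0.0], window_ms=(-1, 2))

    def test_artifact_latency_dispersion_zero_noise_free(self, small_layout):
        stim = _stim([0, 6] * 10)
        rec = mea.simulate_recording(small_layout, [], stim,
                                     coupling=(-1.5, 1.3, 0.1), duration=1.0,
                                     noise_std=0.0, seed=1)
        images = mea.transition_triggered_images(rec)
        img = images[(0, 6)]
        lat = img.peak_latency
        assert np.allclose(lat, lat[0])


class TestSpikePropagation:
    def test_latency_increases_along_axon(self):
        """Toy 3-electrode line along the axon: delay grows at 1 m/s."""
        pos = np.array([[0.0, 0.0], [300.0, 0.0], [600.0, 0.0]])
        tmpl = mea.SpikeTemplate(soma=(0.0, 0.0), amplitude=300.0,
                                 axon_end=(600.0, 0.0), velocity=1.0)
        amp, delay = mea._footprint(tmpl, pos)
        assert delay[0] == 0.0
        assert delay[1] == pytest.approx(300e-6, rel=1e-9)  # 300 um at 1 m/s
        assert delay[2] == pytest.approx(600e-6, rel=1e-9)
        assert amp[0] > amp[1] >= amp[2]

    def test_zero_phase_bandpass_preserves_latency(self, small_layout):
        """filtfilt is zero-phase: the planted template's peak moves by at
        most one sample."""
        fs = small_layout.sampling_rate
        t = np.arange(int(0.5 * fs)) / fs
        trace = 300.0 * mea.spike_kernel(t - 0.25)[None, :].repeat(2, axis=0)
        from scipy.signal import sosfiltfilt
        sos = mea._bandpass_sos((80.0, 2000.0), fs)
        filt = sosfiltfilt(sos, trace, axis=1)
        assert abs(int(np.argmax(np.abs(filt[0]))) -
                   int(np.argmax(np.abs(trace[0])))) <= 1


class TestTransitionImages:
    def test_zero_coupling_average_vanishes(self, small_layout):
        stim = _stim(list(range(12)) * 3)
        rec = mea.simulate_recording(small_layout, [], stim, coupling=(0, 0, 0),
                                     duration=1.7, noise_std=2.0, seed=5)
        images = mea.transition_triggered_images(rec)
        worst = max(img.peak_amplitude.max() for img in images.values())
        assert worst < 5 * 2.0  # noise floor only

    def test_polarity_antisymmetry_noise_free(self, small_layout):
        stim = _stim([0, 3] * 12)
        rec = mea.simulate_recording(small_layout, [], stim,
                                     coupling=(-1.5, 1.3, 0.1), duration=1.2,
                                     noise_std=0.0, seed=6)
        images = mea.transition_triggered_images(rec)
        fwd, bwd = images[(0, 3)], images[(3, 0)]
        peak = np.abs(fwd.waveforms).max()
        assert np.allclose(fwd.waveforms, -bwd.waveforms, atol=1e-9 * peak)

    def test_peaks_exactly_linear_in_field_step(self, small_layout):
        stim = mea.random_vertex_sequence(40, seed=7, segment_duration=0.05)
        c = np.array([-1.5, 1.3, 0.1])
        rec = mea.simulate_recording(small_layout, [], stim, coupling=c,
                                     duration=2.0, noise_std=0.0, seed=8)
        images = mea.transition_triggered_images(rec)
        fit = mea.fit_artifact_axis(images, stim)
        assert fit["r_squared"] > 1 - 1e-9
        assert np.abs(fit["axis"] - c / np.linalg.norm(c)).max() < 1e-6


class TestArtifactAxisFit:
    def _images_for_axis(self, axis, noise, rng, n_el=32, n_events=20):
        """Synthetic per-transition images with a planted coupling axis."""
        axis = np.asarray(axis) / np.linalg.norm(axis)
        stim = _stim([0])
        dirs = mea.icosahedron_directions()
        fs = 20000.0
        t = (np.arange(41) - 20) / fs
        kern = mea.artifact_kernel(t)
        images = {}
        for a in range(12):
            for b in range(12):
                if a == b:
                    continue
                peak = 2.0 * (50.0 * (dirs[b] - dirs[a])) @ axis
                w = peak * np.tile(kern, (n_el, 1))
                w += rng.normal(0, noise / np.sqrt(n_events), w.shape)
                images[(a, b)] = mea.ElectricalImage(
                    waveforms=w, window=t, event_class=(a, b),
                    event_count=n_events)
        return images, stim

    def test_recovers_planted_axis_with_noise(self, rng):
        axis = np.array([-0.74, 0.67, 0.07])
        images, stim = self._images_for_axis(axis, noise=10.0, rng=rng)
        fit = mea.fit_artifact_axis(images, stim)
        cosang = abs(fit["axis"] @ (axis / np.linalg.norm(axis)))
        assert np.degrees(np.arccos(min(cosang, 1.0))) < 2.0
        assert fit["r_squared"] >= 0.99

    def test_exact_recovery_noise_free(self, rng):
        images, stim = self._images_for_axis((0.0, 0.0, 1.0), noise=0.0, rng=rng)
        fit = mea.fit_artifact_axis(images, stim)
        assert np.allclose(np.abs(fit["axis"]), [0, 0, 1], atol=1e-9)
        assert fit["r_squared"] == pytest.approx(1.0, abs=1e-12)

    def test_recovery_improves_with_events(self, rng):
        errs = []
        for n_events in (5, 50):
            angs = []
            for _ in range(10):
                images, stim = self._images_for_axis(
                    (-0.74, 0.67, 0.07), noise=60.0, rng=rng, n_events=n_events)
                fit = mea.fit_artifact_axis(images, stim)
                ref = np.array([-0.74, 0.67, 0.07])
                ref = ref / np.linalg.norm(ref)
                angs.append(np.arccos(min(abs(fit["axis"] @ ref), 1.0)))
            errs.append(np.mean(angs))
        assert errs[1] < errs[0]

    def test_too_few_classes_rejected(self, rng):
        images, stim = self._images_for_axis((0, 0, 1.0), noise=0.0, rng=rng)
        few = {k: images[k] for k in list(images)[:3]}
        with pytest.raises(ValueError):
            mea.fit_artifact_axis(few, stim)


class TestClassifier:
    def _image(self, waveforms, fs=20000.0):
        n = waveforms.shape[1]
        return mea.ElectricalImage(waveforms=waveforms,
                                   window=(np.arange(n) - n // 2) / fs,
                                   event_class="x", event_count=1)

    def test_uniform_simultaneous_artifact_spread_one(self):
        kern = mea.artifact_kernel((np.arange(41) - 20) / 20000.0)
        img = self._image(100.0 * np.tile(kern, (64, 1)))
        res = mea.classify_event(img)
        assert res["spread"] == 1.0
        assert res["label"] == "artifact"

    def test_single_electrode_artifact_looks_like_spike(self):
        """The documented ambiguity: an artifact confined to one electrode is
        indistinguishable from a spike."""
        kern = mea.artifact_kernel((np.arange(41) - 20) / 20000.0)
        w = np.zeros((64, 41))
        w[10] = 100.0 * kern
        res = mea.classify_event(self._image(w))
        assert res["label"] == "spike"

    def test_all_zero_image_unclassifiable(self):
        res = mea.classify_event(self._image(np.zeros((8, 41))))
        assert res["label"] == "unclassifiable"

    def test_default_scenario_perfect_separation(self):
        res = mea.classifier_scenario(seed=0)
        assert len(res["labels"]) == 367 + 144
        assert res["n_misclassified"] == 0
        spikes = res["spread"][res["labels"] == "spike"]
        arts = res["spread"][res["labels"] == "artifact"]
        assert spikes.max() < arts.min()  # disjoint in spread alone


class TestTriggeredStimulusAverage:
    def test_independent_events_give_flat_average(self, rng):
        frames = rng.integers(0, 2, 6000).astype(float)  # 50 s of binary noise
        times = rng.uniform(1.0, 49.0, 400)
        avg = mea.triggered_stimulus_average(times, frames, 120.0, n_lags=20)
        assert np.abs(avg - 0.5).max() < 5 * np.sqrt(0.25 / 400)

    def test_on_cell_average_rises_before_spike(self, rng):
        """A cell firing one frame after bright frames shows an elevated
        average at that lag."""
        frames = rng.integers(0, 2, 12000).astype(float)
        bright = np.nonzero(frames[:-2] == 1)[0]
        chosen = rng.choice(bright, 500, replace=False)
        times = (chosen + 1 + 0.5) / 120.0  # one frame later
        avg = mea.triggered_stimulus_average(times, frames, 120.0, n_lags=10)
        assert avg[1] == pytest.approx(1.0, abs=1e-12)  # the driving frame
        assert abs(avg[5] - 0.5) < 0.1  # uncorrelated lag stays at the mean

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            mea.triggered_stimulus_average([], np.zeros(100))
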