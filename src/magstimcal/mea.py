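"""Synthetic multielectrode-array recordings and induction-artifact analysis.

Rapid magnetic field transitions induce dB/dt-proportional voltage transients
in the recording chain.  On a single electrode the band-limited artifact can
resemble a biological spike, but its spatiotemporal footprint differs
sharply: a spike originates at a soma and propagates along the axon (local,
with growing latency), while the induction artifact appears simultaneously
and near-identically across the whole array.  This module simulates both,
computes electrical images (per-electrode average waveforms around an event),
averages artifacts per ordered field transition, regresses the artifact
amplitude against the field step to recover the coupling axis, and separates
spikes from artifacts by a spatial-spread / latency-dispersion statistic.

Units: electrode positions in um, time in s, signals in uV, fields in uT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "ElectrodeArrayLayout",
    "SpikeTemplate",
    "MagStimulusSequence",
    "ElectricalImage",
    "Recording",
    "hex_layout",
    "icosahedron_directions",
    "random_vertex_sequence",
    "simulate_recording",
    "electrical_image",
    "transition_triggered_images",
    "fit_artifact_axis",
    "classify_event",
    "classifier_scenario",
    "triggered_stimulus_average",
]

DEFAULT_SAMPLING_RATE = 20000.0  # Hz; must exceed twice the 2 kHz band edge
DEFAULT_BANDPASS = (80.0, 2000.0)  # Hz
SPIKE_DECAY_UM = 30.0  # spatial decay constant of the soma footprint
AXON_VELOCITY = 1.0  # m/s
SPREAD_THRESHOLD = 0.5  # classifier: artifact needs > this electrode fraction
DISPERSION_THRESHOLD_MS = 0.2  # classifier: artifact needs < this latency std
SUPRA_FRACTION = 0.3  # electrode counts as active above this fraction of max


# ----------------------------------------------------------------------------
# Geometry and stimulus
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeArrayLayout:
    """Planar electrode positions (um) and the sampling rate (Hz)."""

    positions: np.ndarray  # (n, 2)
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        object.__setattr__(self, "positions", pos)

    @property
    def n_electrodes(self) -> int:
        return self.positions.shape[0]


def hex_layout(width: float = 1890.0, height: float = 900.0,
               n_cols: int = 32, n_rows: int = 16,
               sampling_rate: float = DEFAULT_SAMPLING_RATE) -> ElectrodeArrayLayout:
    """Hexagonally packed array filling a width x height (um) rectangle.

    Defaults give 512 electrodes over 1890 um x 900 um (32 columns of 16
    rows, alternate rows offset by half a pitch).  The exact commercial
    geometry is not public; this is a stated stand-in with the same count and
    extent.
    """
    xs = np.linspace(0.0, width, n_cols)
    ys = np.linspace(0.0, height, n_rows)
    pitch = xs[1] - xs[0] if n_cols > 1 else width
    pos = []
    for r, y in enumerate(ys):
        offset = 0.25 * pitch if r % 2 else -0.25 * pitch
        for x in xs:
            pos.append((float(np.clip(x + offset, 0.0, width)), y))
    return ElectrodeArrayLayout(positions=np.array(pos), sampling_rate=sampling_rate)


def icosahedron_directions() -> np.ndarray:
    """The 12 unit vertices of a regular icosahedron.

    Fixed orientation: cyclic permutations of (0, +-1, +-phi) normalised,
    phi the golden ratio.  Antipodally symmetric; non-self pairwise dot
    products take only the values +-1/sqrt(5) and -1.
    """
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    base = []
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            base.append((0.0, s1, s2 * phi))
            base.append((s1, s2 * phi, 0.0))
            base.append((s2 * phi, 0.0, s1))
    v = np.array(base)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


@dataclass
class MagStimulusSequence:
    """Random piecewise-constant field sequence over the icosahedron vertices.

    Every ``segment_duration`` (default 200 ms) a new vertex is drawn (always
    different from the current one); segments have ``magnitude`` (default
    50 uT).
    """

    vertex_indices: np.ndarray  # (n_segments,)
    magnitude: float
    segment_duration: float
    directions: np.ndarray = field(default_factory=icosahedron_directions)
    seed: int = 0

    @property
    def n_segments(self) -> int:
        return len(self.vertex_indices)

    @property
    def transition_times(self) -> np.ndarray:
        """Times of the switches between segments (s), excluding t = 0."""
        return self.segment_duration * np.arange(1, self.n_segments)

    @property
    def transitions(self) -> list[tuple[int, int]]:
        """(from_vertex, to_vertex) for each switch."""
        idx = self.vertex_indices
        return list(zip(idx[:-1].tolist(), idx[1:].tolist()))

    def delta_b(self, from_idx: int, to_idx: int) -> np.ndarray:
        """Field step (uT) of an ordered transition."""
        return self.magnitude * (self.directions[to_idx] - self.directions[from_idx])


def random_vertex_sequence(n_segments: int, seed: int,
                           magnitude: float = 50.0,
                           segment_duration: float = 0.2) -> MagStimulusSequence:
    """Random vertex sequence with consecutive segments always differing."""
    rng = np.random.default_rng(seed)
    idx = np.empty(n_segments, dtype=int)
    idx[0] = rng.integers(12)
    for k in range(1, n_segments):
        step = rng.integers(1, 12)  # skip 0 => never repeat
        idx[k] = (idx[k - 1] + step) % 12
    return MagStimulusSequence(vertex_indices=idx, magnitude=magnitude,
                               segment_duration=segment_duration, seed=seed)


# ----------------------------------------------------------------------------
# Spike and artifact templates
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeTemplate:
    """A ganglion-cell footprint: soma position, peak amplitude, spatial decay,
    a straight axon path with constant conduction velocity, and a biphasic
    temporal kernel."""

    soma: tuple[float, float]  # um
    amplitude: float  # uV, peak at the soma
    decay: float = SPIKE_DECAY_UM  # um
    axon_end: tuple[float, float] | None = None  # um; None = no axon
    velocity: float = AXON_VELOCITY  # m/s
    kernel_sigma: float = 2e-4  # s, width of the biphasic waveform
    axon_gain: float = 0.4  # axonal amplitude relative to the soma

    def __post_init__(self):
        if self.amplitude <= 0 or self.velocity <= 0:
            raise ValueError("amplitude and velocity must be positive")


def spike_kernel(t: np.ndarray, sigma: float = 2e-4) -> np.ndarray:
    """Biphasic waveform (derivative of a Gaussian), peak magnitude 1 and zero
    integral."""
    t = np.asarray(t, dtype=float)
    return -(t / sigma) * np.exp(0.5 - t * t / (2.0 * sigma * sigma))


def artifact_kernel(t: np.ndarray, sigma: float = 3e-4) -> np.ndarray:
    """Induction-artifact waveform: dB/dt of a smooth (error-function) field
    step, i.e. a Gaussian pulse with peak 1.  The recording band-pass is what
    shapes it further in a simulation."""
    t = np.asarray(t, dtype=float)
    return np.exp(-t * t / (2.0 * sigma * sigma))


def _footprint(template: SpikeTemplate, positions: np.ndarray):
    """Per-electrode amplitude (uV) and delay (s) of a spike template.

    Amplitude decays as 1/(1 + (distance/decay)^2) from the nearest point of
    the soma-axon path; the delay is that point's arc length over the
    conduction velocity; the axonal amplitude tapers to ``axon_gain`` over the
    first 100 um of axon.
    """
    soma = np.asarray(template.soma, dtype=float)
    if template.axon_end is None:
        d = np.linalg.norm(positions - soma, axis=1)
        s = np.zeros_like(d)
    else:
        end = np.asarray(template.axon_end, dtype=float)
        seg = end - soma
        L2 = seg @ seg
        rel = positions - soma
        tpar = np.clip(rel @ seg / L2, 0.0, 1.0) if L2 > 0 else np.zeros(len(rel))
        nearest = soma + tpar[:, None] * seg
        d = np.linalg.norm(positions - nearest, axis=1)
        s = tpar * np.sqrt(L2)
    taper = 1.0 - (1.0 - template.axon_gain) * np.clip(s / 100.0, 0.0, 1.0)
    amp = template.amplitude * taper / (1.0 + (d / template.decay) ** 2)
    delay = s * 1e-6 / template.velocity  # um -> m
    return amp, delay


# ----------------------------------------------------------------------------
# Recording simulation
# ----------------------------------------------------------------------------

@dataclass
class Recording:
    """Simulated band-passed MEA traces plus the ground truth that made them."""

    traces: np.ndarray  # (n_electrodes, n_samples) uV
    layout: ElectrodeArrayLayout
    spike_times: list[np.ndarray]  # per cell, s
    stimulus: MagStimulusSequence | None
    coupling: np.ndarray  # (3,) uV per uT of field step
    duration: float

    @property
    def sampling_rate(self) -> float:
        return self.layout.sampling_rate


def _bandpass_sos(band: tuple[float, float], fs: float):
    low, high = band
    if not (0 < low < high < fs / 2):
        raise ValueError(f"invalid band edges {band} for fs = {fs} Hz")
    return butter(2, [low, high], btype="bandpass", fs=fs, output="sos")


def simulate_recording(layout: ElectrodeArrayLayout,
                       cells: Sequence[tuple[SpikeTemplate, float]],
                       stimulus: MagStimulusSequence | None,
                       coupling,
                       duration: float,
                       noise_std: float = 10.0,
                       electrode_scale: np.ndarray | None = None,
                       bandpass: tuple[float, float] | None = DEFAULT_BANDPASS,
                       seed: int = 0) -> Recording:
    """Simulate MEA traces: Poisson spikes + induction artifacts + noise.

    ``cells`` pairs each template with its Poisson firing rate (Hz).  At each
    stimulus transition an artifact with peak amplitude ``(c . dB) * scale_e``
    is added *simultaneously* on all electrodes (scale_e defaults to 1,
    matching the observation that electrode routing has no apparent effect).
    The trace is zero-phase band-pass filtered (Butterworth, forward-backward)
    unless ``bandpass`` is None.
    """
    fs = layout.sampling_rate
    if bandpass is not None and fs <= 2 * bandpass[1]:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    rng = np.random.default_rng(seed)
    n_samp = int(round(duration * fs))
    n_el = layout.n_electrodes
    coupling = np.asarray(coupling, dtype=float)
    scale = np.ones(n_el) if electrode_scale is None else np.asarray(electrode_scale)
    traces = np.zeros((n_el, n_samp))
    if noise_std > 0:
        traces += rng.normal(0.0, noise_std, size=traces.shape)

    t_axis = np.arange(n_samp) / fs
    spike_times: list[np.ndarray] = []
    for template, rate in cells:
        n_exp = rate * duration
        if n_exp > 1e6:
            raise ValueError("rate x duration too large")
        n_spk = rng.poisson(n_exp)
        times = np.sort(rng.uniform(0.0, duration, size=n_spk))
        spike_times.append(times)
        amp, delay = _footprint(template, layout.positions)
        active = np.nonzero(amp > 1e-3 * template.amplitude)[0]
        half = 6.0 * template.kernel_sigma
        for t0 in times:
            for e in active:
                tc = t0 + delay[e]
                i0 = max(0, int((tc - half) * fs))
                i1 = min(n_samp, int((tc + half) * fs) + 1)
                if i1 <= i0:
                    continue
                traces[e, i0:i1] += amp[e] * spike_kernel(t_axis[i0:i1] - tc,
                                                          template.kernel_sigma)

    if stimulus is not None:
        half = 5 * 3e-4
        for (a, b), tt in zip(stimulus.transitions, stimulus.transition_times):
            if tt >= duration:
                break
            peak = coupling @ stimulus.delta_b(a, b)
            i0 = max(0, int((tt - half) * fs))
            i1 = min(n_samp, int((tt + half) * fs) + 1)
            kern = artifact_kernel(t_axis[i0:i1] - tt)
            traces[:, i0:i1] += peak * scale[:, None] * kern[None, :]

    if bandpass is not None:
        sos = _bandpass_sos(bandpass, fs)
        traces = sosfiltfilt(sos, traces, axis=1)
    return Recording(traces=traces, layout=layout, spike_times=spike_times,
                     stimulus=stimulus, coupling=coupling, duration=duration)


# ----------------------------------------------------------------------------
# Electrical images
# ----------------------------------------------------------------------------

@dataclass
class ElectricalImage:
    """Per-electrode average waveform around an event class."""

    waveforms: np.ndarray  # (n_electrodes, n_window) uV
    window: np.ndarray  # (n_window,) s, relative to the event
    event_class: object
    event_count: int
    dropped_events: int = 0

    @property
    def peak_amplitude(self) -> np.ndarray:
        """Per-electrode peak absolute amplitude (uV)."""
        return np.max(np.abs(self.waveforms), axis=1)

    @property
    def peak_latency(self) -> np.ndarray:
        """Per-electrode time (s) of the absolute peak, relative to the event."""
        return self.window[np.argmax(np.abs(self.waveforms), axis=1)]


def electrical_image(traces: np.ndarray, fs: float, event_times,
                     window_ms: tuple[float, float] = (-1.0, 2.0),
                     event_class: object = "spike") -> ElectricalImage:
    """Average spatiotemporal waveform around the given event times.

    Events whose window would cross the trace boundary are dropped (counted in
    ``dropped_events``).
    """
    traces = np.asarray(traces)
    event_times = np.atleast_1d(np.asarray(event_times, dtype=float))
    if event_times.size == 0:
        raise ValueError("at least one event time is required")
    i_lo = int(round(window_ms[0] * 1e-3 * fs))
    i_hi = int(round(window_ms[1] * 1e-3 * fs))
    n_samp = traces.shape[1]
    acc = np.zeros((traces.shape[0], i_hi - i_lo))
    used = 0
    for t0 in event_times:
        c = int(round(t0 * fs))
        if c + i_lo < 0 or c + i_hi > n_samp:
            continue
        acc += traces[:, c + i_lo:c + i_hi]
        used += 1
    if used == 0:
        raise ValueError("all events fell outside the trace bounds")
    window = np.arange(i_lo, i_hi) / fs
    return ElectricalImage(waveforms=acc / used, window=window,
                           event_class=event_class, event_count=used,
                           dropped_events=len(event_times) - used)


def transition_triggered_images(recording: Recording,
                                window_ms: tuple[float, float] = (-1.0, 2.0),
                                ) -> dict[tuple[int, int], ElectricalImage]:
    """One ElectricalImage per observed ordered field transition (a -> b).

    Transition classes never observed are simply absent from the map.
    """
    stim = recording.stimulus
    if stim is None:
        raise ValueError("recording has no magnetic stimulus")
    by_class: dict[tuple[int, int], list[float]] = {}
    for pair, tt in zip(stim.transitions, stim.transition_times):
        if tt < recording.duration:
            by_class.setdefault(pair, []).append(tt)
    out = {}
    for pair, times in by_class.items():
        try:
            out[pair] = electrical_image(recording.traces, recording.sampling_rate,
                                         times, window_ms, event_class=pair)
        except ValueError:
            continue  # all events at the edge
    return out


def fit_artifact_axis(images: dict[tuple[int, int], ElectricalImage],
                      stimulus: MagStimulusSequence) -> dict:
    """Regress per-class artifact amplitude on the field step dB.

    The per-class scalar amplitude is the spatially averaged waveform's signed
    value at its absolute peak.  Returns the normalised coefficient 3-vector
    (the coupling axis), the raw coefficients (uV/uT) and R^2.
    """
    pairs = [p for p in images if p[0] != p[1]]
    if len(pairs) < 4:
        raise ValueError("need at least 4 transition classes")
    db = np.array([stimulus.delta_b(a, b) for a, b in pairs])
    if np.linalg.matrix_rank(db) < 3:
        raise ValueError("field steps do not span three dimensions")
    amps = np.empty(len(pairs))
    for k, p in enumerate(pairs):
        mean_wave = images[p].waveforms.mean(axis=0)
        amps[k] = mean_wave[np.argmax(np.abs(mean_wave))]
    coef, _, _, _ = np.linalg.lstsq(db, amps, rcond=None)
    pred = db @ coef
    ss_res = float(np.sum((amps - pred) ** 2))
    ss_tot = float(np.sum((amps - amps.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    norm = np.linalg.norm(coef)
    return {"axis": coef / norm if norm > 0 else coef,
            "coefficients": coef, "r_squared": r2}


# ----------------------------------------------------------------------------
# Spike / artifact classification
# ----------------------------------------------------------------------------

def _spread_dispersion(peaks: np.ndarray, latencies: np.ndarray):
    """Classifier features from per-electrode peaks (uV) and latencies (s)."""
    mx = peaks.max()
    if mx <= 0:
        return None
    supra = peaks > SUPRA_FRACTION * mx
    spread = float(supra.mean())
    lat = latencies[supra]
    dispersion_ms = float(np.std(lat) * 1e3) if lat.size >= 2 else float("nan")
    return spread, dispersion_ms


def classify_event(image: ElectricalImage,
                   spread_threshold: float = SPREAD_THRESHOLD,
                   dispersion_threshold_ms: float = DISPERSION_THRESHOLD_MS) -> dict:
    """Label an electrical image as biological spike or induction artifact.

    Spread index = fraction of electrodes whose peak exceeds 30% of the array
    maximum; latency dispersion = std (ms) of peak latencies over those
    electrodes.  An artifact is global and simultaneous (spread above
    threshold AND dispersion below threshold); anything else is a spike.  A
    single supra-threshold electrode leaves dispersion undefined (NaN) but the
    tiny spread already labels the event a spike — this is exactly the
    single-electrode ambiguity in which an artifact restricted to one
    electrode is indistinguishable from a spike.  With no supra-threshold
    electrode the event is unclassifiable.
    """
    feats = _spread_dispersion(image.peak_amplitude, image.peak_latency)
    if feats is None:
        return {"label": "unclassifiable", "spread": 0.0,
                "dispersion_ms": float("nan")}
    spread, dispersion = feats
    is_artifact = spread > spread_threshold and (
        not np.isnan(dispersion) and dispersion < dispersion_threshold_ms)
    return {"label": "artifact" if is_artifact else "spike",
            "spread": spread, "dispersion_ms": dispersion}


# ----------------------------------------------------------------------------
# Default classification scenario
# ----------------------------------------------------------------------------

def classifier_scenario(seed: int, n_spikes: int = 367, n_artifacts: int = 144,
                        layout: ElectrodeArrayLayout | None = None,
                        window_ms: float = 2.0,
                        image_noise_std: float = 1.0,
                        coupling_axis=(-0.74, 0.67, 0.07),
                        coupling_gain: float = 2.0) -> dict:
    """Generate spike and artifact electrical images and classify them.

    The default sizes mirror a typical recording session: 367 cell images
    versus 144 artifact images.  Spike images use random somata, axon
    directions and amplitudes through the same footprint/kernel model as
    :func:`simulate_recording`; artifact images use the artifact kernel scaled
    by ``coupling_gain * (axis . dB)`` with dB drawn from the icosahedron
    transitions.  ``image_noise_std`` (uV) is the residual noise of the
    averaged image.  Returns features, labels and classification results.
    """
    if layout is None:
        layout = hex_layout()
    rng = np.random.default_rng(seed)
    fs = layout.sampling_rate
    pos = layout.positions
    n_el = layout.n_electrodes
    n_t = int(round(window_ms * 1e-3 * fs)) + 1
    t = (np.arange(n_t) - n_t // 2) / fs

    # --- spike images -------------------------------------------------------
    w, h = pos[:, 0].max(), pos[:, 1].max()
    somata = np.column_stack([rng.uniform(0, w, n_spikes),
                              rng.uniform(0, h, n_spikes)])
    theta = rng.uniform(0, 2 * np.pi, n_spikes)
    axon_len = rng.uniform(300.0, 700.0, n_spikes)
    amplitude = rng.uniform(150.0, 400.0, n_spikes)
    amps = np.empty((n_spikes, n_el), dtype=np.float32)
    delays = np.empty((n_spikes, n_el), dtype=np.float32)
    for k in range(n_spikes):
        end = somata[k] + axon_len[k] * np.array([np.cos(theta[k]), np.sin(theta[k])])
        tmpl = SpikeTemplate(soma=tuple(somata[k]), amplitude=float(amplitude[k]),
                             axon_end=tuple(end))
        a, d = _footprint(tmpl, pos)
        amps[k], delays[k] = a, d
    sigma = 2e-4
    spike_waves = amps[:, :, None] * spike_kernel(
        t[None, None, :] - delays[:, :, None], sigma).astype(np.float32)
    spike_waves += image_noise_std * rng.standard_normal(spike_waves.shape,
                                                         dtype=np.float32)

    # --- artifact images ----------------------------------------------------
    dirs = icosahedron_directions()
    axis = np.asarray(coupling_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a_idx = rng.integers(0, 12, n_artifacts)
    b_idx = (a_idx + rng.integers(1, 12, n_artifacts)) % 12
    db = 50.0 * (dirs[b_idx] - dirs[a_idx])
    peaks = coupling_gain * db @ axis  # uV
    art_waves = (peaks[:, None, None].astype(np.float32)
                 * np.ones((1, n_el, 1), dtype=np.float32)
                 * artifact_kernel(t).astype(np.float32)[None, None, :])
    art_waves += image_noise_std * rng.standard_normal(art_waves.shape,
                                                       dtype=np.float32)

    waves = np.concatenate([spike_waves, art_waves], axis=0)
    labels = np.array(["spike"] * n_spikes + ["artifact"] * n_artifacts)
    absw = np.abs(waves)
    peak_amp = absw.max(axis=2)  # (n_images, n_el)
    latencies = t[absw.argmax(axis=2)]
    supra = peak_amp > SUPRA_FRACTION * peak_amp.max(axis=1, keepdims=True)
    spreads = supra.mean(axis=1)
    lat = np.where(supra, latencies, np.nan)
    n_supra = supra.sum(axis=1)
    with np.errstate(invalid="ignore"):
        dispersions = np.where(n_supra >= 2, np.nanstd(lat, axis=1) * 1e3,
                               np.nan)
    # NaN dispersion (single supra-threshold electrode) compares False -> spike
    is_art = (spreads > SPREAD_THRESHOLD) & (dispersions < DISPERSION_THRESHOLD_MS)
    predicted = np.where(is_art, "artifact", "spike")
    return {"labels": labels, "predicted": predicted,
            "spread": spreads, "dispersion_ms": dispersions,
            "n_misclassified": int(np.sum(predicted != labels))}


# ----------------------------------------------------------------------------
# Event-triggered stimulus average
# ----------------------------------------------------------------------------

def triggered_stimulus_average(event_times, frames: np.ndarray,
                               frame_rate: float = 120.0,
                               n_lags: int = 30) -> np.ndarray:
    """Mean stimulus frame value at each lag before the events.

    ``frames`` has shape (n_frames, ...) — one value (or pixel array) per
    stimulus frame at ``frame_rate``.  Lag 0 is the frame containing the
    event; lag k the frame k steps earlier.  Events whose lag window precedes
    the frame log are dropped; with no usable events a ValueError is raised.
    """
    event_times = np.atleast_1d(np.asarray(event_times, dtype=float))
    frames = np.asarray(frames, dtype=float)
    if event_times.size == 0:
        raise ValueError("no events")
    idx = np.floor(event_times * frame_rate).astype(int)
    ok = (idx - (n_lags - 1) >= 0) & (idx < frames.shape[0])
    idx = idx[ok]
    if idx.size == 0:
        raise ValueError("no events covered by the frame log")
    lags = np.arange(n_lags)
    gather = frames[idx[:, None] - lags[None, :]]  # (n_events, n_lags, ...)
    return gather.mean(axis=0)
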