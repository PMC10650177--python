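"""Synthetic perifacial sEMG sessions via a volume-conduction model.

The generative model: each of eight muscle sources emits band-limited
(20-350 Hz shaped) Gaussian noise multiplied by a raised-cosine burst
envelope during its scheduled action windows, and is silent otherwise.
Sixteen perifacial electrodes record a linear instantaneous mixture of the
sources, with mixing coefficients decaying with electrode-source distance
(inverse-distance volume conduction). Mains interference, a DC offset and
broadband sensor noise are added on top.

A session follows a cued protocol: for each action and intensity, a cue
phase, an action phase and a rest phase in sequence; five actions x two
intensities x five repetitions form a block, three blocks separated by long
rests form a session. Weak actions (normal-intensity eye closure and
frowning) are given near-noise-floor amplitudes by default, reflecting how
poorly distal electrodes pick up small movements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import signal

from .codec import Recording, default_channel_labels

__all__ = [
    "ACTIONS",
    "INTENSITIES",
    "SOURCE_LABELS",
    "SourceActivation",
    "MixingModel",
    "ProtocolSpec",
    "NoiseSpec",
    "LabeledEpoch",
    "FaceGeometry",
    "default_geometry",
    "independent_burst_sources",
    "schedule_epochs",
    "generate_activation",
    "build_mixing_matrix",
    "mix_sources",
    "add_interference",
    "simulate_session",
]

ACTIONS = ("raise_eyebrows", "frown", "close_eyes", "purse_lips", "lift_mouth_corners")
INTENSITIES = ("normal", "forceful")

#: Muscle groups behind the eight simulated sources.
SOURCE_LABELS = (
    "frontalis_l",
    "frontalis_r",
    "corrugator",
    "orb_oculi_l",
    "orb_oculi_r",
    "orb_oris",
    "zygomaticus_l",
    "zygomaticus_r",
)

#: Which sources each action recruits (rows sum to roughly comparable drive).
ACTION_SOURCE_WEIGHTS: dict[str, dict[str, float]] = {
    "raise_eyebrows": {"frontalis_l": 1.0, "frontalis_r": 1.0, "corrugator": 0.2},
    "frown": {"corrugator": 1.0, "frontalis_l": 0.3, "frontalis_r": 0.3},
    "close_eyes": {"orb_oculi_l": 1.0, "orb_oculi_r": 1.0},
    "purse_lips": {"orb_oris": 1.0, "zygomaticus_l": 0.15, "zygomaticus_r": 0.15},
    "lift_mouth_corners": {"zygomaticus_l": 1.0, "zygomaticus_r": 1.0, "orb_oris": 0.3},
}

#: Per-action amplitude scale (arbitrary source units). Eye closure and
#: frowning are weak: at normal intensity they sit near the sensor noise
#: floor, which is why such epochs are often unlabelable in practice.
ACTION_AMPLITUDE: dict[str, float] = {
    "raise_eyebrows": 1.0,
    "frown": 0.25,
    "close_eyes": 0.2,
    "purse_lips": 1.0,
    "lift_mouth_corners": 0.8,
}

#: Envelope scale per intensity; forceful doubles the drive.
INTENSITY_SCALE: dict[str, float] = {"normal": 1.0, "forceful": 2.0}

#: Source bandwidth (Hz) of the shaped Gaussian noise.
SOURCE_BAND = (20.0, 350.0)


@dataclass(frozen=True)
class ProtocolSpec:
    """Cued-session timing: per (action, intensity) a cue, an action window
    and a rest, repeated ``reps_per_block`` times per block."""

    actions: tuple[str, ...] = ACTIONS
    intensities: tuple[str, ...] = INTENSITIES
    reps_per_block: int = 5
    blocks: int = 3
    action_duration_s: float = 2.0
    rest_duration_s: float = 3.0
    interblock_rest_s: float = 30.0
    cue_duration_s: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "action_duration_s",
            "rest_duration_s",
            "interblock_rest_s",
            "cue_duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.reps_per_block < 1 or self.blocks < 1:
            raise ValueError("reps_per_block and blocks must be >= 1")
        unknown = set(self.actions) - set(ACTIONS)
        if unknown:
            raise ValueError(f"unknown actions: {sorted(unknown)}")
        unknown = set(self.intensities) - set(INTENSITIES)
        if unknown:
            raise ValueError(f"unknown intensities: {sorted(unknown)}")

    @property
    def n_epochs(self) -> int:
        return (
            self.blocks
            * self.reps_per_block
            * len(self.actions)
            * len(self.intensities)
        )

    def block_duration_s(self) -> float:
        per_trial = self.cue_duration_s + self.action_duration_s + self.rest_duration_s
        return (
            self.reps_per_block
            * len(self.actions)
            * len(self.intensities)
            * per_trial
        )

    def session_duration_s(self) -> float:
        return self.blocks * self.block_duration_s() + (
            self.blocks - 1
        ) * self.interblock_rest_s


@dataclass(frozen=True)
class LabeledEpoch:
    """One scheduled action window inside a session recording."""

    epoch_id: int
    action: str
    intensity: str
    onset_sample: int
    duration_samples: int
    block: int
    rep: int

    @property
    def end_sample(self) -> int:
        return self.onset_sample + self.duration_samples

    def slice(self, array: np.ndarray) -> np.ndarray:
        """View of this epoch's samples in a channels x time array."""
        return array[..., self.onset_sample : self.end_sample]


@dataclass
class SourceActivation:
    """A single muscle source's time series over a whole session; zero
    outside the action windows scheduled for its (action, intensity).

    Composite session sources (a muscle recruited by several actions) carry
    ``action = intensity = None``.
    """

    source_id: str
    action: str | None
    intensity: str | None
    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("activation samples must be finite")


@dataclass(frozen=True)
class FaceGeometry:
    """2-D sketch of electrode and source positions (arbitrary face units)."""

    electrode_labels: tuple[str, ...]
    electrode_positions: np.ndarray  # n_electrodes x 2
    source_labels: tuple[str, ...]
    source_positions: np.ndarray  # n_sources x 2


@dataclass
class MixingModel:
    """Linear volume-conduction map from sources to electrodes."""

    electrode_labels: list[str]
    source_labels: list[str]
    matrix: np.ndarray  # n_electrodes x n_sources
    geometry: FaceGeometry | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.electrode_labels), len(self.source_labels)):
            raise ValueError("matrix shape must be n_electrodes x n_sources")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("mixing coefficients must be finite")

    @property
    def n_electrodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive contamination: mains sinusoid, per-channel DC, white noise."""

    powerline_freq: float = 50.0
    powerline_amplitude: float = 0.2
    dc_offset: float | np.ndarray = 0.5
    white_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.powerline_freq <= 0:
            raise ValueError("powerline_freq must be positive")
        if self.powerline_amplitude < 0 or self.white_noise_sd < 0:
            raise ValueError("noise amplitudes must be non-negative")


# ---------------------------------------------------------------------------
# Scheduling


def schedule_epochs(protocol: ProtocolSpec, rate: float) -> tuple[list[LabeledEpoch], int]:
    """Lay out the session timeline; returns the epochs and total samples.

    Within a block, repetitions iterate over actions, and for each action the
    intensities run in protocol order, each trial as cue - action - rest.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    cue = int(round(protocol.cue_duration_s * rate))
    act = int(round(protocol.action_duration_s * rate))
    rest = int(round(protocol.rest_duration_s * rate))
    interblock = int(round(protocol.interblock_rest_s * rate))

    epochs: list[LabeledEpoch] = []
    cursor = 0
    epoch_id = 0
    for block in range(protocol.blocks):
        for rep in range(protocol.reps_per_block):
            for action in protocol.actions:
                for intensity in protocol.intensities:
                    onset = cursor + cue
                    epochs.append(
                        LabeledEpoch(
                            epoch_id=epoch_id,
                            action=action,
                            intensity=intensity,
                            onset_sample=onset,
                            duration_samples=act,
                            block=block,
                            rep=rep,
                        )
                    )
                    epoch_id += 1
                    cursor = onset + act + rest
        if block < protocol.blocks - 1:
            cursor += interblock
    return epochs, cursor


# ---------------------------------------------------------------------------
# Source generation


def _burst(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise under a raised-cosine envelope."""
    noise = rng.standard_normal(n)
    low, high = SOURCE_BAND
    high = min(high, 0.49 * rate)
    if rate > 2 * low:
        sos = signal.butter(4, [low, high], btype="bandpass", fs=rate, output="sos")
        noise = signal.sosfilt(sos, noise)
    rms = np.sqrt(np.mean(noise**2))
    if rms > 0:
        noise /= rms
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))
    return envelope * noise


def generate_activation(
    action: str,
    intensity: str,
    protocol: ProtocolSpec,
    rate: float,
    seed: int,
    *,
    amplitude: float = 1.0,
    intensity_scale: Mapping[str, float] | None = None,
    source_id: str | None = None,
) -> SourceActivation:
    """Session-long activation of one source recruited by (action, intensity).

    Bursts occupy exactly the scheduled windows of that action and intensity;
    the envelope peak is ``amplitude * intensity_scale[intensity]`` (forceful
    doubles the normal drive by default). Deterministic given the seed.
    """
    if action not in ACTIONS:
        raise ValueError(f"unknown action {action!r}")
    if intensity not in INTENSITIES:
        raise ValueError(f"unknown intensity {intensity!r}")
    scales = dict(INTENSITY_SCALE if intensity_scale is None else intensity_scale)
    epochs, total = schedule_epochs(protocol, rate)
    samples = np.zeros(total)
    rng = np.random.default_rng(seed)
    scale = amplitude * scales[intensity]
    for ep in epochs:
        burst = _burst(rng, ep.duration_samples, rate)
        if ep.action == action and ep.intensity == intensity:
            samples[ep.onset_sample : ep.end_sample] = scale * burst
    return SourceActivation(
        source_id=source_id or f"{action}_{intensity}",
        action=action,
        intensity=intensity,
        samples=samples,
        rate=rate,
    )


# ---------------------------------------------------------------------------
# Geometry and mixing


def independent_burst_sources(
    n_sources: int,
    duration_s: float,
    rate: float,
    seed: int,
    bursts_per_source: int = 6,
    burst_duration_s: float = 1.0,
) -> np.ndarray:
    """Equal-strength independent burst sources for separation benchmarks.

    Each source emits ``bursts_per_source`` raised-cosine bursts of
    band-limited Gaussian noise at staggered, non-overlapping-by-source
    onsets, so sources are mutually independent and strongly non-Gaussian
    (sparse) — the regime where ICA recovery is well defined. Returns an
    ``n_sources x n_samples`` array.
    """
    n = int(round(duration_s * rate))
    burst_len = int(round(burst_duration_s * rate))
    if bursts_per_source * burst_len * n_sources > n:
        raise ValueError("duration too short for the requested burst schedule")
    rng = np.random.default_rng(seed)
    sources = np.zeros((n_sources, n))
    slot = n // (bursts_per_source * n_sources)
    k = 0
    for b in range(bursts_per_source):
        for j in range(n_sources):
            onset = k * slot + rng.integers(0, max(1, slot - burst_len))
            sources[j, onset : onset + burst_len] += _burst(rng, burst_len, rate)
            k += 1
    return sources


def default_geometry() -> FaceGeometry:
    """Sixteen electrodes on an ellipse around the face, eight muscle sources
    inside it. Units are arbitrary 'face units' (the ellipse is 2 x 2.6)."""
    # Symmetric montage: L1..L8 down the left periphery, R1..R8 mirrored.
    t = np.linspace(-1.1, 1.1, 8)
    left = np.column_stack([-np.sqrt(np.clip(1.3**2 - (t / 1.0) ** 2, 0.04, None)), t])
    right = np.column_stack([-left[:, 0], left[:, 1]])
    electrode_positions = np.vstack([left, right])
    source_positions = np.array(
        [
            [-0.35, 0.95],  # frontalis_l
            [0.35, 0.95],  # frontalis_r
            [0.0, 0.75],  # corrugator
            [-0.45, 0.45],  # orb_oculi_l
            [0.45, 0.45],  # orb_oculi_r
            [0.0, -0.75],  # orb_oris
            [-0.55, -0.45],  # zygomaticus_l
            [0.55, -0.45],  # zygomaticus_r
        ]
    )
    return FaceGeometry(
        electrode_labels=tuple(default_channel_labels(16)),
        electrode_positions=electrode_positions,
        source_labels=SOURCE_LABELS,
        source_positions=source_positions,
    )


def build_mixing_matrix(
    geometry: FaceGeometry,
    attenuation_law: str | Callable[[np.ndarray], np.ndarray] = "inverse_distance",
    exponent: float = 1.0,
) -> MixingModel:
    """Volume-conduction mixing matrix from a 2-D geometry.

    ``attenuation_law`` may be ``"inverse_distance"`` (coefficient = 1/d**p
    with p = ``exponent``) or any callable mapping distances to non-negative
    coefficients that decay with distance.
    """
    diff = geometry.electrode_positions[:, None, :] - geometry.source_positions[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    if np.any(dist <= 0):
        raise ValueError("electrode coincides with a source; distances must be > 0")
    if callable(attenuation_law):
        matrix = np.asarray(attenuation_law(dist), dtype=float)
    elif attenuation_law == "inverse_distance":
        matrix = 1.0 / dist**exponent
    else:
        raise ValueError(f"unknown attenuation law {attenuation_law!r}")
    if np.any(matrix < 0):
        raise ValueError("attenuation law produced negative coefficients")
    return MixingModel(
        electrode_labels=list(geometry.electrode_labels),
        source_labels=list(geometry.source_labels),
        matrix=matrix,
        geometry=geometry,
    )


def mix_sources(sources: Sequence[SourceActivation], model: MixingModel) -> Recording:
    """Instantaneous linear mixture: channel i = sum_j A[i, j] * s_j(t)."""
    if len(sources) != model.n_sources:
        raise ValueError(
            f"got {len(sources)} sources for a {model.n_sources}-source model"
        )
    for src, label in zip(sources, model.source_labels):
        if src.source_id != label:
            raise ValueError(
                f"source order mismatch: got {src.source_id!r}, expected {label!r}"
            )
    rates = {src.rate for src in sources}
    lengths = {len(src.samples) for src in sources}
    if len(rates) != 1 or len(lengths) != 1:
        raise ValueError("all sources must share rate and length")
    S = np.vstack([src.samples for src in sources])
    return Recording(
        samples=model.matrix @ S,
        rate=rates.pop(),
        channel_labels=list(model.electrode_labels),
    )


def add_interference(recording: Recording, noise: NoiseSpec) -> Recording:
    """Add mains sinusoid (common phase), per-channel DC and white noise."""
    if noise.powerline_freq >= recording.rate / 2:
        raise ValueError("powerline frequency must be below Nyquist")
    rng = np.random.default_rng(noise.seed)
    t = np.arange(recording.n_samples) / recording.rate
    phase = rng.uniform(0, 2 * np.pi)
    powerline = noise.powerline_amplitude * np.sin(
        2 * np.pi * noise.powerline_freq * t + phase
    )
    dc = np.broadcast_to(
        np.atleast_1d(np.asarray(noise.dc_offset, dtype=float)),
        (recording.n_channels,),
    )[:, None]
    white = (
        noise.white_noise_sd
        * rng.standard_normal((recording.n_channels, recording.n_samples))
        if noise.white_noise_sd > 0
        else 0.0
    )
    return recording.with_samples(recording.samples + powerline[None, :] + dc + white)


# ---------------------------------------------------------------------------
# Full sessions


def _session_sources(
    protocol: ProtocolSpec,
    rate: float,
    seed: int,
    amplitude_jitter_sd: float,
) -> list[SourceActivation]:
    """Eight muscle sources over the session, each the superposition of the
    bursts of every (action, intensity) trial that recruits it."""
    epochs, total = schedule_epochs(protocol, rate)
    ss = np.random.SeedSequence([int(seed), 0x5EED])
    # One child stream per epoch; co-activated sources share the burst
    # envelope timing but draw independent carrier noise (motor-unit
    # activity of distinct muscles is independent even when co-recruited).
    epoch_rngs = [np.random.default_rng(c) for c in ss.spawn(len(epochs))]
    sources = [np.zeros(total) for _ in SOURCE_LABELS]
    for ep, rng in zip(epochs, epoch_rngs):
        jitter = (
            np.exp(rng.normal(0.0, amplitude_jitter_sd))
            if amplitude_jitter_sd > 0
            else 1.0
        )
        scale = ACTION_AMPLITUDE[ep.action] * INTENSITY_SCALE[ep.intensity] * jitter
        weights = ACTION_SOURCE_WEIGHTS[ep.action]
        for j, label in enumerate(SOURCE_LABELS):
            w = weights.get(label, 0.0)
            if w == 0.0:
                continue
            burst = _burst(rng, ep.duration_samples, rate)
            sources[j][ep.onset_sample : ep.end_sample] += w * scale * burst
    return [
        SourceActivation(
            source_id=label, action=None, intensity=None, samples=s, rate=rate
        )
        for label, s in zip(SOURCE_LABELS, sources)
    ]


def simulate_session(
    protocol: ProtocolSpec | None = None,
    model: MixingModel | None = None,
    noise: NoiseSpec | None = None,
    rate: float = 1000.0,
    seed: int = 0,
    amplitude_jitter_sd: float = 0.2,
    return_sources: bool = False,
):
    """Simulate one labeled acquisition session.

    Returns ``(recording, epochs)`` — or ``(recording, epochs, sources)`` with
    ``return_sources=True`` — where the recording is the noisy electrode
    mixture and each epoch carries its (action, intensity) label and sample
    span. ``amplitude_jitter_sd`` is the s.d. of a log-normal trial-to-trial
    drive fluctuation. Bit-reproducible for a given seed.
    """
    protocol = protocol or ProtocolSpec()
    model = model or build_mixing_matrix(default_geometry())
    noise = NoiseSpec(seed=int(seed) + 1) if noise is None else noise
    epochs, _ = schedule_epochs(protocol, rate)
    sources = _session_sources(protocol, rate, seed, amplitude_jitter_sd)
    clean = mix_sources(sources, model)
    noisy = add_interference(clean, noise)
    if return_sources:
        return noisy, epochs, sources
    return noisy, epochs


def write_labels(epochs: Sequence[LabeledEpoch], path) -> None:
    """Write epoch labels as TSV: epoch_id, action, intensity, onset, duration."""
    import pandas as pd

    pd.DataFrame(
        {
            "epoch_id": [e.epoch_id for e in epochs],
            "action": [e.action for e in epochs],
            "intensity": [e.intensity for e in epochs],
            "onset_sample": [e.onset_sample for e in epochs],
            "duration_samples": [e.duration_samples for e in epochs],
            "block": [e.block for e in epochs],
            "rep": [e.rep for e in epochs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_labels(path) -> list[LabeledEpoch]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        LabeledEpoch(
            epoch_id=int(r.epoch_id),
            action=str(r.action),
            intensity=str(r.intensity),
            onset_sample=int(r.onset_sample),
            duration_samples=int(r.duration_samples),
            block=int(getattr(r, "block", 0)),
            rep=int(getattr(r, "rep", 0)),
        )
        for r in df.itertuples(index=False)
    ]
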