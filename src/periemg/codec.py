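"""Device-side data model for a 16-channel wireless sEMG acquisition system.

Covers the arithmetic and formats a host needs to talk to the device:

* throughput of the acquisition link (:func:`data_rate`),
* conversion between 24-bit delta-sigma ADC codes and electrode voltages
  (:func:`code_to_volts` / :func:`volts_to_code`),
* the binary frame stream the firmware emits over TCP
  (:func:`encode_frame` / :func:`decode_frame` / :func:`decode_stream`),
* the plain-text recording dialect the host software saves
  (:func:`read_recording` / :func:`write_recording`).

The frame byte layout is a documented dialect of this package (the device
protocol only fixes "header, packet number, check digit"): a 2-byte header
``0xA5 0x5A``, a 4-byte little-endian packet counter, one little-endian
signed 32-bit word per channel (the 24-bit conversion sign-extended), and a
single XOR checksum byte over everything that precedes it.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "AdcConfig",
    "Frame",
    "Recording",
    "FrameError",
    "data_rate",
    "code_to_volts",
    "volts_to_code",
    "encode_frame",
    "decode_frame",
    "decode_stream",
    "find_dropped_packets",
    "frames_to_recording",
    "read_recording",
    "write_recording",
    "default_channel_labels",
]

FRAME_HEADER = b"\xa5\x5a"
_CODE_MIN = -(2**23)
_CODE_MAX = 2**23 - 1


class FrameError(ValueError):
    """Raised when a binary frame fails structural or checksum validation."""


def default_channel_labels(n_channels: int = 16) -> list[str]:
    """Electrode labels L1..L8, R1..R8 for the perifacial montage."""
    if n_channels == 16:
        return [f"L{i}" for i in range(1, 9)] + [f"R{i}" for i in range(1, 9)]
    return [f"ch{i}" for i in range(1, n_channels + 1)]


@dataclass(frozen=True)
class AdcConfig:
    """Front-end configuration of the 24-bit delta-sigma converter.

    ``vref`` defaults to 4.5 V, the internal reference typical of this ADC
    family; the least significant bit maps to ``vref / (gain * (2**23 - 1))``
    volts at the electrode.
    """

    resolution_bits: int = 24
    gain: float = 24.0
    vref: float = 4.5
    sps: int = 1000

    def __post_init__(self) -> None:
        if self.resolution_bits != 24:
            raise ValueError("only 24-bit converters are modelled")
        if not (250 <= self.sps <= 16000):
            raise ValueError(f"sps {self.sps} outside the valid range [250, 16000]")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.vref <= 0:
            raise ValueError("vref must be positive")

    @property
    def lsb_volts(self) -> float:
        return self.vref / (self.gain * _CODE_MAX)

    @property
    def full_scale_volts(self) -> float:
        """Input voltage mapped to the maximum positive code."""
        return self.vref / self.gain


@dataclass(frozen=True)
class Frame:
    """One decoded sample instant: header tag, packet counter, channel codes."""

    packet_number: int
    codes: tuple[int, ...]
    checksum: int

    @property
    def n_channels(self) -> int:
        return len(self.codes)


@dataclass
class Recording:
    """Multichannel voltage time series.

    ``samples`` is ``n_channels x n_samples`` (row per electrode), in volts.
    """

    samples: np.ndarray
    rate: float
    channel_labels: list[str] = field(default_factory=list)
    adc: AdcConfig | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.samples.shape[0] == 0:
            raise ValueError("recording must have at least one channel")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.channel_labels:
            self.channel_labels = default_channel_labels(self.samples.shape[0])
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """New recording sharing this one's metadata (rate, labels, ADC)."""
        return Recording(
            samples=samples,
            rate=self.rate,
            channel_labels=list(self.channel_labels),
            adc=self.adc,
        )


# ---------------------------------------------------------------------------
# Throughput and code/voltage conversion


def data_rate(n_channels: int, sampling_freq: float, bits_per_sample: int) -> int:
    """Raw acquisition throughput in bits/s: channels x rate x bits.

    With 16 channels at 1 kHz and 32 bits per sample (the 24-bit conversion
    widened to a 32-bit word for transport) the device produces 512 kbit/s.
    """
    if n_channels <= 0 or sampling_freq <= 0 or bits_per_sample <= 0:
        raise ValueError("all throughput arguments must be positive")
    return int(round(n_channels * sampling_freq * bits_per_sample))


def code_to_volts(code, adc: AdcConfig = AdcConfig()):
    """Map signed 24-bit conversion codes to input-referred volts.

    Scale law: ``volts = code * vref / (gain * (2**23 - 1))`` so the maximum
    positive code corresponds to ``vref / gain`` at the electrode.
    Accepts scalars or arrays.
    """
    arr = np.asarray(code)
    if np.any(arr < _CODE_MIN) or np.any(arr > _CODE_MAX):
        raise ValueError("code outside the signed 24-bit range")
    volts = arr * (adc.vref / (adc.gain * _CODE_MAX))
    return float(volts) if np.isscalar(code) else volts


def volts_to_code(volts, adc: AdcConfig = AdcConfig()):
    """Inverse of :func:`code_to_volts`, rounded to the nearest code and clipped
    to the 24-bit range."""
    arr = np.asarray(volts, dtype=float)
    codes = np.rint(arr * (adc.gain * _CODE_MAX) / adc.vref).astype(np.int64)
    codes = np.clip(codes, _CODE_MIN, _CODE_MAX)
    return int(codes) if np.isscalar(volts) else codes


# ---------------------------------------------------------------------------
# Frame packetization


def _xor_checksum(payload: bytes) -> int:
    acc = 0
    for b in payload:
        acc ^= b
    return acc


def frame_size(n_channels: int) -> int:
    return 2 + 4 + 4 * n_channels + 1


def encode_frame(sample_codes: Sequence[int], packet_number: int) -> bytes:
    """Pack one sample instant into the binary frame dialect."""
    codes = [int(c) for c in sample_codes]
    if not codes:
        raise ValueError("frame needs at least one channel code")
    for c in codes:
        if not (-(2**31) <= c < 2**31):
            raise ValueError(f"code {c} does not fit a signed 32-bit word")
    if not (0 <= packet_number < 2**32):
        raise ValueError("packet number must fit an unsigned 32-bit counter")
    body = FRAME_HEADER + struct.pack("<I", packet_number)
    body += struct.pack(f"<{len(codes)}i", *codes)
    return body + bytes([_xor_checksum(body)])


def decode_frame(buf: bytes, n_channels: int = 16) -> Frame:
    """Decode one frame; raises :class:`FrameError` on a bad header, short
    buffer or checksum mismatch."""
    size = frame_size(n_channels)
    if len(buf) < size:
        raise FrameError(f"truncated frame: {len(buf)} < {size} bytes")
    if buf[:2] != FRAME_HEADER:
        raise FrameError("bad frame header tag")
    frame = buf[:size]
    if _xor_checksum(frame[:-1]) != frame[-1]:
        raise FrameError("checksum mismatch")
    packet_number = struct.unpack_from("<I", frame, 2)[0]
    codes = struct.unpack_from(f"<{n_channels}i", frame, 6)
    return Frame(packet_number=packet_number, codes=codes, checksum=frame[-1])


def decode_stream(buf: bytes, n_channels: int = 16) -> tuple[list[Frame], int]:
    """Decode a byte stream of frames, resynchronizing on the header tag.

    Corrupted bytes are skipped until the next valid frame; returns the decoded
    frames and the number of bytes discarded during resynchronization.
    """
    frames: list[Frame] = []
    size = frame_size(n_channels)
    pos = 0
    skipped = 0
    while pos + size <= len(buf):
        try:
            frames.append(decode_frame(buf[pos : pos + size], n_channels))
            pos += size
        except FrameError:
            pos += 1
            skipped += 1
    skipped += len(buf) - pos
    return frames, skipped


def find_dropped_packets(frames: Sequence[Frame]) -> list[int]:
    """Packet numbers missing from a consecutive counter sequence."""
    missing: list[int] = []
    for prev, cur in zip(frames, frames[1:]):
        gap = (cur.packet_number - prev.packet_number) % 2**32
        missing.extend((prev.packet_number + k) % 2**32 for k in range(1, gap))
    return missing


def frames_to_recording(
    frames: Sequence[Frame],
    adc: AdcConfig = AdcConfig(),
    channel_labels: list[str] | None = None,
) -> Recording:
    """Assemble decoded frames into a voltage :class:`Recording`."""
    if not frames:
        raise ValueError("no frames to assemble")
    codes = np.array([f.codes for f in frames], dtype=np.int64).T
    return Recording(
        samples=code_to_volts(codes, adc),
        rate=float(adc.sps),
        channel_labels=channel_labels or default_channel_labels(codes.shape[0]),
        adc=adc,
    )


# ---------------------------------------------------------------------------
# Plain-text recording dialect


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write the text dialect: '#' metadata header then one row per sample
    instant, one whitespace-separated column per channel, in volts."""
    path = Path(path)
    header = [
        f"rate_hz: {recording.rate!r}",
        f"channels: {' '.join(recording.channel_labels)}",
    ]
    if recording.adc is not None:
        header.append(
            "adc: gain={0} vref={1} sps={2}".format(
                recording.adc.gain, recording.adc.vref, recording.adc.sps
            )
        )
    np.savetxt(
        path,
        recording.samples.T,
        fmt="%.9e",
        header="\n".join(header),
        comments="# ",
    )


def read_recording(path: str | Path) -> Recording:
    """Read the text dialect written by :func:`write_recording`."""
    path = Path(path)
    rate: float | None = None
    labels: list[str] | None = None
    adc: AdcConfig | None = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            meta = line.lstrip("# ").strip()
            if meta.startswith("rate_hz:"):
                rate = float(meta.split(":", 1)[1])
            elif meta.startswith("channels:"):
                labels = meta.split(":", 1)[1].split()
            elif meta.startswith("adc:"):
                kv = dict(item.split("=") for item in meta.split(":", 1)[1].split())
                adc = AdcConfig(
                    gain=float(kv["gain"]), vref=float(kv["vref"]), sps=int(kv["sps"])
                )
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.size == 0:
        raise ValueError(f"{path} contains no samples")
    if rate is None:
        raise ValueError(f"{path} is missing the '# rate_hz:' metadata line")
    return Recording(samples=data.T, rate=rate, channel_labels=labels or [], adc=adc)
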