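"""Per-component EMG features and epoch-level feature matrices.

Eight features per component: five time-domain —

* IEMG  = sum |x_i|
* VAR   = (1/N) sum (x_i - mean)^2      (population form, 1/N)
* MAV   = (1/N) sum |x_i|
* SSI   = sum x_i^2
* RMS   = sqrt((1/N) sum x_i^2)

and three frequency-domain, computed from an amplitude spectrum S(n) on
frequencies f_n:

* FC    = sum f_n S(n) / sum S(n)       (spectral centroid)
* MF    = sum S(n) / N_bins             (mean spectrum amplitude; note this
          is the printed "frequency mean value", *not* median frequency)
* FRMS  = sqrt(sum f_n^2 S(n) / sum S(n))

The identities IEMG = N * MAV and SSI = N * RMS^2 hold exactly, and
FRMS >= FC always (Cauchy-Schwarz). With eight ICA components this yields
the standard 64-dimensional epoch vector.

An all-zero spectrum leaves FC/FRMS undefined; :func:`frequency_domain_features`
raises :class:`ZeroSpectrumError`, while :func:`extract_feature_matrix`
substitutes 0.0 for both (documented sentinel) so matrices never carry NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "FEATURE_NAMES",
    "ZeroSpectrumError",
    "TimeDomainFeatures",
    "FrequencyDomainFeatures",
    "SpectrumEstimate",
    "time_domain_features",
    "power_spectrum",
    "frequency_domain_features",
    "component_features",
    "extract_feature_matrix",
    "slice_epochs",
]

FEATURE_NAMES = ("iemg", "var", "mav", "ssi", "rms", "fc", "mf", "frms")


class ZeroSpectrumError(ValueError):
    """Spectral moments are undefined for an all-zero spectrum."""


class TimeDomainFeatures(NamedTuple):
    iemg: float
    var: float
    mav: float
    ssi: float
    rms: float


class FrequencyDomainFeatures(NamedTuple):
    fc: float
    mf: float
    frms: float


@dataclass(frozen=True)
class SpectrumEstimate:
    """Non-negative amplitude spectrum on ascending frequencies."""

    freqs: np.ndarray
    amplitudes: np.ndarray
    method: str = "fft"

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        s = np.asarray(self.amplitudes, dtype=float)
        if f.shape != s.shape:
            raise ValueError("freqs and amplitudes must have the same length")
        if np.any(s < 0) or not np.all(np.isfinite(s)):
            raise ValueError("amplitudes must be finite and non-negative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "amplitudes", s)


def time_domain_features(samples) -> TimeDomainFeatures:
    """Evaluate the five amplitude-derived features exactly as defined."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot compute features of an empty signal")
    n = x.size
    abs_x = np.abs(x)
    iemg = float(abs_x.sum())
    mav = iemg / n
    ssi = float(np.sum(x**2))
    rms = float(np.sqrt(ssi / n))
    var = float(np.mean((x - x.mean()) ** 2))
    return TimeDomainFeatures(iemg=iemg, var=var, mav=mav, ssi=ssi, rms=rms)


def power_spectrum(samples, rate: float, method: str = "fft") -> SpectrumEstimate:
    """Amplitude spectrum of a detrended epoch on [0, rate/2].

    ``method='fft'`` (default): magnitude of a single discrete transform of
    the mean-removed signal, normalized by N. ``method='welch'``: square root
    of the Welch power density (averaged periodograms).
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples for a spectrum")
    if rate <= 0:
        raise ValueError("rate must be positive")
    x = x - x.mean()
    if method == "fft":
        amps = np.abs(np.fft.rfft(x)) / x.size
        freqs = np.fft.rfftfreq(x.size, d=1.0 / rate)
    elif method == "welch":
        freqs, psd = sps.welch(x, fs=rate, nperseg=min(256, x.size))
        amps = np.sqrt(psd)
    else:
        raise ValueError(f"unknown spectrum method {method!r}")
    return SpectrumEstimate(freqs=freqs, amplitudes=amps, method=method)


def frequency_domain_features(spectrum: SpectrumEstimate) -> FrequencyDomainFeatures:
    """Spectral centroid, mean amplitude, and RMS frequency of a spectrum."""
    s = spectrum.amplitudes
    f = spectrum.freqs
    total = s.sum()
    mf = float(s.mean()) if s.size else 0.0
    if total <= 0:
        raise ZeroSpectrumError("FC and FRMS are undefined for a zero spectrum")
    fc = float((f * s).sum() / total)
    frms = float(np.sqrt((f**2 * s).sum() / total))
    return FrequencyDomainFeatures(fc=fc, mf=mf, frms=frms)


def component_features(samples, rate: float, method: str = "fft") -> dict[str, float]:
    """All eight features of one component epoch, zero-spectrum policy applied."""
    td = time_domain_features(samples)
    spectrum = power_spectrum(samples, rate, method)
    try:
        fd = frequency_domain_features(spectrum)
        fc, mf, frms = fd.fc, fd.mf, fd.frms
    except ZeroSpectrumError:
        fc, mf, frms = 0.0, 0.0, 0.0
    return {
        "iemg": td.iemg,
        "var": td.var,
        "mav": td.mav,
        "ssi": td.ssi,
        "rms": td.rms,
        "fc": fc,
        "mf": mf,
        "frms": frms,
    }


def slice_epochs(components: np.ndarray, epochs: Sequence) -> list[np.ndarray]:
    """Cut a components x time matrix into per-epoch component blocks."""
    out = []
    for ep in epochs:
        if ep.end_sample > components.shape[-1]:
            raise ValueError(f"epoch {ep.epoch_id} extends past the component matrix")
        out.append(components[:, ep.onset_sample : ep.end_sample])
    return out


def extract_feature_matrix(
    epoch_components: Sequence[np.ndarray],
    rate: float,
    labels: Sequence | None = None,
    method: str = "fft",
) -> pd.DataFrame:
    """Epoch-by-feature matrix: 8 features per component, fixed column order.

    ``epoch_components`` is one channels-free ``n_components x n_samples``
    block per labeled epoch; every epoch must have the same component count.
    Columns are ``c{k}_{feature}`` for component k in 1..n_components and
    feature in IEMG, VAR, MAV, SSI, RMS, FC, MF, FRMS; with the default 8
    components this is the 64-dimensional epoch vector. Optional ``labels``
    (objects with .action/.intensity or (action, intensity) pairs) append
    ``action`` and ``intensity`` columns.
    """
    if not epoch_components:
        raise ValueError("no epochs given")
    n_components = {np.asarray(block).shape[0] for block in epoch_components}
    if len(n_components) != 1:
        raise ValueError("all epochs must have the same component count")
    n_comp = n_components.pop()
    rows = []
    for block in epoch_components:
        block = np.asarray(block, dtype=float)
        row: dict[str, float] = {}
        for k in range(n_comp):
            feats = component_features(block[k], rate, method)
            for name in FEATURE_NAMES:
                row[f"c{k + 1}_{name}"] = feats[name]
        rows.append(row)
    df = pd.DataFrame(rows)
    if labels is not None:
        if len(labels) != len(df):
            raise ValueError("labels length must match the epoch count")
        actions, intensities = [], []
        for lab in labels:
            if hasattr(lab, "action"):
                actions.append(lab.action)
                intensities.append(lab.intensity)
            else:
                a, i = lab
                actions.append(a)
                intensities.append(i)
        df["action"] = actions
        df["intensity"] = intensities
    return df
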