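"""Device-agreement statistics for paired sEMG signals.

Four indices quantify how similarly two acquisition systems record the same
movement: Spearman rank correlation (monotone association), an energy ratio
(min/max of the two signal energies, symmetric and in [0, 1]), the linear
(Pearson) correlation coefficient, and a lag-0 normalized cross-correlation
coefficient. The latter two are algebraically identical on the same pair of
signals; both are reported because device-comparison studies conventionally
list them side by side. An optional max-over-lags mode of the
cross-correlation reports the best lag as well, for pairs with residual
alignment error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "spearman",
    "energy",
    "energy_ratio",
    "lcc",
    "ccc",
    "compare_recordings",
]


@dataclass
class AgreementReport:
    """Per-movement table of the four agreement indices."""

    table: pd.DataFrame  # columns: movement, spearman, energy_ratio, lcc, ccc

    def __post_init__(self) -> None:
        expected = ["movement", "spearman", "energy_ratio", "lcc", "ccc"]
        if list(self.table.columns) != expected:
            raise ValueError(f"report columns must be {expected}")


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("signals must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return x, y


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties; in [-1, 1]."""
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation is undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def energy(x, dt: float) -> float:
    """Discrete signal energy: sum x^2 * dt (Riemann sum of the integral)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.asarray(x, dtype=float).ravel()
    return float(np.sum(x**2) * dt)


def energy_ratio(x, y, dt: float = 1.0) -> float:
    """Symmetric energy similarity: min(E_x, E_y) / max(E_x, E_y) in [0, 1]."""
    x, y = _check_pair(x, y)
    ex, ey = energy(x, dt), energy(y, dt)
    if ex == 0 and ey == 0:
        raise ValueError("energy ratio undefined when both signals are zero")
    return float(min(ex, ey) / max(ex, ey))


def lcc(x, y) -> float:
    """Linear (Pearson) correlation via the centered sum formula."""
    x, y = _check_pair(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0:
        raise ValueError("LCC undefined for constant input")
    return float(np.sum(xc * yc) / denom)


def ccc(x, y, max_lag: int | None = None):
    """Normalized cross-correlation coefficient.

    At lag 0 (default) this is the raw-sum Pearson formula
    ``(n sum xy - sum x sum y) / sqrt((n sum x^2 - (sum x)^2)(n sum y^2 - (sum y)^2))``
    and equals :func:`lcc` exactly. With ``max_lag`` set, the Pearson
    coefficient of the overlapping segments is computed for every lag in
    ``[-max_lag, max_lag]`` and ``(best_coefficient, best_lag)`` is returned,
    where positive lag means y is delayed relative to x.
    """
    x, y = _check_pair(x, y)
    if max_lag is None:
        return _ccc_lag0(x, y)
    best_val, best_lag = -np.inf, 0
    for lag in range(-int(max_lag), int(max_lag) + 1):
        if lag >= 0:
            xs, ys = x[: x.size - lag or None], y[lag:]
        else:
            xs, ys = x[-lag:], y[: y.size + lag]
        if xs.size < 2 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
            continue
        val = _ccc_lag0(xs, ys)
        if val > best_val:
            best_val, best_lag = val, lag
    if not np.isfinite(best_val):
        raise ValueError("CCC undefined: no lag with nonconstant overlap")
    return float(best_val), int(best_lag)


def _ccc_lag0(x: np.ndarray, y: np.ndarray) -> float:
    n = x.size
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = np.sqrt(
        (n * np.sum(x**2) - np.sum(x) ** 2) * (n * np.sum(y**2) - np.sum(y) ** 2)
    )
    if den == 0:
        raise ValueError("CCC undefined for constant input")
    return float(num / den)


def compare_recordings(
    pairs: Mapping[str, tuple[Sequence, Sequence]], dt: float = 1.0
) -> AgreementReport:
    """Agreement table over movements: one row of all four indices per pair.

    ``pairs`` maps a movement label to an aligned ``(x, y)`` signal pair that
    went through identical preprocessing on both devices.
    """
    rows = []
    for movement, (x, y) in pairs.items():
        rows.append(
            {
                "movement": movement,
                "spearman": spearman(x, y),
                "energy_ratio": energy_ratio(x, y, dt),
                "lcc": lcc(x, y),
                "ccc": ccc(x, y),
            }
        )
    return AgreementReport(
        table=pd.DataFrame(rows, columns=["movement", "spearman", "energy_ratio", "lcc", "ccc"])
    )
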