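"""Blind source separation of multichannel sEMG via whitening + fixed-point ICA.

The electrode signals are modelled as an instantaneous linear mixture
``x(t) = A s(t)`` of statistically independent muscle sources; the unmixing
map ``s(t) = W x(t)`` is estimated in two steps:

1. PCA whitening reduces the 16 channels to ``n_components`` (default 8)
   uncorrelated unit-variance directions, recording the transform so it can
   be re-applied to new data and inverted.
2. A fixed-point iteration with the log-cosh contrast and symmetric
   decorrelation estimates the square rotation that maximizes
   non-Gaussianity of the components.

ICA is identifiable only up to sign, scale and permutation of the sources
(and not at all for Gaussian sources). Results are canonicalized: each
component has unit variance, its sign is fixed so the largest-magnitude
sample is positive, and components are ordered by explained input variance.
Recovery quality against a known ground truth can be scored with
:func:`amari_index` or :func:`match_components`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codec import Recording

__all__ = [
    "WhiteningTransform",
    "UnmixingResult",
    "whiten",
    "fit_ica",
    "separate",
    "amari_index",
    "match_components",
]


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, Recording):
        return data.samples
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a channels x time matrix")
    return arr


@dataclass(frozen=True)
class WhiteningTransform:
    """Affine map ``z = K (x - mean)`` giving unit-covariance components."""

    mean: np.ndarray  # n_channels
    matrix: np.ndarray  # n_components x n_channels

    def apply(self, x: np.ndarray) -> np.ndarray:
        return self.matrix @ (x - self.mean[:, None])


@dataclass
class UnmixingResult:
    """Estimated unmixing map and the separated components.

    ``W`` maps centered channel data straight to components
    (``rotation @ whitening.matrix``); ``mixing_estimate`` is its
    pseudo-inverse, i.e. the estimated volume-conduction columns.
    """

    W: np.ndarray  # n_components x n_channels
    rotation: np.ndarray  # n_components x n_components
    whitening: WhiteningTransform
    components: np.ndarray  # n_components x time
    n_components: int
    n_iter: int
    converged: bool
    tol: float

    @property
    def mixing_estimate(self) -> np.ndarray:
        return np.linalg.pinv(self.W)


def whiten(data, n_components: int | None = None) -> tuple[np.ndarray, WhiteningTransform]:
    """PCA-whiten channels x time data down to ``n_components`` directions.

    Raises if the data do not carry variance in at least ``n_components``
    directions (relative singular-value cutoff 1e-10).
    """
    x = _as_matrix(data)
    n_channels, n_samples = x.shape
    n_components = n_channels if n_components is None else int(n_components)
    if n_components > n_channels:
        raise ValueError("n_components cannot exceed the channel count")
    mean = x.mean(axis=1)
    xc = x - mean[:, None]
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    if s[0] == 0 or s[n_components - 1] / s[0] < 1e-10:
        raise ValueError(
            f"data rank below n_components={n_components}; cannot whiten"
        )
    k = (u[:, :n_components] / s[:n_components]).T * np.sqrt(n_samples)
    transform = WhiteningTransform(mean=mean, matrix=k)
    return transform.apply(x), transform


def _sym_decorrelate(w: np.ndarray) -> np.ndarray:
    """W <- (W W^T)^(-1/2) W."""
    eigval, eigvec = np.linalg.eigh(w @ w.T)
    eigval = np.clip(eigval, 1e-12, None)
    return (eigvec / np.sqrt(eigval)) @ eigvec.T @ w


def fit_ica(
    data,
    n_components: int = 8,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> UnmixingResult:
    """Estimate the unmixing matrix with fixed-point (log-cosh) iteration.

    Deterministic given ``seed`` (which sets the random orthonormal starting
    rotation). Non-convergence within ``max_iter`` is reported through
    ``converged=False`` on the result, not raised: the last iterate is often
    still usable, and Gaussian-dominated data may legitimately never meet
    the tolerance.
    """
    x = _as_matrix(data)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples to fit ICA")
    z, transform = whiten(x, n_components)
    n, n_samples = z.shape
    rng = np.random.default_rng(seed)
    w, _ = np.linalg.qr(rng.standard_normal((n, n)))
    w = _sym_decorrelate(w)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        wz = w @ z
        g = np.tanh(wz)
        g_prime = 1.0 - g**2
        w_new = (g @ z.T) / n_samples - g_prime.mean(axis=1)[:, None] * w
        w_new = _sym_decorrelate(w_new)
        delta = np.max(np.abs(np.abs(np.einsum("ij,ij->i", w_new, w)) - 1.0))
        w = w_new
        if delta < tol:
            converged = True
            break
    W = w @ transform.matrix
    components = w @ z
    W, components = _canonicalize(W, components)
    return UnmixingResult(
        W=W,
        rotation=w,
        whitening=transform,
        components=components,
        n_components=n,
        n_iter=n_iter,
        converged=converged,
        tol=tol,
    )


def _canonicalize(W: np.ndarray, components: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix ICA's inherent ambiguities: unit component variance, positive peak
    sign, order by explained input variance (pseudo-inverse column norm)."""
    sd = components.std(axis=1)
    sd[sd == 0] = 1.0
    W = W / sd[:, None]
    components = components / sd[:, None]
    peak = np.abs(components).argmax(axis=1)
    signs = np.sign(components[np.arange(len(peak)), peak])
    signs[signs == 0] = 1.0
    W = W * signs[:, None]
    components = components * signs[:, None]
    col_norms = np.linalg.norm(np.linalg.pinv(W), axis=0)
    order = np.argsort(-col_norms)
    return W[order], components[order]


def separate(data, result: UnmixingResult) -> np.ndarray:
    """Apply a fitted unmixing map to (new) channel data: s = W (x - mean)."""
    x = _as_matrix(data)
    if x.shape[0] != result.W.shape[1]:
        raise ValueError(
            f"recording has {x.shape[0]} channels but W expects {result.W.shape[1]}"
        )
    return result.W @ (x - result.whitening.mean[:, None])


def amari_index(estimated_unmixing: np.ndarray, true_mixing: np.ndarray) -> float:
    """Permutation/scale-invariant recovery score in [0, 1]; 0 is perfect.

    Computed on ``P = estimated_unmixing @ true_mixing``: for a perfect
    separation P is a scaled permutation matrix and the index vanishes.
    """
    p = np.abs(np.asarray(estimated_unmixing) @ np.asarray(true_mixing))
    k = p.shape[0]
    if p.shape[0] != p.shape[1]:
        raise ValueError("P must be square; pass the reduced mixing matrix")
    row = (p / p.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    col = (p / p.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((row.sum() + col.sum()) / (2.0 * k * (k - 1.0)))


def match_components(
    true_sources: np.ndarray, components: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy sign/permutation-invariant matching of components to sources.

    Returns ``(assignment, correlations)`` where ``assignment[i]`` is the
    component index matched to source ``i`` and ``correlations[i]`` the
    absolute Pearson correlation of that pair.
    """
    s = np.asarray(true_sources, dtype=float)
    c = np.asarray(components, dtype=float)
    corr = np.zeros((s.shape[0], c.shape[0]))
    s_c = s - s.mean(axis=1, keepdims=True)
    c_c = c - c.mean(axis=1, keepdims=True)
    s_n = np.linalg.norm(s_c, axis=1)
    c_n = np.linalg.norm(c_c, axis=1)
    denom = np.outer(s_n, c_n)
    denom[denom == 0] = np.inf
    corr = np.abs(s_c @ c_c.T) / denom
    assignment = np.full(s.shape[0], -1)
    correlations = np.zeros(s.shape[0])
    work = corr.copy()
    for _ in range(min(work.shape)):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        assignment[i] = j
        correlations[i] = corr[i, j]
        work[i, :] = -1.0
        work[:, j] = -1.0
    return assignment, correlations
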