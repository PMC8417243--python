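"""Chebyshev spectral graph convolution encoder.

The channel graph's adjacency A (|Pearson r|, zero diagonal) is turned into
the symmetric normalized Laplacian L = I - D^{-1/2} A D^{-1/2}, whose
spectrum lies in [0, 2]. Rescaling, L~ = (2/λ_max) L - I, maps it into
[-1, 1], where Chebyshev polynomials T_k are well behaved, so a spectral
filter can be applied without any eigendecomposition through the recurrence

    T_0 X = X,  T_1 X = L~ X,  T_k X = 2 L~ T_{k-1} X - T_{k-2} X.

One convolution layer computes sum_k (T_k(L~) X) θ_k followed by ReLU; the
encoder stacks two such layers and a dense layer that flattens the node
features into an 18-value status code — one value per channel — consumed
downstream in chronological order.

λ_max is computed by dense eigendecomposition: the graphs here are tiny
(18 x 18), so this is exact and cheap. Degree-zero (isolated) nodes get a
zero D^{-1/2} entry and a zero Laplacian row, so an edgeless graph has
L = 0; λ_max is then floor-clamped to 1e-6 to keep the rescaling defined
(giving L~ = -I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reconstruction import ChannelGraph

LAMBDA_MAX_FLOOR = 1e-6


@dataclass
class GraphSpectrum:
    """Normalized Laplacian, its largest eigenvalue, and the rescaled form."""

    laplacian: np.ndarray
    lambda_max: float
    scaled_laplacian: np.ndarray


def scaled_laplacian(adjacency: np.ndarray) -> GraphSpectrum:
    """Symmetric normalized Laplacian rescaled to spectrum in [-1, 1]."""
    a = np.asarray(adjacency, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.any(a < 0):
        raise ValueError("adjacency must be nonnegative")
    if np.any(np.abs(np.diag(a)) > 0):
        raise ValueError("adjacency diagonal must be zero")

    deg = a.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    norm_adj = a * inv_sqrt[:, None] * inv_sqrt[None, :]
    lap = np.diag((deg > 0).astype(float)) - norm_adj  # isolated nodes: zero row
    lam = float(np.linalg.eigvalsh(lap).max()) if lap.any() else 0.0
    lam = max(lam, LAMBDA_MAX_FLOOR)
    scaled = (2.0 / lam) * lap - np.eye(a.shape[0])
    return GraphSpectrum(laplacian=lap, lambda_max=lam, scaled_laplacian=scaled)


def chebyshev_basis(spec: GraphSpectrum, X: np.ndarray, order_K: int) -> list[np.ndarray]:
    """[T_0(L~) X, ..., T_{K-1}(L~) X] via the three-term recurrence."""
    X = np.asarray(X, dtype=np.float64)
    if order_K < 1:
        raise ValueError("order_K must be >= 1")
    n = spec.scaled_laplacian.shape[0]
    if X.shape[0] != n:
        raise ValueError(f"X has {X.shape[0]} rows for a {n}-node graph")
    basis = [X]
    if order_K >= 2:
        basis.append(spec.scaled_laplacian @ X)
    for _ in range(2, order_K):
        basis.append(2.0 * spec.scaled_laplacian @ basis[-1] - basis[-2])
    return basis


def chebyshev_operator_stack(spec: GraphSpectrum, order_K: int) -> np.ndarray:
    """The K matrices T_k(L~) themselves, stacked (K, n, n).

    Precomputing these once per window turns both convolution layers into
    plain tensor contractions during training.
    """
    n = spec.scaled_laplacian.shape[0]
    return np.stack(chebyshev_basis(spec, np.eye(n), order_K))


def cheb_conv_layer(X: np.ndarray, spec: GraphSpectrum, theta: np.ndarray) -> np.ndarray:
    """One graph convolution layer: ReLU( sum_k T_k(L~) X θ_k ).

    theta has shape (K, in_width, out_width).
    """
    theta = np.asarray(theta, dtype=np.float64)
    if theta.ndim != 3:
        raise ValueError("theta must be (K, in_width, out_width)")
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != theta.shape[1]:
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else X.shape} does not "
            f"match theta in_width {theta.shape[1]}"
        )
    basis = chebyshev_basis(spec, X, theta.shape[0])
    out = sum(b @ th for b, th in zip(basis, theta))
    return np.maximum(out, 0.0)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


@dataclass
class EncoderParams:
    """Learnable parameters of the two-layer graph encoder + dense map."""

    theta_1: np.ndarray  # (K, n_bands, width_1)
    theta_2: np.ndarray  # (K, width_1, width_2)
    fc_weights: np.ndarray  # (n_channels * width_2, n_channels)
    fc_bias: np.ndarray  # (n_channels,)

    @property
    def order_K(self) -> int:
        return self.theta_1.shape[0]

    @property
    def n_channels(self) -> int:
        return self.fc_weights.shape[1]

    @classmethod
    def initialize(
        cls,
        rng: np.random.Generator,
        n_channels: int = 18,
        n_bands: int = 16,
        order_K: int = 3,
        width_1: int = 32,
        width_2: int = 32,
    ) -> "EncoderParams":
        """Glorot-uniform initialization; widths 16 -> 32 -> 32 -> 18."""
        if order_K < 1:
            raise ValueError("order_K must be >= 1")
        flat = n_channels * width_2
        return cls(
            theta_1=_glorot(rng, (order_K, n_bands, width_1), n_bands, width_1),
            theta_2=_glorot(rng, (order_K, width_1, width_2), width_1, width_2),
            fc_weights=_glorot(rng, (flat, n_channels), flat, n_channels),
            fc_bias=np.zeros(n_channels),
        )


@dataclass
class StatusCode:
    """The encoder's per-window embedding: one value per channel."""

    values: np.ndarray
    window_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()


def encode_status(g: ChannelGraph, params: EncoderParams,
                  window_index: int = 0, use_relative: bool = True) -> StatusCode:
    """Graph -> status code: two Chebyshev conv layers, flatten, dense map.

    Node features default to the relative band energies (each row sums to 1),
    which are scale-free and numerically well conditioned; set
    ``use_relative=False`` for raw energies.
    """
    X = g.node_features.relative if use_relative else g.node_features.energies
    if X.shape[0] != params.n_channels:
        raise ValueError(
            f"graph has {X.shape[0]} channels, params expect {params.n_channels}"
        )
    spec = scaled_laplacian(g.adjacency)
    h1 = cheb_conv_layer(X, spec, params.theta_1)
    h2 = cheb_conv_layer(h1, spec, params.theta_2)
    values = h2.ravel() @ params.fc_weights + params.fc_bias
    return StatusCode(values=values, window_index=window_index)
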