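"""Band-energy feature extraction and channel-graph construction.

Each channel of a window is decomposed with a full 4-level wavelet packet
transform (both the approximation and detail branches split at every level),
giving 2^4 = 16 terminal sub-bands that tile 0 .. fs/2 in equal widths. The
energy of each terminal node — the sum of squared coefficients — summarizes
that sub-band; the per-channel 16-vector of energies (or its normalized
relative form) is the node feature vector. Edges of the channel graph are
absolute pairwise Pearson correlations between the per-channel vectors.

Terminal packet nodes are returned in *frequency* order, not the natural
tree order (the packet tree interleaves bands because the detail branch
mirrors the spectrum); PyWavelets' ``order="freq"`` handles the re-sort.

Signals are extended with periodization at the borders, which keeps the
coefficient count at ``n / 2**depth`` per node and makes the transform
exactly orthonormal for orthogonal wavelets, so total band energy equals
total signal energy (Parseval) to floating-point precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt

from .eeg_io import EEGSegment

logger = logging.getLogger(__name__)

DEFAULT_WAVELET = "db4"
DEFAULT_DEPTH = 4


def wpd_terminal_coefficients(
    signal: np.ndarray,
    depth: int = DEFAULT_DEPTH,
    wavelet_name: str = DEFAULT_WAVELET,
) -> list[np.ndarray]:
    """Terminal wavelet-packet coefficient arrays, frequency-ordered ascending.

    Requires an orthogonal wavelet so that sub-band energies add up to the
    signal energy.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if len(signal) < 2**depth:
        raise ValueError(
            f"signal length {len(signal)} too short for depth {depth} "
            f"(needs >= {2**depth})"
        )
    try:
        wavelet = pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {wavelet_name!r}") from exc
    if not wavelet.orthogonal:
        raise ValueError(f"wavelet {wavelet_name!r} is not orthogonal")
    wp = pywt.WaveletPacket(signal, wavelet, mode="periodization", maxlevel=depth)
    return [np.asarray(node.data, dtype=np.float64)
            for node in wp.get_level(depth, order="freq")]


@dataclass
class BandEnergies:
    """Energies and relative shares for one channel's terminal sub-bands."""

    energies: np.ndarray
    relative: np.ndarray
    defined: bool  # False when total energy is zero (relative is all zeros)


def band_energies(coeff_sets: list[np.ndarray]) -> BandEnergies:
    """Per-node energy (sum of squared coefficients) and relative share."""
    if not coeff_sets:
        raise ValueError("coeff_sets must be nonempty")
    energies = np.array([float(np.sum(np.square(c))) for c in coeff_sets])
    total = energies.sum()
    if total > 0:
        return BandEnergies(energies, energies / total, True)
    return BandEnergies(energies, np.zeros_like(energies), False)


@dataclass
class BandEnergyMatrix:
    """Per-channel sub-band energy vectors (channels x 2^depth).

    ``energies`` is in µV²·samples; ``relative`` rows sum to 1 (unless a
    channel is identically zero). Columns are frequency-ordered ascending.
    """

    energies: np.ndarray
    relative: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.energies.shape != self.relative.shape:
            raise ValueError("energies and relative must share shape")
        if np.any(self.energies < 0):
            raise ValueError("energies must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.energies.shape[0]

    @property
    def n_bands(self) -> int:
        return self.energies.shape[1]

    @property
    def band_edges_hz(self) -> np.ndarray:
        """Edges of the frequency-ordered sub-bands, 0 .. fs/2."""
        return np.linspace(0.0, self.sampling_rate / 2.0, self.n_bands + 1)


def channel_energy_matrix(
    seg: EEGSegment,
    depth: int = DEFAULT_DEPTH,
    wavelet_name: str = DEFAULT_WAVELET,
) -> BandEnergyMatrix:
    """Band-energy rows for every channel of a segment."""
    rows = [band_energies(wpd_terminal_coefficients(ch, depth, wavelet_name))
            for ch in seg.samples]
    return BandEnergyMatrix(
        energies=np.stack([r.energies for r in rows]),
        relative=np.stack([r.relative for r in rows]),
        sampling_rate=seg.sampling_rate,
    )


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; constant inputs are defined as 0."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        logger.warning("constant input to pearson_correlation; returning 0")
        return 0.0
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


@dataclass
class ChannelGraph:
    """Weighted channel graph: |Pearson r| adjacency + band-energy features."""

    adjacency: np.ndarray
    node_features: BandEnergyMatrix
    raw_correlations: np.ndarray

    def __post_init__(self) -> None:
        a = self.adjacency
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")

    @property
    def n_channels(self) -> int:
        return self.adjacency.shape[0]


def build_channel_graph(
    bem: BandEnergyMatrix,
    mode: str = "energy_vectors",
    seg: EEGSegment | None = None,
) -> ChannelGraph:
    """Pairwise channel correlations -> weighted graph.

    mode="energy_vectors" (default) correlates the per-channel 16-value
    band-energy vectors; mode="raw_signals" correlates the raw time series
    of ``seg`` instead. Edge weights are |r| (nonnegative, as required by
    the normalized-Laplacian machinery); signed values are kept in
    ``raw_correlations``.
    """
    if mode == "energy_vectors":
        vectors = bem.energies
    elif mode == "raw_signals":
        if seg is None:
            raise ValueError("raw_signals mode requires the segment")
        if seg.n_channels != bem.n_channels:
            raise ValueError("segment/feature channel counts differ")
        vectors = seg.samples
    else:
        raise ValueError(f"unknown mode {mode!r}")

    n = vectors.shape[0]
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            corr[i, j] = corr[j, i] = pearson_correlation(vectors[i], vectors[j])
    adjacency = np.abs(corr)
    np.fill_diagonal(adjacency, 0.0)
    return ChannelGraph(adjacency=adjacency, node_features=bem, raw_correlations=corr)


def plot_band_energy_percentage(
    bem: BandEnergyMatrix, path: str, title: str = "Relative sub-band energy"
) -> None:
    """Bar plot of channel-averaged relative energy per sub-band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shares = 100.0 * bem.relative.mean(axis=0)
    edges = bem.band_edges_hz
    labels = [f"{edges[k]:.0f}-{edges[k + 1]:.0f}" for k in range(bem.n_bands)]
    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.bar(range(bem.n_bands), shares)
    ax.set_xticks(range(bem.n_bands), labels, rotation=60, fontsize=7)
    ax.set_xlabel("sub-band (Hz)")
    ax.set_ylabel("energy share (%)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
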