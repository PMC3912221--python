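"""Phase lag index (PLI) functional connectivity between all channel pairs.

The PLI of two phase series is the absolute mean sign of the sine of
their phase difference:

    PLI = | < sign( sin( delta_phi(t_k) ) ) > |,   k = 1..N

It measures the asymmetry of the distribution of instantaneous phase
differences around zero: a consistent non-zero phase lead or lag gives a
PLI near 1, while zero-lag coupling — the signature of volume conduction
and common sources at the sensor level — contributes sign(sin(0)) = 0 and
is therefore suppressed by construction. Samples with a phase difference
of exactly 0 or +/-pi carry no lag-direction information and count as 0.

Per-subject, per-band matrices are epoch-wise PLI matrices averaged
element-wise (not the PLI of concatenated epochs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import BandDefinition, EpochArray, bandpass, instantaneous_phase

__all__ = [
    "ConnectivityMatrix",
    "pli_pair",
    "pli_matrix",
    "average_epochs",
    "mean_connectivity",
    "mask_channels",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative channel x channel PLI weights in [0, 1]."""

    weights: np.ndarray
    channel_ids: list[str] = field(default_factory=list)
    band: BandDefinition | None = None
    n_epochs_averaged: int = 1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("PLI weights must lie in [0, 1]")
        self.weights = w
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:03d}" for i in range(w.shape[0])]
        elif len(self.channel_ids) != w.shape[0]:
            raise ValueError("channel_ids length does not match matrix size")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


def _wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles into [-pi, pi]."""
    return np.mod(x + np.pi, 2.0 * np.pi) - np.pi


def pli_pair(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """PLI between two phase series of equal length.

    With sign(sin(.)) the wrapping of the phase difference is
    mathematically redundant (sin is 2-pi periodic) but kept explicit.
    """
    a = np.asarray(phase_a, dtype=float).ravel()
    b = np.asarray(phase_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.size == 0:
        raise ValueError("empty phase series")
    dphi = _wrap_phase(a - b)
    return float(np.abs(np.mean(np.sign(np.sin(dphi)))))


def pli_matrix(
    epoch: EpochArray,
    band: BandDefinition,
    exclude_channels: list[str] | None = None,
) -> ConnectivityMatrix:
    """All-pairs PLI on the band-filtered epoch.

    ``exclude_channels`` drops known-bad sensors by id before the matrix
    is built (the reference acquisition excluded four malfunctioning
    sensors from all subjects).
    """
    if exclude_channels:
        epoch = mask_channels(epoch, exclude_channels)
    if epoch.n_channels < 2:
        raise ValueError("need at least 2 channels for a connectivity matrix")
    phases = instantaneous_phase(bandpass(epoch, band)).phase
    n = phases.shape[0]
    sin_p, cos_p = np.sin(phases), np.cos(phases)
    w = np.zeros((n, n))
    for i in range(n - 1):
        # sin(phi_i - phi_j) per sample, vectorised over j > i
        s = np.sign(sin_p[i] * cos_p[i + 1 :] - cos_p[i] * sin_p[i + 1 :])
        w[i, i + 1 :] = np.abs(s.mean(axis=1))
    w = w + w.T
    return ConnectivityMatrix(w, list(epoch.channel_ids), band, 1)


def mask_channels(epoch: EpochArray, exclude: list[str]) -> EpochArray:
    unknown = set(exclude) - set(epoch.channel_ids)
    if unknown:
        raise ValueError(f"unknown channel ids to exclude: {sorted(unknown)}")
    keep = [i for i, c in enumerate(epoch.channel_ids) if c not in exclude]
    return EpochArray(epoch.data[keep], epoch.fs, [epoch.channel_ids[i] for i in keep])


def average_epochs(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of per-epoch matrices (same band, same channels)."""
    if not matrices:
        raise ValueError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.channel_ids != first.channel_ids:
            raise ValueError("heterogeneous channel sets cannot be averaged")
        if (m.band is None) != (first.band is None) or (
            m.band is not None and first.band is not None and m.band.name != first.band.name
        ):
            raise ValueError("matrices come from different bands")
    mean = np.mean([m.weights for m in matrices], axis=0)
    total_epochs = sum(m.n_epochs_averaged for m in matrices)
    return ConnectivityMatrix(mean, list(first.channel_ids), first.band, total_epochs)


def mean_connectivity(matrix: ConnectivityMatrix) -> float:
    """Mean of the strictly-upper-triangle entries (average connectivity)."""
    n = matrix.n_channels
    if n < 2:
        raise ValueError("need at least 2 channels")
    iu = np.triu_indices(n, k=1)
    return float(matrix.weights[iu].mean())
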