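"""Epoch handling, band-pass decomposition, relative power, and phase extraction.

A resting-state recording is cut into fixed-length artifact-free epochs
(the reference acquisition uses 625 Hz sampling and 4096-sample epochs,
i.e. 6.554 s). Each epoch is decomposed into the six canonical frequency
bands — delta (0.5-4 Hz), theta (4-8 Hz), lower alpha (8-10 Hz), upper
alpha (10-13 Hz), beta (13-30 Hz), gamma (30-45 Hz) — by zero-phase
frequency-domain masking of the epoch's discrete Fourier transform.
Instantaneous phase is obtained from the analytic signal (Hilbert
transform) of the band-limited epoch.

Conventions
-----------
* The band-pass mask keeps DFT bins with ``f_lo <= f <= f_hi`` (both edges
  inclusive; adjacent bands may share a single edge bin).
* Relative power assigns each bin to a band by the lower-open interval
  ``(f_lo, f_hi]``, so contiguous bands partition the spectrum and the six
  fractions sum to one when normalised by total power over 0.5-45 Hz.
* No samples are trimmed after filtering by default; a configurable trim
  is available for callers that want to discard filter edge effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "EpochArray",
    "BandDefinition",
    "PhaseArray",
    "CANONICAL_BANDS",
    "select_epochs",
    "bandpass",
    "relative_power",
    "instantaneous_phase",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[f_lo, f_hi]`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got "
                f"({self.f_lo}, {self.f_hi})"
            )

    def validate_for_fs(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.f_hi} Hz is not below "
                f"the Nyquist frequency {fs / 2} Hz"
            )


#: The six canonical resting-state bands; contiguous from 0.5 to 45 Hz.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("lower_alpha", 8.0, 10.0),
    BandDefinition("upper_alpha", 10.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)


@dataclass
class EpochArray:
    """One channels x samples segment of multichannel signal.

    Parameters
    ----------
    data:
        2-D float array, shape ``(n_channels, n_samples)``.
    fs:
        Sampling frequency in Hz.
    channel_ids:
        Channel labels; defaults to ``ch000, ch001, ...``.
    """

    data: np.ndarray
    fs: float
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got ndim={self.data.ndim}")
        if self.data.shape[1] < 2:
            raise ValueError("an epoch needs at least 2 samples")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains non-finite values")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        elif len(self.channel_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for {self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Epoch duration in seconds (n_samples / fs)."""
        return self.n_samples / self.fs


@dataclass
class PhaseArray:
    """Instantaneous phase per channel per sample, wrapped to [-pi, pi)."""

    phase: np.ndarray
    fs: float
    band: BandDefinition | None = None
    channel_ids: list[str] = field(default_factory=list)


def select_epochs(raw: EpochArray, epoch_len: int, n_epochs: int) -> list[EpochArray]:
    """Cut the first ``n_epochs`` consecutive non-overlapping windows.

    Mirrors the selection of the first artifact-free epochs from a
    continuous recording (artifact screening itself is out of scope: the
    input is assumed clean).
    """
    if epoch_len < 2 or n_epochs < 1:
        raise ValueError("epoch_len must be >= 2 and n_epochs >= 1")
    needed = epoch_len * n_epochs
    if raw.n_samples < needed:
        raise ValueError(
            f"need {needed} samples for {n_epochs} epochs of {epoch_len}, "
            f"but only {raw.n_samples} are available"
        )
    return [
        EpochArray(
            raw.data[:, i * epoch_len : (i + 1) * epoch_len].copy(),
            raw.fs,
            list(raw.channel_ids),
        )
        for i in range(n_epochs)
    ]


def _rfft_freqs(n: int, fs: float) -> np.ndarray:
    return np.fft.rfftfreq(n, d=1.0 / fs)


def bandpass(epoch: EpochArray, band: BandDefinition) -> EpochArray:
    """Zero-phase band-pass by masking the epoch's DFT.

    Bins with ``f_lo <= f <= f_hi`` are kept, everything else (including
    DC) is zeroed, and the signal is reconstructed by the inverse real
    FFT. Hard band edges; by construction no phase distortion inside the
    passband.
    """
    band.validate_for_fs(epoch.fs)
    freqs = _rfft_freqs(epoch.n_samples, epoch.fs)
    mask = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    spec = np.fft.rfft(epoch.data, axis=1)
    spec[:, ~mask] = 0.0
    out = np.fft.irfft(spec, n=epoch.n_samples, axis=1)
    return EpochArray(out, epoch.fs, list(epoch.channel_ids))


def relative_power(
    epoch: EpochArray, bands: tuple[BandDefinition, ...] = CANONICAL_BANDS
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of spectral power per band, per channel.

    The periodogram is the unwindowed squared magnitude of the epoch's
    FFT. Each bin is assigned to the band whose interval ``(f_lo, f_hi]``
    contains it, and fractions are normalised by the total power over the
    union of all bands (0.5-45 Hz for the canonical set), so they sum to
    one when the bands are contiguous.

    Returns
    -------
    per_channel:
        Array of shape ``(n_channels, n_bands)``.
    mean:
        Band fractions averaged over channels, shape ``(n_bands,)``.
    """
    _check_non_overlapping(bands)
    freqs = _rfft_freqs(epoch.n_samples, epoch.fs)
    power = np.abs(np.fft.rfft(epoch.data, axis=1)) ** 2
    band_power = np.empty((epoch.n_channels, len(bands)))
    for j, band in enumerate(bands):
        band.validate_for_fs(epoch.fs)
        sel = (freqs > band.f_lo) & (freqs <= band.f_hi)
        band_power[:, j] = power[:, sel].sum(axis=1)
    total = band_power.sum(axis=1)
    if np.any(total <= 0):
        dead = [epoch.channel_ids[i] for i in np.flatnonzero(total <= 0)]
        raise ValueError(f"zero in-band power (all-zero signal?) on channels {dead}")
    frac = band_power / total[:, None]
    return frac, frac.mean(axis=0)


def _check_non_overlapping(bands: tuple[BandDefinition, ...]) -> None:
    ordered = sorted(bands, key=lambda b: b.f_lo)
    for a, b in zip(ordered, ordered[1:]):
        if b.f_lo < a.f_hi:
            raise ValueError(f"bands {a.name!r} and {b.name!r} overlap")


def instantaneous_phase(epoch: EpochArray, trim: int = 0) -> PhaseArray:
    """Per-channel instantaneous phase of the analytic signal.

    The epoch is expected to be band-limited already (use :func:`bandpass`
    first); the Hilbert construction is only meaningful on narrow-band
    signals. ``trim`` drops that many samples from each end of the phase
    series to discard transform edge effects (default keeps everything).
    """
    if np.any(np.ptp(epoch.data, axis=1) == 0):
        flat = [epoch.channel_ids[i] for i in np.flatnonzero(np.ptp(epoch.data, axis=1) == 0)]
        raise ValueError(f"constant channels have no defined phase: {flat}")
    analytic = hilbert(epoch.data, axis=1)
    phase = np.angle(analytic)
    # wrap (-pi, pi] -> [-pi, pi)
    phase = np.mod(phase + np.pi, 2.0 * np.pi) - np.pi
    if trim:
        if 2 * trim >= phase.shape[1]:
            raise ValueError("trim removes the whole epoch")
        phase = phase[:, trim:-trim]
    return PhaseArray(phase, epoch.fs, None, list(epoch.channel_ids))
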