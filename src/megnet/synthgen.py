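"""Synthetic inputs with planted ground truth for every pipeline stage.

Because the original cohort's recordings are not public, every downstream
stage is exercised on synthetic data whose structure is known by
construction:

* **Coupled oscillators** — multichannel band-limited signals in which
  channels of the same planted module share a common narrow-band Gaussian
  driver observed at channel-specific delays, so that any two coupled
  channels have a consistent non-zero phase lag (the configured
  ``phase_lag`` at the band's centre frequency, realised as an integer
  sample shift). Cross-module leakage is controlled separately, and a
  zero-lag mixing operator emulates volume conduction / common sources.
* **Planted weighted graphs** — block-structured connectivity matrices
  with a known module partition, for the modularity and node-role math.
* **Synthetic cohorts** — subject tables (sex, head surface, VO2 max, IQ,
  network metrics) generated from an explicit linear / mediation model
  with Gaussian noise. Covariate marginals imitate the reference cohort:
  sex ~ Bernoulli(0.5); head surface ~ Normal(231, 19) cm^2; VO2 max ~
  Normal(52, 7) ml/kg/min for men and Normal(40, 5.5) for women; IQ has
  mean 108 and residual SD 13 around the planted effects.

Every generator is a pure function of its spec, including the seed; no
global random state is touched. These generators make no attempt at
realistic MEG forward models, sensor geometry, 1/f spectra, or artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .netmodules import Partition, modularity_q
from .spectral import BandDefinition, EpochArray, bandpass

__all__ = [
    "OscillatorSpec",
    "PlantedGraphSpec",
    "CohortSpec",
    "generate_coupled_oscillators",
    "mix_zero_lag",
    "generate_planted_graph",
    "generate_cohort",
    "phase_lag_to_samples",
]


# ---------------------------------------------------------------------------
# coupled oscillators

@dataclass(frozen=True)
class OscillatorSpec:
    """Planted phase-lagged modular coupling for a multichannel recording.

    ``phase_lag`` must differ from 0 and pi: at those values the planted
    coupling is invisible to the phase lag index by design of the measure.
    """

    n_channels: int
    module_labels: tuple[int, ...]
    carrier_band: tuple[float, float] = (8.0, 13.0)
    coupling_within: float = 0.9
    coupling_between: float = 0.0
    phase_lag: float = math.pi / 4
    noise_sd: float = 1.0
    fs: float = 625.0
    n_samples: int = 4096
    n_epochs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or len(self.module_labels) != self.n_channels:
            raise ValueError("module_labels must have one entry per channel")
        lo, hi = self.carrier_band
        if not (0 < lo < hi):
            raise ValueError("carrier band must satisfy 0 < f_lo < f_hi")
        if self.fs <= 2 * hi:
            raise ValueError(f"fs={self.fs} must exceed twice the upper carrier {hi}")
        if self.n_samples < 512:
            raise ValueError("n_samples must be >= 512")
        for c, name in ((self.coupling_within, "coupling_within"),
                        (self.coupling_between, "coupling_between")):
            if not (0 <= c <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        wrapped = math.remainder(self.phase_lag, 2 * math.pi)
        if abs(wrapped) < 1e-9 or abs(abs(wrapped) - math.pi) < 1e-9:
            raise ValueError(
                "phase_lag of 0 or pi plants coupling the PLI cannot detect; "
                "choose a strictly intermediate lag"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


def phase_lag_to_samples(phase_lag: float, f_center: float, fs: float) -> int:
    """Integer sample delay approximating ``phase_lag`` at ``f_center``.

    ``round(phase_lag / (2 pi f_center) * fs)``, forced away from zero so a
    requested non-zero lag never collapses to simultaneity. The realised
    lag is therefore exact only at the centre frequency and quantised to
    the sample grid.
    """
    d = round(phase_lag / (2 * math.pi * f_center) * fs)
    if d == 0:
        d = 1 if phase_lag > 0 else -1
    return int(d)


def _bandlimited_noise(rng: np.random.Generator, n: int, band: tuple[float, float], fs: float) -> np.ndarray:
    x = rng.standard_normal(n)
    ep = EpochArray(x[None, :], fs)
    y = bandpass(ep, BandDefinition("carrier", band[0], band[1])).data[0]
    sd = y.std()
    return y / sd if sd > 0 else y


def generate_coupled_oscillators(spec: OscillatorSpec) -> list[EpochArray]:
    """Generate ``spec.n_epochs`` epochs of planted phase-lagged coupling.

    Channel ``c`` of module ``m`` observes that module's driver at delay
    ``c * d`` samples (``d`` from :func:`phase_lag_to_samples`), scaled by
    ``coupling_within``, plus the mean of the other modules' drivers at the
    same delay scaled by ``coupling_between``, plus independent white
    noise of SD ``noise_sd``. Distinct channels thus differ in delay by a
    non-zero multiple of ``d``, giving every coupled pair a consistent
    non-zero lag.
    """
    rng = np.random.default_rng(spec.seed)
    f_center = 0.5 * (spec.carrier_band[0] + spec.carrier_band[1])
    d = abs(phase_lag_to_samples(spec.phase_lag, f_center, spec.fs))
    max_shift = d * max(1, spec.n_channels - 1)
    modules = sorted(set(spec.module_labels))
    epochs = []
    for _ in range(spec.n_epochs):
        drivers = {
            m: _bandlimited_noise(rng, spec.n_samples + max_shift, spec.carrier_band, spec.fs)
            for m in modules
        }
        data = np.empty((spec.n_channels, spec.n_samples))
        for c, m in enumerate(spec.module_labels):
            off = max_shift - c * d  # larger channel index -> later (delayed) copy
            sig = spec.coupling_within * drivers[m][off : off + spec.n_samples]
            others = [drivers[o][off : off + spec.n_samples] for o in modules if o != m]
            if others and spec.coupling_between > 0:
                sig = sig + spec.coupling_between * np.mean(others, axis=0)
            data[c] = sig + spec.noise_sd * rng.standard_normal(spec.n_samples)
        epochs.append(EpochArray(data, spec.fs))
    return epochs


def mix_zero_lag(epochs: list[EpochArray], mixing: np.ndarray) -> list[EpochArray]:
    """Apply an instantaneous (zero-lag) channel mixing to every epoch.

    Each output sample is a weighted sum of the input channels at the same
    time point — the sensor-level signature of volume conduction. Used to
    check that the PLI ignores what such mixing adds.
    """
    mixing = np.asarray(mixing, dtype=float)
    if mixing.ndim != 2 or mixing.shape[0] != mixing.shape[1]:
        raise ValueError("mixing matrix must be square")
    out = []
    for ep in epochs:
        if mixing.shape[0] != ep.n_channels:
            raise ValueError(
                f"mixing is {mixing.shape[0]}x{mixing.shape[1]} but epoch has "
                f"{ep.n_channels} channels"
            )
        out.append(EpochArray(mixing @ ep.data, ep.fs, list(ep.channel_ids)))
    return out


# ---------------------------------------------------------------------------
# planted graphs

@dataclass(frozen=True)
class PlantedGraphSpec:
    module_sizes: tuple[int, ...] = (5, 5)
    w_in: float = 1.0
    w_out: float = 0.05
    weight_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.module_sizes) < 1 or any(s < 1 for s in self.module_sizes):
            raise ValueError("module_sizes must be positive")
        if self.w_in < 0 or self.w_out < 0:
            raise ValueError("w_in and w_out must be >= 0")
        if self.weight_noise_sd < 0:
            raise ValueError("weight_noise_sd must be >= 0")


def generate_planted_graph(spec: PlantedGraphSpec) -> tuple[ConnectivityMatrix, Partition]:
    """Block-structured symmetric weight matrix with its planted partition.

    Within-module entries are ``w_in``, between-module entries ``w_out``,
    optionally perturbed by symmetric Gaussian noise; weights are clipped
    to [0, 1] (PLI range), the diagonal is zero.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.repeat(np.arange(len(spec.module_sizes)), spec.module_sizes)
    n = labels.size
    w = np.where(labels[:, None] == labels[None, :], spec.w_in, spec.w_out).astype(float)
    if spec.weight_noise_sd > 0:
        noise = rng.normal(0, spec.weight_noise_sd, size=(n, n))
        w = w + np.triu(noise, 1) + np.triu(noise, 1).T
    np.fill_diagonal(w, 0.0)
    w = np.clip(w, 0.0, 1.0)
    matrix = ConnectivityMatrix(w)
    return matrix, Partition(labels, modularity_q(matrix, labels), 0)


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class CohortSpec:
    """Planted covariate and mediation structure for a subject table.

    The generated table follows

        metric   = 1   + beta_vo2_to_metric * vo2 + e_metric
        mediator = 0.5 + mediation_a * vo2        + e_mediator
        iq       = 108 + beta_vo2_to_iq * vo2 + mediation_b * mediator + e_iq

    with independent Gaussian errors of the configured SDs, so the planted
    indirect vo2 -> iq effect through the mediator is exactly
    ``mediation_a * mediation_b`` and the planted direct effect is
    ``beta_vo2_to_iq``. The default noise SDs (mediator 10, IQ 13) put the
    default mediation slopes of 0.5 at a standardised path strength of
    roughly 0.4 each — moderate, detectable effects on a cohort of a few
    hundred subjects — while keeping the IQ marginal near the reference
    cohort's 108 (13).
    """

    n_subjects: int = 219
    beta_vo2_to_metric: float = 0.0
    beta_vo2_to_iq: float = 0.0
    mediation_a: float = 0.0
    mediation_b: float = 0.0
    noise_sds: dict = field(
        default_factory=lambda: {"metric": 1.0, "mediator": 10.0, "iq": 13.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be >= 10")
        for key in ("metric", "mediator", "iq"):
            if self.noise_sds.get(key, 0) <= 0:
                raise ValueError(f"noise_sds[{key!r}] must be > 0")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Synthetic subject table with planted linear and mediation effects."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    sex = rng.integers(0, 2, size=n)  # 1 = male
    head = rng.normal(231.0, 19.0, size=n)
    vo2 = np.where(sex == 1, rng.normal(52.0, 7.0, size=n), rng.normal(40.0, 5.5, size=n))
    metric = 1.0 + spec.beta_vo2_to_metric * vo2 + rng.normal(
        0, spec.noise_sds["metric"], size=n
    )
    mediator = 0.5 + spec.mediation_a * vo2 + rng.normal(
        0, spec.noise_sds["mediator"], size=n
    )
    iq = (
        108.0
        + spec.beta_vo2_to_iq * vo2
        + spec.mediation_b * mediator
        + rng.normal(0, spec.noise_sds["iq"], size=n)
    )
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:04d}" for i in range(n)],
            "sex": sex,
            "head_surface_cm2": head,
            "vo2max": vo2,
            "iq": iq,
            "metric": metric,
            "mediator": mediator,
        }
    )
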