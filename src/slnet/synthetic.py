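"""Synthetic two-group resting-state EEG cohorts with planted coupling.

Each channel is a stochastic alpha-band oscillator (damped AR(2) process with
spectral peak near 10 Hz) plus independent white measurement noise.
Inter-channel dependence is induced by *shared latent drivers*: every channel
mixes in a global driver with weight ``base_coupling``; in group B (cases) a
second, focal driver is additionally mixed into a fixed contiguous block of
channels with weight ``effect_size``.  Generalized synchronization between
two channels therefore rises with the product of their driver weights, which
synchronization likelihood detects — a scalar knob for a group-level
connectivity difference without any claim of biophysical realism (no volume
conduction, no electrode geometry, no artifacts).

Defaults reproduce the recording structure of a routine pediatric EEG
work-up: two groups of 35 subjects, 17 channels, four 8-s epochs at 512 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import EpochedRecording

__all__ = [
    "CohortSpec",
    "DEFAULT_CHANNELS",
    "FOCAL_BLOCK",
    "generate_cohort",
    "generate_recording",
    "designated_edges",
]

# 10-20 montage minus the four electrodes dropped to limit eye-movement
# artifact (Fp1, Fp2, A1, A2).
DEFAULT_CHANNELS = (
    "F8", "F4", "Fz", "F3", "F7",
    "T8", "C4", "Cz", "C3", "T7",
    "P8", "P4", "Pz", "P3", "P7",
    "O1", "O2",
)

# Contiguous temporo-central block sharing the focal driver in group B.
FOCAL_BLOCK = ("T8", "C4", "Cz", "C3", "T7", "P8")


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Attributes
    ----------
    n_per_group : int
        Subjects per group (>= 2).
    n_channels : int
        Number of EEG channels.
    fs : float
        Sampling frequency, Hz.
    epoch_seconds : float
        Epoch duration, s; ``epoch_seconds * fs`` must be an integer >= 64.
    n_epochs : int
        Artifact-free epochs per subject.
    base_coupling : float
        Global-driver mixing weight shared by all channels, in [0, 1).
    effect_size : float
        Extra focal-driver weight planted in group B on the designated
        channel block; ``base_coupling + effect_size < 1``.
    noise_sd : float
        White measurement-noise SD relative to unit signal variance.
    seed : int
        Master seed; expands to per-subject substreams.
    """

    n_per_group: int = 35
    n_channels: int = 17
    fs: float = 512.0
    epoch_seconds: float = 8.0
    n_epochs: int = 4
    base_coupling: float = 0.3
    effect_size: float = 0.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("invalid spec: n_per_group must be >= 2")
        if self.n_channels < 2:
            raise ValueError("invalid spec: n_channels must be >= 2")
        if self.fs <= 0:
            raise ValueError("invalid spec: fs must be > 0")
        n_samp = self.epoch_seconds * self.fs
        if abs(n_samp - round(n_samp)) > 1e-9 or round(n_samp) < 64:
            raise ValueError(
                "invalid spec: epoch_seconds * fs must be an integer >= 64"
            )
        if not 0.0 <= self.base_coupling < 1.0:
            raise ValueError("invalid spec: base_coupling must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("invalid spec: effect_size must be >= 0")
        if self.base_coupling + self.effect_size >= 1.0:
            raise ValueError("invalid spec: base_coupling + effect_size must be < 1")
        if self.noise_sd < 0:
            raise ValueError("invalid spec: noise_sd must be >= 0")
        if self.n_epochs < 1:
            raise ValueError("invalid spec: n_epochs must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_seconds * self.fs))

    def channel_labels(self) -> list[str]:
        if self.n_channels <= len(DEFAULT_CHANNELS):
            return list(DEFAULT_CHANNELS[: self.n_channels])
        extra = [f"X{i}" for i in range(self.n_channels - len(DEFAULT_CHANNELS))]
        return list(DEFAULT_CHANNELS) + extra

    def focal_channels(self) -> list[int]:
        """Indices of the channel block carrying the planted focal driver."""
        labels = self.channel_labels()
        idx = [labels.index(c) for c in FOCAL_BLOCK if c in labels]
        if len(idx) < 2:  # tiny montages: fall back to the first half
            idx = list(range(max(2, self.n_channels // 2)))
        return idx


def designated_edges(spec: CohortSpec) -> list[tuple[int, int]]:
    """Channel pairs on which group B's coupling increment is planted."""
    block = spec.focal_channels()
    return [(i, j) for a, i in enumerate(block) for j in block[a + 1:]]


def _ar2_oscillator(
    rng: np.random.Generator,
    n: int,
    fs: float,
    peak_hz: float = 10.0,
    radius: float = 0.97,
    burn_in: int = 512,
) -> np.ndarray:
    """Unit-variance damped AR(2) process with spectral peak near ``peak_hz``.

    Pole radius 0.97 gives a resonance a few Hz wide — an alpha-like rhythm
    for an awake, eyes-closed recording.
    """
    from scipy.signal import lfilter

    theta = 2.0 * np.pi * peak_hz / fs
    a1 = 2.0 * radius * np.cos(theta)
    a2 = -(radius**2)
    eps = rng.standard_normal(n + burn_in)
    x = lfilter([1.0], [1.0, -a1, -a2], eps)[burn_in:]
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_recording(
    spec: CohortSpec, group: str, subject_index: int
) -> EpochedRecording:
    """One subject's recording; seeded by (spec.seed, group, subject_index).

    Per-subject seeds are derived from the master seed with a
    ``SeedSequence`` keyed on group and subject index, so subject ``k`` is
    bitwise reproducible regardless of how many other subjects are drawn.
    """
    if group not in ("control", "case"):
        raise ValueError("group must be 'control' or 'case'")
    group_key = 0 if group == "control" else 1
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), group_key, int(subject_index)])
    )
    n_total = spec.n_samples * spec.n_epochs
    a = spec.base_coupling
    b = spec.effect_size if group == "case" else 0.0
    block = set(spec.focal_channels())

    global_driver = _ar2_oscillator(rng, n_total, spec.fs)
    focal_driver = _ar2_oscillator(rng, n_total, spec.fs)

    data = np.empty((spec.n_channels, n_total))
    for c in range(spec.n_channels):
        own = _ar2_oscillator(rng, n_total, spec.fs)
        b_c = b if c in block else 0.0
        w_own = np.sqrt(max(0.0, 1.0 - a**2 - b_c**2))
        sig = w_own * own + a * global_driver + b_c * focal_driver
        data[c] = sig + spec.noise_sd * rng.standard_normal(n_total)

    epochs = [
        data[:, k * spec.n_samples : (k + 1) * spec.n_samples].copy()
        for k in range(spec.n_epochs)
    ]
    prefix = "ctrl" if group == "control" else "case"
    return EpochedRecording(
        subject_id=f"{prefix}{subject_index:03d}",
        channel_labels=spec.channel_labels(),
        fs=spec.fs,
        epochs=epochs,
    )


def generate_cohort(spec: CohortSpec) -> list[tuple[EpochedRecording, str]]:
    """Two labelled groups of synthetic recordings, deterministic given seed.

    Group A ("control") channels share only the global driver; group B
    ("case") additionally mixes the focal driver into the designated block
    with weight ``effect_size``.  With ``effect_size == 0`` both groups are
    drawn from the identical generative law.
    """
    cohort: list[tuple[EpochedRecording, str]] = []
    for group in ("control", "case"):
        for k in range(spec.n_per_group):
            cohort.append((generate_recording(spec, group, k), group))
    return cohort
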