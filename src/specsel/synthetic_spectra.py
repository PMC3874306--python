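"""Synthetic IR-like spectra with planted informative wavelengths.

Every spectrum is a fixed smooth baseline plus, at each planted index, a
truncated Gaussian band whose amplitude increases affinely with the class
concentration (Beer-Lambert-style linearity), plus scaled correlated
copies on neighboring variables and white noise.  The generator returns
the planted indices as the recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .spectral_data import SampleSet, from_arrays

# amplitude(c) = AMP_SLOPE * c + AMP_OFFSET, c in percent
AMP_SLOPE = 0.008
AMP_OFFSET = 0.1
# correlated neighbor k steps away carries a 0.8**k scaled copy
REDUNDANCY_DECAY = 0.8
# sd of the independent jitter on redundant copies
JITTER_SD = 0.02
# bands are cut to exactly zero beyond this many widths from their center
BAND_TRUNCATION = 4.0

# role-count tables for the two reference concentration designs:
# class -> (n_train, n_test, n_commercial)
HIGH_COUNTS: dict[int, tuple[int, int, int]] = {
    20: (20, 6, 0),
    25: (19, 18, 2),
    50: (16, 13, 0),
    70: (14, 1, 0),
    100: (17, 6, 19),
}
LOW_COUNTS: dict[int, tuple[int, int, int]] = {
    2: (19, 1, 0),
    4: (17, 1, 0),
    6: (16, 13, 0),
    8: (22, 6, 0),
    10: (21, 6, 1),
    16: (20, 6, 1),
    20: (19, 6, 0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full ground truth of a generated dataset."""

    variable_count: int = 176
    class_levels: tuple[int, ...] = (20, 25, 50, 70, 100)
    counts_per_class_per_role: Mapping[int, tuple[int, int, int]] = field(
        default_factory=lambda: dict(HIGH_COUNTS)
    )
    informative_indices: tuple[int, ...] = (94, 95)
    band_width: float = 1.5
    redundancy_spread: int = 2
    noise_sd: float = 0.01
    baseline_coeffs: tuple[float, ...] = (0.5, 0.3, -0.2)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.variable_count < 1:
            raise ConfigError("variable_count must be >= 1")
        if not self.informative_indices:
            raise ConfigError("informative_indices must not be empty")
        for j in self.informative_indices:
            if not 1 <= j <= self.variable_count:
                raise ConfigError(
                    f"informative_indices: index {j} outside 1..{self.variable_count}"
                )
        if self.band_width <= 0:
            raise ConfigError("band_width must be positive")
        if self.redundancy_spread < 0:
            raise ConfigError("redundancy_spread must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if set(self.counts_per_class_per_role) != set(self.class_levels):
            raise ConfigError(
                "counts_per_class_per_role keys must equal class_levels"
            )
        for c, counts in self.counts_per_class_per_role.items():
            if len(counts) != 3 or any(n < 0 for n in counts):
                raise ConfigError(
                    f"counts_per_class_per_role[{c}] must be 3 non-negative counts"
                )


def high_concentration_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Five-level design (20/25/50/70/100 %): 86 train, 44 test, 21 commercial."""
    return replace(SyntheticConfig(rng_seed=seed), **overrides)


def low_concentration_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Seven-level design (2..20 %): 134 train, 39 test, 2 commercial."""
    cfg = SyntheticConfig(
        class_levels=(2, 4, 6, 8, 10, 16, 20),
        counts_per_class_per_role=dict(LOW_COUNTS),
        rng_seed=seed,
    )
    return replace(cfg, **overrides)


def amplitude(concentration: float) -> float:
    """Band amplitude as an affine, strictly increasing map of percent
    concentration."""
    return AMP_SLOPE * float(concentration) + AMP_OFFSET


def _baseline(config: SyntheticConfig) -> np.ndarray:
    v = config.variable_count
    t = np.arange(v) / max(v - 1, 1)
    out = np.zeros(v)
    for p, coef in enumerate(config.baseline_coeffs):
        out += coef * t**p
    return out


def _band(config: SyntheticConfig, center: int) -> np.ndarray:
    """Unit-amplitude Gaussian band, truncated to exactly zero beyond
    BAND_TRUNCATION band widths so distant variables carry no signal."""
    idx = np.arange(1, config.variable_count + 1, dtype=float)
    band = np.exp(-((idx - center) ** 2) / (2.0 * config.band_width**2))
    band[np.abs(idx - center) > BAND_TRUNCATION * config.band_width] = 0.0
    return band


def class_signal(config: SyntheticConfig, concentration: float) -> np.ndarray:
    """Noise-free class-dependent part of a spectrum (bands + redundant
    copies, before jitter)."""
    v = config.variable_count
    amp = amplitude(concentration)
    signal = np.zeros(v)
    for j in config.informative_indices:
        signal += amp * _band(config, j)
        for k in range(1, config.redundancy_spread + 1):
            for neighbor in (j - k, j + k):
                if 1 <= neighbor <= v:
                    signal[neighbor - 1] += REDUNDANCY_DECAY**k * amp
    return signal


def _redundant_positions(config: SyntheticConfig) -> list[int]:
    positions = set()
    for j in config.informative_indices:
        for k in range(1, config.redundancy_spread + 1):
            for neighbor in (j - k, j + k):
                if 1 <= neighbor <= config.variable_count:
                    positions.add(neighbor)
    return sorted(positions)


def generate_dataset(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[SampleSet, tuple[int, ...]]:
    """Generate a labeled sample set and return it with the planted indices.

    Sample order is deterministic: classes in ``class_levels`` order, roles
    train/test/commercial within each class.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    baseline = _baseline(config)
    redundant = np.array(_redundant_positions(config), dtype=int) - 1
    rows, labels, roles = [], [], []
    for c in config.class_levels:
        signal = baseline + class_signal(config, c)
        n_train, n_test, n_comm = config.counts_per_class_per_role[c]
        for role, n in (("train", n_train), ("test", n_test), ("commercial", n_comm)):
            for _ in range(n):
                spectrum = signal.copy()
                if redundant.size:
                    spectrum[redundant] += rng.normal(0.0, JITTER_SD, redundant.size)
                if config.noise_sd > 0:
                    spectrum += rng.normal(0.0, config.noise_sd, config.variable_count)
                rows.append(spectrum)
                labels.append(str(c))
                roles.append(role)
    matrix = np.vstack(rows) if rows else np.empty((0, config.variable_count))
    sample_set = from_arrays(
        matrix, labels, roles, class_levels=[str(c) for c in config.class_levels]
    )
    return sample_set, tuple(config.informative_indices)


def recovery_window(config: SyntheticConfig) -> set[int]:
    """Indices counted as a successful recovery: planted ones plus their
    correlated neighbors within ``redundancy_spread``."""
    window = set()
    for j in config.informative_indices:
        for k in range(-config.redundancy_spread, config.redundancy_spread + 1):
            if 1 <= j + k <= config.variable_count:
                window.add(j + k)
    return window


def difficulty_sweep(
    base: SyntheticConfig, noise_grid: Sequence[float]
) -> list[tuple[SampleSet, tuple[int, ...]]]:
    """One dataset per noise level, all other parameters shared; each level
    draws from its own substream of the base seed."""
    if len(noise_grid) == 0:
        raise ConfigError("noise_grid must not be empty")
    streams = np.random.SeedSequence(base.rng_seed).spawn(len(noise_grid))
    out = []
    for sd, ss in zip(noise_grid, streams):
        cfg = replace(base, noise_sd=float(sd))
        out.append(generate_dataset(cfg, rng=np.random.default_rng(ss)))
    return out
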