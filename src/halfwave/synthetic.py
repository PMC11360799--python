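"""Stage-labelled synthetic EEG epochs for end-to-end pipeline testing.

Each sleep stage is emulated as a sum of band-limited sinusoids — frequencies
drawn within the classical EEG bands (delta 0.5-4 Hz, theta 4-8 Hz, alpha
8-12 Hz, beta 12-30 Hz) with amplitudes set by per-stage relative band
weights and an overall RMS amplitude — plus additive white Gaussian noise.
Optional fixed tones (e.g. a 13 Hz spindle-like component for stage 2) are
added deterministically on top.

The default stage specs follow textbook sleep EEG: slow-wave stages are
delta-dominant and high-amplitude, stage 1 theta-dominant, stage 2 theta with
a sigma-band burst, wake alpha/beta, and REM a mixed low-amplitude theta/beta
pattern.  This is a controllable test harness, not a physiological simulator:
no 1/f background, artifacts, or stage transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BANDS",
    "SLPDB_PROPORTIONS",
    "StageSpec",
    "SimConfig",
    "DEFAULT_STAGE_SPECS",
    "default_stage_specs",
    "generate_epoch",
    "generate_dataset",
    "draw_class_counts",
]

#: classical EEG frequency bands in Hz: (low, high)
BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}

#: empirical slpdb sleep-stage proportions (S1, S2, S3, S4, R, W)
SLPDB_PROPORTIONS = {
    "S1": 0.1779,
    "S2": 0.3828,
    "S3": 0.0476,
    "S4": 0.0178,
    "R": 0.0689,
    "W": 0.3050,
}


@dataclass(frozen=True)
class StageSpec:
    """Generative recipe for one sleep stage.

    Parameters
    ----------
    stage : str
        Stage label, e.g. "S2".
    band_weights : tuple of 4 floats
        Relative power in (delta, theta, alpha, beta); non-negative, not all
        zero.
    amplitude : float
        Target RMS of the oscillatory part, arbitrary units (think µV).
    noise_sd : float
        SD of the additive white Gaussian noise.
    tones : tuple of (freq_hz, amplitude) pairs
        Deterministic extra sinusoids (random phase), e.g. sleep spindles.
    n_components : int
        Sinusoids drawn per nonzero band.
    """

    stage: str
    band_weights: tuple[float, float, float, float]
    amplitude: float = 30.0
    noise_sd: float = 5.0
    tones: tuple[tuple[float, float], ...] = ()
    n_components: int = 2

    def __post_init__(self) -> None:
        w = np.asarray(self.band_weights, dtype=float)
        if w.size != 4 or np.any(w < 0) or not np.any(w > 0):
            raise ValueError(
                "band_weights must be 4 non-negative values, not all zero"
            )

    @property
    def dominant_band(self) -> str:
        return list(BANDS)[int(np.argmax(self.band_weights))]


@dataclass(frozen=True)
class SimConfig:
    """Dataset-level simulation settings."""

    fs: float = 250.0
    epoch_seconds: float = 30.0
    seed: int | None = None

    def __post_init__(self) -> None:
        n = self.fs * self.epoch_seconds
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise ValueError("fs * epoch_seconds must be a positive integer")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_seconds))


#: default stage recipes (delta, theta, alpha, beta weights)
DEFAULT_STAGE_SPECS = {
    "W": StageSpec("W", (0.05, 0.10, 0.50, 0.35), amplitude=30.0, noise_sd=5.0),
    "S1": StageSpec("S1", (0.10, 0.60, 0.20, 0.10), amplitude=45.0, noise_sd=5.0),
    "S2": StageSpec(
        "S2", (0.25, 0.50, 0.05, 0.20), amplitude=60.0, noise_sd=5.0,
        tones=((13.0, 15.0),),
    ),
    "S3": StageSpec("S3", (0.80, 0.15, 0.03, 0.02), amplitude=110.0, noise_sd=8.0),
    "S4": StageSpec("S4", (0.92, 0.05, 0.02, 0.01), amplitude=150.0, noise_sd=8.0),
    "R": StageSpec("R", (0.10, 0.45, 0.15, 0.30), amplitude=18.0, noise_sd=4.0),
}


def default_stage_specs(stages=("W", "S1", "S2", "S3", "R")) -> list[StageSpec]:
    """The default five-class stage set (S4 available on request)."""
    return [DEFAULT_STAGE_SPECS[s] for s in stages]


def generate_epoch(
    spec: StageSpec,
    cfg: SimConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """One synthetic epoch of ``cfg.n_samples`` samples for the given stage."""
    cfg = cfg or SimConfig()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    t = np.arange(cfg.n_samples) / cfg.fs
    w = np.asarray(spec.band_weights, dtype=float)
    w = w / w.sum()

    x = np.zeros(cfg.n_samples)
    for (lo, hi), weight in zip(BANDS.values(), w):
        if weight == 0:
            continue
        # n_components sinusoids sharing this band's power budget:
        # sum of a^2/2 over the band = amplitude^2 * weight
        a = spec.amplitude * np.sqrt(2.0 * weight / spec.n_components)
        freqs = rng.uniform(lo, min(hi, cfg.fs / 2), size=spec.n_components)
        phases = rng.uniform(0, 2 * np.pi, size=spec.n_components)
        for f, ph in zip(freqs, phases):
            x += a * np.sin(2 * np.pi * f * t + ph)
    for f, a in spec.tones:
        x += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if spec.noise_sd > 0:
        x += rng.normal(0.0, spec.noise_sd, cfg.n_samples)
    return x


def draw_class_counts(
    n_total: int,
    proportions: dict[str, float],
    rng: np.random.Generator,
) -> dict[str, int]:
    """Multinomial class counts for ``n_total`` epochs."""
    stages = list(proportions)
    p = np.asarray([proportions[s] for s in stages], dtype=float)
    p = p / p.sum()
    counts = rng.multinomial(n_total, p)
    return dict(zip(stages, (int(c) for c in counts)))


def generate_dataset(
    cfg: SimConfig | None = None,
    specs: list[StageSpec] | None = None,
    n_epochs_per_class: int = 40,
    class_proportions: dict[str, float] | None = None,
    n_total: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled synthetic dataset of shape (n_epochs, n_samples).

    Balanced by default (``n_epochs_per_class`` per stage spec); passing
    ``class_proportions`` (e.g. :data:`SLPDB_PROPORTIONS`) with ``n_total``
    draws imbalanced multinomial counts instead.  Epochs are shuffled; fully
    deterministic under ``cfg.seed``.
    """
    cfg = cfg or SimConfig()
    specs = specs if specs is not None else default_stage_specs()
    if len(specs) < 2:
        raise ValueError("need at least 2 stage specs")
    rng = np.random.default_rng(cfg.seed)

    by_stage = {s.stage: s for s in specs}
    if class_proportions is not None:
        if n_total is None:
            raise ValueError("n_total is required with class_proportions")
        missing = set(class_proportions) - set(by_stage)
        if missing:
            raise ValueError(f"no StageSpec for classes {sorted(missing)}")
        counts = draw_class_counts(n_total, class_proportions, rng)
    else:
        counts = {s.stage: n_epochs_per_class for s in specs}

    epochs, labels = [], []
    for stage, count in counts.items():
        spec = by_stage[stage]
        for _ in range(count):
            epochs.append(generate_epoch(spec, cfg, rng))
            labels.append(stage)
    X = np.asarray(epochs)
    y = np.asarray(labels, dtype=object)
    perm = rng.permutation(len(labels))
    return X[perm], y[perm]
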