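"""Time-domain features of the level-2 Halfwave reduction, per 30-s epoch.

Six scalars summarise the piecewise-linear reduced epoch:

==============  ======================================================
``E``           number of surviving extremal points
``S_mean_abs``  mean absolute slope of the linear segments
``S_max``       maximum signed segment slope
``E_bar``       mean of the extremal values
``y_min``       absolute minimum of the extremal values
``y_max``       absolute maximum of the extremal values
==============  ======================================================

Slopes are in value units per sample (indices as abscissa); multiply by the
sampling rate for per-second units.  The segment slopes form a variable-length
set, summarised here by the mean absolute slope (``slope_summary="mean"``
gives the signed mean instead).  The amplitude statistics are computed on the
reduced extremal values by default; ``raw_stats=True`` computes them on the
raw window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .reduction import Signal, reduce_to_level

__all__ = [
    "FEATURE_NAMES",
    "Epoch",
    "EpochFeatures",
    "segment_epochs",
    "extract_features",
    "features_from_knots",
    "build_feature_matrix",
    "LabeledSet",
    "HalfwaveFeatureExtractor",
]

FEATURE_NAMES = ("E", "S_mean_abs", "S_max", "E_bar", "y_min", "y_max")


@dataclass(frozen=True)
class Epoch:
    """A fixed-length signal window with an optional sleep-stage label."""

    signal: Signal
    label: str | None = None


@dataclass(frozen=True)
class EpochFeatures:
    E: int
    S_mean_abs: float
    S_max: float
    E_bar: float
    y_min: float
    y_max: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.E, self.S_mean_abs, self.S_max, self.E_bar, self.y_min, self.y_max],
            dtype=float,
        )


@dataclass(frozen=True)
class LabeledSet:
    """Feature matrix X (d features x n epochs) with per-epoch labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (features x epochs)")
        if X.shape[1] != y.size:
            raise ValueError(
                f"X has {X.shape[1]} columns but {y.size} labels were given"
            )
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.X.shape[1]


def segment_epochs(
    signal: Signal | np.ndarray,
    epoch_seconds: float = 30.0,
    fs: float | None = None,
    labels: Sequence[str] | None = None,
) -> list[Epoch]:
    """Cut a signal into consecutive non-overlapping fixed-length epochs.

    A trailing partial epoch is discarded; the epoch count is
    ``floor(len(signal) / (fs * epoch_seconds))``.  At the default 250 Hz and
    30 s every epoch holds exactly 7500 samples.
    """
    if not isinstance(signal, Signal):
        signal = Signal(np.asarray(signal, dtype=float), fs=fs or 250.0)
    width_f = signal.fs * epoch_seconds
    width = int(round(width_f))
    if width <= 0 or abs(width_f - width) > 1e-9:
        raise ValueError(
            f"fs * epoch_seconds must be a positive integer, got {width_f}"
        )
    n_epochs = len(signal) // width
    epochs = []
    for j in range(n_epochs):
        sl = Signal(
            signal.samples[j * width : (j + 1) * width],
            fs=signal.fs,
            t0=signal.t0 + j * width,
        )
        epochs.append(Epoch(sl, None if labels is None else labels[j]))
    return epochs


def features_from_knots(
    indices: np.ndarray, values: np.ndarray, slope_summary: str = "mean_abs"
) -> EpochFeatures:
    """Feature vector from the knots of a piecewise-linear reduced epoch."""
    indices = np.asarray(indices, dtype=float)
    values = np.asarray(values, dtype=float)
    e = int(values.size)
    if e < 2:
        raise ValueError("need at least 2 knots; use extract_features for fallback")
    slopes = np.diff(values) / np.diff(indices)
    if slope_summary == "mean_abs":
        s_summary = float(np.mean(np.abs(slopes)))
    elif slope_summary == "mean":
        s_summary = float(np.mean(slopes))
    else:
        raise ValueError(f"unknown slope_summary {slope_summary!r}")
    return EpochFeatures(
        E=e,
        S_mean_abs=s_summary,
        S_max=float(np.max(slopes)),
        E_bar=float(np.mean(values)),
        y_min=float(np.min(values)),
        y_max=float(np.max(values)),
    )


def extract_features(
    epoch: Epoch | Signal | np.ndarray,
    level: int = 2,
    preserve_endpoints: bool = True,
    raw_stats: bool = False,
    slope_summary: str = "mean_abs",
) -> EpochFeatures:
    """Six time-domain features of one epoch's level-``level`` reduction.

    Degenerate epochs whose reduction keeps fewer than two points fall back to
    zero slopes with ``E_bar``/``y_min``/``y_max`` taken from the raw window.
    """
    if isinstance(epoch, Epoch):
        sig = epoch.signal
    elif isinstance(epoch, Signal):
        sig = epoch
    else:
        sig = Signal(np.asarray(epoch, dtype=float))
    lvl = reduce_to_level(sig, k=level, preserve_endpoints=preserve_endpoints)
    if len(lvl) < 2:
        raw = sig.samples
        return EpochFeatures(
            E=len(lvl),
            S_mean_abs=0.0,
            S_max=0.0,
            E_bar=float(np.mean(raw)),
            y_min=float(np.min(raw)),
            y_max=float(np.max(raw)),
        )
    feats = features_from_knots(lvl.indices, lvl.values, slope_summary)
    if raw_stats:
        raw = sig.samples
        feats = EpochFeatures(
            E=feats.E,
            S_mean_abs=feats.S_mean_abs,
            S_max=feats.S_max,
            E_bar=float(np.mean(raw)),
            y_min=float(np.min(raw)),
            y_max=float(np.max(raw)),
        )
    return feats


def build_feature_matrix(
    epochs: Sequence[Epoch | Signal | np.ndarray],
    level: int = 2,
    standardize: bool = False,
    **kwargs,
) -> LabeledSet:
    """Stack per-epoch feature vectors as the columns of a d x n matrix.

    Labels are carried in epoch order.  With ``standardize`` each feature row
    is centred and scaled to unit variance over the given epochs (constant
    rows are centred only).
    """
    n = len(epochs)
    X = np.empty((len(FEATURE_NAMES), n), dtype=float)
    y = np.empty(n, dtype=object)
    for j, ep in enumerate(epochs):
        X[:, j] = extract_features(ep, level=level, **kwargs).as_array()
        y[j] = ep.label if isinstance(ep, Epoch) else None
    if standardize and n:
        mean = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mean) / sd
    return LabeledSet(X, y)


class HalfwaveFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping raw epochs to the six Halfwave features.

    Input is an array of shape ``(n_epochs, n_samples)``; output has shape
    ``(n_epochs, 6)`` with columns ordered as :data:`FEATURE_NAMES`.  The
    transform is stateless; ``fit`` only records the epoch length.

    Parameters
    ----------
    level : int, default 2
        Halfwave reduction level applied to each epoch.
    fs : float, default 250.0
        Sampling rate in Hz (carried into the Signal objects).
    preserve_endpoints : bool, default True
        Keep the last extremal point across reduction passes.
    raw_stats : bool, default False
        Compute the amplitude statistics on the raw window instead of the
        reduced extremal values.
    slope_summary : {"mean_abs", "mean"}, default "mean_abs"
        How the variable-length slope set is collapsed to one scalar.
    """

    def __init__(
        self,
        level: int = 2,
        fs: float = 250.0,
        preserve_endpoints: bool = True,
        raw_stats: bool = False,
        slope_summary: str = "mean_abs",
    ):
        self.level = level
        self.fs = fs
        self.preserve_endpoints = preserve_endpoints
        self.raw_stats = raw_stats
        self.slope_summary = slope_summary

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = check_array(X, dtype=float)
        out = np.empty((X.shape[0], len(FEATURE_NAMES)), dtype=float)
        for j in range(X.shape[0]):
            out[j] = extract_features(
                Signal(X[j], fs=self.fs),
                level=self.level,
                preserve_endpoints=self.preserve_endpoints,
                raw_stats=self.raw_stats,
                slope_summary=self.slope_summary,
            ).as_array()
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
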