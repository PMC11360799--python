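"""Halfwave piecewise-linear signal reduction.

The Halfwave method compresses a sampled signal to its alternating sequence of
local extrema (level 1) and then iteratively deletes *trivial* half-waves:
consecutive extremum pairs whose amplitude change ``|Δi| = |y[i+1] - y[i]|`` is
no larger than both neighbouring changes.  Each deletion pass produces the next
reduction level; the fixed point of the iteration is the *complete* Halfwave.
Linear interpolation through the surviving extrema reconstructs a simplified
piecewise-linear version of the waveform.

Conventions
-----------
* Sample indices are 0-based within an epoch.
* Extremum kinds alternate strictly between MIN and MAX at every level.
* Plateau runs of equal samples contribute a single representative extremum,
  the first sample of the run (sampled data has non-isolated extrema; the
  first-of-run rule keeps the output deterministic and alternating).
* ``preserve_endpoints=True`` (default) keeps the final extremal point across
  reduction passes.  The literal variant additionally discards the last point
  on every pass; it never converges to a non-trivial fixed point and exists
  only for fidelity to the published index-set definition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Kind",
    "Signal",
    "ExtremalPoint",
    "HalfwaveLevel",
    "find_extrema",
    "reduce_once",
    "reduce_to_level",
    "reduce_complete",
    "to_piecewise",
]


class Kind(enum.IntEnum):
    """Extremum kind; values chosen so that alternation means sign flips."""

    MIN = -1
    MAX = 1


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled real-valued series.

    Parameters
    ----------
    samples : array-like of float
        The sample values (arbitrary units, e.g. µV).  Length must be >= 2.
    fs : float
        Sampling rate in Hz, > 0.  Default 250.
    t0 : int
        Start offset in samples of this slice within a longer recording.
    """

    samples: np.ndarray
    fs: float = 250.0
    t0: int = 0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("Signal needs a 1-D array of at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Signal samples must all be finite")
        if not self.fs > 0:
            raise ValueError(f"Sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class ExtremalPoint:
    index: int
    value: float
    kind: Kind


@dataclass(frozen=True)
class HalfwaveLevel:
    """Ordered alternating extremal points at reduction level ``level``.

    ``indices`` are sample positions (strictly increasing), ``values`` the
    signal values there, ``kinds`` +1 for maxima and -1 for minima, strictly
    alternating.  ``complete`` is True when a further reduction pass is known
    to leave the points unchanged.
    """

    indices: np.ndarray
    values: np.ndarray
    kinds: np.ndarray
    level: int = 1
    complete: bool = False

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        val = np.asarray(self.values, dtype=float)
        knd = np.asarray(self.kinds, dtype=np.int8)
        if not (idx.size == val.size == knd.size):
            raise ValueError("indices, values and kinds must have equal length")
        if idx.size >= 2:
            if np.any(np.diff(idx) <= 0):
                raise ValueError("extremal indices must be strictly increasing")
            if np.any(knd[:-1] + knd[1:] != 0):
                raise ValueError("extremum kinds must alternate MIN/MAX")
        if self.level < 1:
            raise ValueError("reduction level must be >= 1")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "values", val)
        object.__setattr__(self, "kinds", knd)

    def __len__(self) -> int:
        return self.indices.size

    @property
    def points(self) -> list[ExtremalPoint]:
        return [
            ExtremalPoint(int(i), float(v), Kind(int(k)))
            for i, v, k in zip(self.indices, self.values, self.kinds)
        ]

    def __iter__(self) -> Iterator[ExtremalPoint]:
        return iter(self.points)


def _as_signal(signal: Signal | Sequence[float] | np.ndarray) -> Signal:
    if isinstance(signal, Signal):
        return signal
    return Signal(np.asarray(signal, dtype=float))


def find_extrema(
    signal: Signal | Sequence[float] | np.ndarray,
    include_endpoints: bool = True,
) -> HalfwaveLevel:
    """Level-1 Halfwave: the alternating sequence of local extrema.

    Interior extrema are samples strictly greater (maxima) or strictly smaller
    (minima) than the nearest differing neighbours on both sides; a plateau run
    of equal samples is represented by its first sample.  With
    ``include_endpoints`` (default) the first and last samples are appended
    with kinds chosen to preserve alternation, so the piecewise-linear
    reconstruction spans the whole epoch.

    A constant signal with ``include_endpoints=False`` yields an empty level.
    """
    sig = _as_signal(signal)
    x = sig.samples
    n = x.size

    # Compress plateau runs to their first sample.
    change = np.empty(n, dtype=bool)
    change[0] = True
    np.not_equal(x[1:], x[:-1], out=change[1:])
    run_starts = np.flatnonzero(change)
    rv = x[run_starts]

    if rv.size < 2:  # constant signal
        if not include_endpoints:
            return HalfwaveLevel(
                np.empty(0, np.int64), np.empty(0, float), np.empty(0, np.int8)
            )
        return HalfwaveLevel(
            np.array([0, n - 1], np.int64),
            np.array([x[0], x[-1]], float),
            np.array([Kind.MIN, Kind.MAX], np.int8),
        )

    s = np.sign(np.diff(rv))  # nonzero by construction
    turn = s[1:] != s[:-1]
    int_pos = np.flatnonzero(turn) + 1  # positions into run_starts
    int_idx = run_starts[int_pos]
    int_kind = np.where(s[int_pos - 1] > 0, np.int8(Kind.MAX), np.int8(Kind.MIN))

    if not include_endpoints:
        return HalfwaveLevel(int_idx, x[int_idx], int_kind)

    if int_idx.size:
        first_kind = -int_kind[0]
        last_kind = -int_kind[-1]
    else:
        # monotone: rising -> MIN ... MAX, falling -> MAX ... MIN
        first_kind = np.int8(Kind.MIN if s[0] > 0 else Kind.MAX)
        last_kind = -first_kind
    indices = np.concatenate(([0], int_idx, [n - 1]))
    kinds = np.concatenate(([first_kind], int_kind, [last_kind])).astype(np.int8)
    return HalfwaveLevel(indices.astype(np.int64), x[indices], kinds)


def _trivial_segment_set(deltas: np.ndarray, preserve_endpoints: bool) -> list[int]:
    """Indices i of segments (x_i, x_{i+1}) to delete in one pass.

    Greedy left-to-right scan over interior i in [1, n-2] admitting i when
    |Δi| <= |Δ(i+1)| and |Δi| <= |Δ(i-1)| and i-1 was not admitted; the skip
    guarantees i in D implies i-1, i+1 not in D even under ties.  When
    ``preserve_endpoints`` is False the literal trailing index n joins D.
    """
    n = deltas.size  # = point count - 1
    a = np.abs(deltas)
    admitted: list[int] = []
    prev = -2
    for i in range(1, n - 1):
        if i - 1 == prev:
            continue
        if a[i] <= a[i + 1] and a[i] <= a[i - 1]:
            admitted.append(i)
            prev = i
    if not preserve_endpoints:
        admitted.append(n)
    return admitted


def reduce_once(
    level: HalfwaveLevel, preserve_endpoints: bool = True
) -> HalfwaveLevel:
    """One Halfwave reduction pass: delete all trivial half-wave segments.

    Returns the subsequence ``{x_i : i not in D and i-1 not in D}`` where D is
    the trivial-segment index set computed from the successive differences
    Δi = y[i+1] - y[i].  Fewer than 2 points is a fixed point and is returned
    unchanged (level incremented, marked complete).
    """
    m = len(level)
    if m < 2:
        return replace(level, level=level.level + 1, complete=True)

    deltas = np.diff(level.values)
    d_set = _trivial_segment_set(deltas, preserve_endpoints)
    if not d_set:
        return replace(level, level=level.level + 1, complete=True)

    drop = np.zeros(m, dtype=bool)
    for i in d_set:
        drop[i] = True
        if i + 1 < m:
            drop[i + 1] = True
    keep = ~drop
    return HalfwaveLevel(
        level.indices[keep],
        level.values[keep],
        level.kinds[keep],
        level=level.level + 1,
        complete=False,
    )


def reduce_to_level(
    signal: Signal | Sequence[float] | np.ndarray,
    k: int = 2,
    include_endpoints: bool = True,
    preserve_endpoints: bool = True,
) -> HalfwaveLevel:
    """Level-k Halfwave: extrema extraction followed by k-1 reduction passes.

    The downstream feature pipeline uses k=2: deeper levels oversimplify
    low-amplitude sleep EEG to the point where epochs keep a single extremum.
    """
    if k < 1:
        raise ValueError(f"reduction level must be >= 1, got {k}")
    lvl = find_extrema(signal, include_endpoints=include_endpoints)
    for _ in range(k - 1):
        lvl = reduce_once(lvl, preserve_endpoints=preserve_endpoints)
        if lvl.complete:  # fixed point reached before level k
            break
    return lvl


def reduce_complete(
    signal: Signal | Sequence[float] | np.ndarray,
    include_endpoints: bool = True,
    preserve_endpoints: bool = True,
) -> HalfwaveLevel:
    """The complete Halfwave: iterate reduction passes to the fixed point.

    Terminates in at most the initial point count of passes, since the point
    count is non-increasing and strictly decreases on every non-fixed pass.
    """
    lvl = find_extrema(signal, include_endpoints=include_endpoints)
    for _ in range(len(lvl) + 1):
        nxt = reduce_once(lvl, preserve_endpoints=preserve_endpoints)
        if len(nxt) == len(lvl):
            return replace(nxt, complete=True)
        lvl = nxt
    raise AssertionError("Halfwave reduction failed to converge")  # pragma: no cover


def to_piecewise(level: HalfwaveLevel) -> np.ndarray:
    """Knots ``(index, value)`` of the piecewise-linear reduced signal.

    Linear interpolation between consecutive knots reconstructs the reduced
    waveform; an empty level yields an empty (0, 2) array.
    """
    return np.column_stack((level.indices.astype(float), level.values))
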