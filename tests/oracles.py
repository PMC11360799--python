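"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's numpy implementations: plain Python
lists and explicit set semantics, so they can serve as an independent check
of the Halfwave reduction step.
"""

from __future__ import annotations


def brute_force_trivial_set(values, preserve_endpoints=True) -> set[int]:
    """The trivial-segment index set D from the successive differences.

    Interior i in [1, n-2] joins D when |Δi| <= |Δ(i+1)| and |Δi| <= |Δ(i-1)|
    and i-1 did not join (left-to-right, so D never holds adjacent indices
    even under ties).  Without endpoint preservation the trailing index n
    joins unconditionally.
    """
    y = [float(v) for v in values]
    n = len(y) - 1
    deltas = [y[i + 1] - y[i] for i in range(n)]
    D: set[int] = set()
    for i in range(1, n - 1):
        if (i - 1) in D:
            continue
        if abs(deltas[i]) <= abs(deltas[i + 1]) and abs(deltas[i]) <= abs(deltas[i - 1]):
            D.add(i)
    if not preserve_endpoints:
        D.add(n)
    return D


def brute_force_reduce_once(values, preserve_endpoints=True) -> list[int]:
    """Kept point positions: {i : i not in D and i-1 not in D}."""
    if len(values) < 2:
        return list(range(len(values)))
    D = brute_force_trivial_set(values, preserve_endpoints)
    return [i for i in range(len(values)) if i not in D and (i - 1) not in D]


def brute_force_extrema(samples) -> list[int]:
    """Interior strict extrema by exhaustive nearest-differing-neighbour scan.

    Returns sample indices; plateau runs are represented by their first
    sample, matching the documented convention.  Endpoints excluded.
    """
    x = [float(v) for v in samples]
    n = len(x)
    out = []
    for i in range(1, n - 1):
        if x[i] == x[i - 1]:
            continue  # not the first sample of its plateau run
        left = next((x[j] for j in range(i - 1, -1, -1) if x[j] != x[i]), None)
        right = next((x[j] for j in range(i + 1, n) if x[j] != x[i]), None)
        if left is None or right is None:
            continue
        if x[i] > left and x[i] > right:
            out.append(i)
        elif x[i] < left and x[i] < right:
            out.append(i)
    return out
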