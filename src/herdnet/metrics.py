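"""Dependent variables: the Gini index of herd wealth, and per-run tracking
of the largest patron-client network's size and duration.

Network size is the largest number of clients any single patron maintained
simultaneously during a run. Network duration is the longest consecutive
stretch of steps during which that run-maximal network was the reigning
largest network in the system; the reign counter resets whenever the
reigning network's identity changes or the network dissolves and re-forms.
"""
from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .model import World

__all__ = [
    "gini",
    "NetworkTracker",
    "record_network_state",
    "finalize_network_metrics",
]


def gini(wealths) -> float:
    """Population Gini index of a wealth vector.

    Computed as sum_ij |x_i - x_j| / (2 n^2 mean): 0 for perfect equality,
    (n-1)/n when one household owns everything (-> 1 as n grows). No sample
    correction is applied.

    Raises ``ValueError`` on empty or all-zero input, where the index is
    undefined.
    """
    x = np.asarray(wealths, dtype=float)
    if x.ndim != 1:
        raise ValueError("gini expects a 1-D wealth vector")
    if x.size == 0:
        raise ValueError("gini is undefined for an empty population")
    if np.any(x < 0):
        raise ValueError("wealths must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("gini is undefined when all wealths are zero")
    n = x.size
    xs = np.sort(x)
    # Equivalent to the mean-absolute-difference form, O(n log n).
    ranks = np.arange(1, n + 1)
    # clamp float round-off: the index is 0 for perfect equality
    return max(0.0, float(2.0 * (ranks * xs).sum() / (n * total) - (n + 1) / n))


class NetworkTracker:
    """Per-run bookkeeping for the largest patron-client network.

    A network is identified by (patron id, step at which this patron stint
    formed); dissolving and re-forming yields a new identity. Ties for the
    reigning largest network go to the earliest-formed stint, then the
    lowest patron id.
    """

    __slots__ = (
        "run_max_size",
        "run_max_key",
        "_current_key",
        "_current_len",
        "_best",
    )

    def __init__(self) -> None:
        self.run_max_size: int = 0
        self.run_max_key: tuple[int, int] | None = None
        self._current_key: tuple[int, int] | None = None
        self._current_len: int = 0
        self._best: dict[tuple[int, int], int] = {}

    def record(self, world: "World") -> None:
        """Record the end-of-step network state (call once per step)."""
        pat = np.flatnonzero(world.alive & (world.n_clients > 0))
        if pat.size == 0:
            self._current_key = None
            self._current_len = 0
            return
        sizes = world.n_clients[pat]
        size = int(sizes.max())
        cand = pat[sizes == size]
        if cand.size == 1:
            best = int(cand[0])
        else:
            formed = world.network_formed_step[cand]
            best = int(cand[np.lexsort((cand, formed))[0]])
        key = (best, int(world.network_formed_step[best]))

        if key == self._current_key:
            self._current_len += 1
        else:
            self._current_key = key
            self._current_len = 1
        prev = self._best.get(key, 0)
        if self._current_len > prev:
            self._best[key] = self._current_len

        if size > self.run_max_size:
            self.run_max_size = size
            self.run_max_key = key

    def finalize(self) -> tuple[int, int]:
        """Return (largest network size, its longest reign in steps)."""
        if self.run_max_key is None:
            return 0, 0
        return self.run_max_size, self._best.get(self.run_max_key, 0)


def record_network_state(world: "World", tracker: NetworkTracker) -> NetworkTracker:
    tracker.record(world)
    return tracker


def finalize_network_metrics(tracker: NetworkTracker) -> tuple[int, int]:
    return tracker.finalize()
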