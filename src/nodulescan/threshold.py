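"""Iterative two-cluster mean (Ridler–Calvard / ISODATA style) density threshold.

The slice's density threshold is the fixed point of the recurrence

    IT  <- mean of all pixels                       (initialisation)
    T   <- ( mean{I <= IT} + mean{I > IT} ) / 2     (new threshold)

repeated with ``IT <- T`` until ``|IT - T| <= tolerance``.  The default
tolerance of 0.9 intensity units is the value that gives the best lung
segmentations on 12-bit CT data.  The converged value separates the dark
lung fields and exterior air from the bright chest wall and is reused as
the base of the five-threshold candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np

from .core import CtSlice, InvalidInputError

__all__ = ["ThresholdState", "iterative_mean_threshold"]


@dataclass
class ThresholdState:
    """Result of the iterative mean-threshold recurrence.

    ``it`` is the previous threshold, ``t`` the new one; at convergence
    ``|it - t| <= tolerance``.  ``trace`` records every T produced, in
    order, so the iteration path itself can be checked.
    """

    it: float
    t: float
    n_iter: int
    converged: bool
    trace: List[float] = field(default_factory=list)

    @property
    def threshold(self) -> float:
        return self.t


def _two_cluster_mean(values: np.ndarray, it: float) -> float:
    """One update: mean of the two cluster means split at ``it``.

    Pixels equal to ``it`` belong to the lower cluster.  If a cluster is
    empty, its mean is replaced by ``it`` itself, which keeps the
    recurrence defined on constant-heavy images.
    """
    low = values[values <= it]
    high = values[values > it]
    m_low = low.mean() if low.size else it
    m_high = high.mean() if high.size else it
    return (m_low + m_high) / 2.0


def iterative_mean_threshold(
    slice_: CtSlice,
    tolerance: float = 0.9,
    max_iter: int = 100,
) -> ThresholdState:
    """Compute the slice's density threshold by iterated two-cluster means.

    Parameters
    ----------
    slice_
        Input CT slice; the recurrence runs on the raw pixel values.
    tolerance
        Convergence tolerance on ``|IT - T|`` in intensity units
        (default 0.9).
    max_iter
        Safety cap on iterations.  The recurrence converges on any real
        image; the cap guards pathological inputs and is reported via
        ``converged=False``.

    Returns
    -------
    ThresholdState
        The converged threshold ``t`` together with the iteration trace.
    """
    if tolerance <= 0:
        raise InvalidInputError(f"tolerance must be > 0, got {tolerance}")
    if max_iter < 1:
        raise InvalidInputError(f"max_iter must be >= 1, got {max_iter}")
    values = slice_.pixels.ravel()
    if values.size == 0:
        raise InvalidInputError("empty slice")

    it = float(values.mean())
    trace: List[float] = []
    converged = False
    t = it
    for n in range(1, max_iter + 1):
        t = float(_two_cluster_mean(values, it))
        trace.append(t)
        if abs(it - t) <= tolerance:
            converged = True
            break
        it = t
    return ThresholdState(it=it, t=t, n_iter=len(trace), converged=converged, trace=trace)
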