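"""Density-modification masks.

Two masks drive the phase refinements:

* the (m_rho, s_rho) pair derived from rho: positive density keeps its value
  (m=1, s=1); slightly negative density (0 >= rho > -t*sigma) is converted to
  zero (m=0, s=-1) because the slightly negative zones cannot host atomic
  CORE regions; very negative density (rho <= -t*sigma, <1% of the cell at
  t=2.5) keeps its magnitude with restored sign (m=1, s=-1);

* the binary m_delta mask on delta_M: 1 where delta_M clears the threshold
  t1*sigma(delta_M), 0 otherwise — the mask of the tangent-formula recycle.

The sigma entering the rho thresholds is ALWAYS the all-reflection Parseval
value, even when rho was synthesized from the strong subset; this phase-free
convention is what gives ~0.62% very-negative voxels at random phases in the
slow mode and ~0.17% in the fast mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .maps import DensityMap

__all__ = ["MaskSet", "compute_masks", "compute_m_delta"]


@dataclass
class MaskSet:
    """Per-voxel mask m in {0,1}, sign s in {-1,1}, and their product."""

    m: np.ndarray
    s: np.ndarray
    t: float

    @property
    def combined(self) -> np.ndarray:
        return self.m * self.s

    @property
    def fractions(self) -> Tuple[float, float, float]:
        """(positive, zero-class, very-negative) voxel percentages; sum 100."""
        n = self.m.size
        pos = float(np.count_nonzero((self.m == 1) & (self.s == 1))) / n * 100.0
        zero = float(np.count_nonzero(self.m == 0)) / n * 100.0
        neg = float(np.count_nonzero((self.m == 1) & (self.s == -1))) / n * 100.0
        return pos, zero, neg

    @property
    def mean_m(self) -> float:
        return float(self.m.mean())


def compute_masks(rho: DensityMap, sigma_rho: float, t: float = 2.5) -> MaskSet:
    """Classify every voxel of rho against the thresholds 0 and -t*sigma.

    ``sigma_rho`` must be the phase-independent all-reflection Parseval sigma.
    Boundary ties: rho exactly 0 is in the zero class; rho exactly -t*sigma
    is very negative.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    if sigma_rho <= 0:
        raise ValueError("sigma_rho must be positive")
    v = rho.values
    m = np.ones(v.shape, dtype=np.int8)
    s = np.ones(v.shape, dtype=np.int8)
    snz = (v <= 0) & (v > -t * sigma_rho)
    very_neg = v <= -t * sigma_rho
    m[snz] = 0
    s[snz | very_neg] = -1
    return MaskSet(m=m, s=s, t=t)


def compute_m_delta(delta: DensityMap, t1: float = 2.5) -> np.ndarray:
    """Binary mask: 1 where delta_M >= t1 * sigma(delta_M) (grid sigma)."""
    if delta.values.max() == delta.values.min():
        raise ValueError("constant map: m_delta undefined")
    sigma = delta.sigma
    return (delta.values >= t1 * sigma).astype(np.int8)
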