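"""Normalized residuals and per-iteration diagnostics of the phase refinement.

All integrals are evaluated as V * (voxel mean) and divided by the
normalization constant SRO2 = integral of rho^2 over the cell (computed from
the |E| values of the current working subset via Parseval, hence phase
independent), making every reported quantity a dimensionless, volume-free
ratio.  The key identity R_delta = P + Q - 2*S_delta holds by construction
on every iteration.

R_delta does not converge to zero at the true phases: the unmodelled sea of
weak cross-vector (B-type) peaks leaves a floor of G2NORM * <m_rho>, with
G2NORM = 1.12 the normalized mean square of that background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Tuple

import numpy as np

from .crystal import ReflectionSet
from .maps import DensityMap
from .masks import MaskSet

__all__ = [
    "G2NORM",
    "IterationDiagnostics",
    "normalization_constants",
    "residual_integrals",
    "cc_masked",
    "r_delta_floor",
    "k_delta_p",
    "r_rho",
]

#: Normalized <g^2> of the B-peak background entering the R_delta floor.
G2NORM = 1.12

#: Theoretical random-phase value of the P integral (half of rho^2 is positive).
P0 = 0.50


@dataclass
class IterationDiagnostics:
    """One row of the refinement log (Table-style normalized integrals)."""

    iteration: int = 0
    minus2S_delta: float = np.nan
    P: float = np.nan
    Q: float = np.nan
    R_delta: float = np.nan
    k_delta_p: float = np.nan
    zero_pct: float = np.nan
    neg_pct: float = np.nan
    CC_rho_prime: float = np.nan
    CC_rho_dprime: float = np.nan
    SRO2: float = np.nan
    SDEL: float = np.nan
    R_rho: float = np.nan
    S_rho: float = np.nan

    @property
    def S_delta(self) -> float:
        return -0.5 * self.minus2S_delta

    def as_row(self) -> dict:
        return {
            "iteration": self.iteration,
            "minus2S_delta": self.minus2S_delta,
            "P": self.P,
            "Q": self.Q,
            "R_delta": self.R_delta,
            "k_delta_p": self.k_delta_p,
            "zero_pct": self.zero_pct,
            "neg_pct": self.neg_pct,
            "CC_rho_prime": self.CC_rho_prime,
            "CC_rho_dprime": self.CC_rho_dprime,
        }


def normalization_constants(
    refl: ReflectionSet,
    c: float,
    mode: Literal["slow", "fast"] = "slow",
) -> Tuple[float, float]:
    """(SRO2, SDEL) for the current mode.

    SRO2 = integral of rho^2 dV over the mode's working subset (all
    reflections in slow mode, |E| >= E_lim in fast mode), phase independent
    via Parseval.  SDEL = integral of delta_M^2 dV / SRO2
    = c^2 * sum_all(|E|-<|E|>)^2 / sum_working |E|^2; with the default c and
    slow mode this equals c identically.
    """
    sel = refl.strong_flags if mode == "fast" else slice(None)
    sum_work = float(np.sum(refl.E[sel] ** 2))
    if sum_work <= 0:
        raise ValueError("empty working set")
    V = refl.cell.volume
    sro2 = 2.0 * sum_work / V
    dE2 = float(np.sum((refl.E - refl.E_mean) ** 2))
    sdel = c * c * 2.0 * dE2 / V / sro2
    return sro2, sdel


def residual_integrals(
    delta: DensityMap,
    rho: DensityMap,
    masks: MaskSet,
    sro2: float,
    iteration: int = 0,
) -> IterationDiagnostics:
    """S_delta, P, Q, R_delta and CC_rho' for one iteration.

    S_delta = (1/SRO2) int delta_M * m * s * rho dV
    P       = (1/SRO2) int rho^2 * m dV
    Q       = (1/SRO2) int delta_M^2 * m dV
    R_delta = P + Q - 2 S_delta;   CC_rho' = S_delta / sqrt(P*Q).
    """
    if delta.dims != rho.dims:
        raise ValueError("delta and rho grids differ")
    V = rho.cell.volume
    m = masks.m
    ms = masks.combined
    S = V * float(np.mean(delta.values * ms * rho.values)) / sro2
    P = V * float(np.mean(rho.values**2 * m)) / sro2
    Q = V * float(np.mean(delta.values**2 * m)) / sro2
    cc = S / np.sqrt(P * Q) if P * Q > 0 else 0.0
    pos, zero, neg = masks.fractions
    return IterationDiagnostics(
        iteration=iteration,
        minus2S_delta=-2.0 * S,
        P=P,
        Q=Q,
        R_delta=P + Q - 2.0 * S,
        k_delta_p=k_delta_p(P, -2.0 * S),
        zero_pct=zero,
        neg_pct=neg,
        CC_rho_prime=cc,
        SRO2=sro2,
    )


def cc_masked(
    modified: DensityMap, rho: DensityMap, s: np.ndarray, support: np.ndarray
) -> float:
    """Correlation of a modified map with |rho| = rho*s on a voxel support.

    Used for CC_rho'': ``modified`` is the ipp output rho'' and ``support``
    its preserved-voxel indicator.
    """
    a = modified.values
    num = float(np.mean(a * rho.values * s))
    den = float(np.mean(rho.values**2 * support)) * float(np.mean(a * a))
    return num / np.sqrt(den) if den > 0 else 0.0


def r_delta_floor(mean_m: float) -> float:
    """Theoretical minimum of R_delta at the true phases: G2NORM * <m_rho>."""
    if not 0.0 <= mean_m <= 1.0:
        raise ValueError("mean_m must be in [0, 1]")
    return G2NORM * mean_m


def k_delta_p(P: float, minus2S: float) -> float:
    """Empirical slope k = (P - P0) / (2*S_delta) with the theoretical P0 = 0.50.

    Undefined (NaN) when S_delta = 0, e.g. on the random-phase first iteration.
    """
    two_S = -minus2S
    if two_S == 0:
        return np.nan
    return (P - P0) / two_S


def r_rho(
    rho_chi: DensityMap,
    rho_phi: DensityMap,
    s: np.ndarray,
    sro2: float,
) -> Tuple[float, float]:
    """(R_rho, S_rho): agreement of rho(chi) with |rho(Phi)| = rho(Phi)*s.

    R_rho = (1/SRO2) int [rho(chi) - rho(Phi)*s]^2 dV vanishes when chi is
    the phase set of the full-set transform of |rho(Phi)| (synthesis/analysis
    closure); S_rho is its phase-dependent cross term.
    """
    if rho_chi.dims != rho_phi.dims:
        raise ValueError("grids differ")
    V = rho_phi.cell.volume
    diff = rho_chi.values - rho_phi.values * s
    R = V * float(np.mean(diff * diff)) / sro2
    S = V * float(np.mean(rho_chi.values * rho_phi.values * s)) / sro2
    return R, S
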