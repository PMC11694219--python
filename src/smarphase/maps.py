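"""Fourier syntheses, forward transforms, map statistics and the CORE radius.

Conventions
-----------
The density synthesis is

    rho(r) = (1/V) * sum_{+-h} |E_h| cos(2 pi h.r - phi_h),

evaluated on a periodic grid by placing the Hermitian coefficient pair
(F_h, conj(F_h)) on the reciprocal grid and applying an (unnormalized)
forward FFT, so a voxel at index x holds the density at fractional
coordinate x/N.  The matching analysis step is

    F_h = (V / N_vox) * sum_voxels map(x) * exp(+2 pi i h.x/N),

which makes synthesize/forward_transform an exact round trip on
band-limited data.  Masked (non-band-limited) maps are transformed as-is on
the fixed grid: aliasing is part of the discrete algorithm's contract.

The delta_M synthesis uses difference coefficients c*(|E| - <|E|>) with the
phases alpha of |rho|; the scale constant c = sum|E|^2 / sum(|E|-<|E|>)^2
makes the rho-component of delta_M unit-scaled.  Every phase update and every
ratio diagnostic downstream is invariant under rescaling c.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .crystal import ReflectionSet, UnitCell

__all__ = [
    "DensityMap",
    "choose_grid",
    "synthesize_rho",
    "synthesize_delta_m",
    "forward_transform",
    "map_sigma",
    "compute_c",
    "core_radius",
]


@dataclass
class DensityMap:
    """Real-valued periodic 3D grid over the unit cell (mean zero: no F000)."""

    values: np.ndarray
    cell: UnitCell
    delta_grid: float = 0.0  # nominal voxel edge in angstroms

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("map values must be a 3D array")

    @property
    def dims(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def n_vox(self) -> int:
        return int(np.prod(self.values.shape))

    @property
    def sigma(self) -> float:
        """Grid standard deviation (maps are mean-zero, so this is the RMS)."""
        return float(np.sqrt(np.mean(self.values**2)))

    def like(self, values: np.ndarray) -> "DensityMap":
        return replace(self, values=values)


def _smooth235(n: int) -> int:
    """Smallest 5-smooth (FFT-friendly) integer >= n."""
    while True:
        m = n
        for p in (2, 3, 5):
            while m % p == 0:
                m //= p
        if m == 1:
            return n
        n += 1


def choose_grid(refl: ReflectionSet, delta_grid: Optional[float] = None) -> Tuple[int, int, int]:
    """Grid dims: per axis the smallest FFT-friendly N >= max(edge/delta, 2*h_max+2).

    The default voxel edge is d_min/3, reproducing ~0.33 A voxels at atomic
    resolution, which the 26-neighbour peak criterion presumes.
    """
    if delta_grid is None:
        delta_grid = refl.d_min / 3.0
    edges = np.array([refl.cell.a, refl.cell.b, refl.cell.c])
    hmax = refl.h_max
    dims = []
    for edge, hm in zip(edges, hmax):
        n = max(int(np.ceil(edge / delta_grid)), 2 * int(hm) + 2)
        dims.append(_smooth235(n))
    return tuple(dims)


def _coefficient_grid(
    hkl: np.ndarray, coeff: np.ndarray, dims: Sequence[int]
) -> np.ndarray:
    """Place half-set coefficients plus Friedel mates on the reciprocal grid."""
    hmax = np.abs(hkl).max(axis=0)
    if np.any(2 * hmax + 1 > np.asarray(dims)):
        raise ValueError("grid dims below Nyquist range of the reflection set")
    G = np.zeros(tuple(dims), dtype=complex)
    idx = tuple((hkl % np.asarray(dims)).T)
    idx_neg = tuple(((-hkl) % np.asarray(dims)).T)
    G[idx] = coeff
    G[idx_neg] = np.conj(coeff)
    return G


def _synthesize(
    hkl: np.ndarray,
    coeff: np.ndarray,
    cell: UnitCell,
    dims: Sequence[int],
    delta_grid: float,
) -> DensityMap:
    G = _coefficient_grid(hkl, coeff, dims)
    values = np.fft.fftn(G).real / cell.volume
    return DensityMap(values=values, cell=cell, delta_grid=delta_grid)


def synthesize_rho(
    refl: ReflectionSet,
    phases: Optional[np.ndarray] = None,
    subset: Literal["all", "strong"] = "all",
    dims: Optional[Sequence[int]] = None,
    delta_grid: Optional[float] = None,
) -> DensityMap:
    """rho(r) = (1/V) sum_{+-h} |E_h| cos(2 pi h.r - phi_h) on the grid.

    ``subset='strong'`` restricts the Fourier terms to |E| >= E_lim (the fast
    convergence mode); the grid is always chosen from the full set so that
    slow- and fast-mode maps share voxels.
    """
    phi = refl.phi if phases is None else np.asarray(phases, dtype=float)
    if phi is None:
        raise ValueError("phases are required (none stored on the reflection set)")
    if dims is None:
        dims = choose_grid(refl, delta_grid)
    if delta_grid is None:
        delta_grid = refl.d_min / 3.0
    if subset == "strong":
        sel = refl.strong_flags
        if not sel.any():
            raise ValueError("no strong reflections (|E| >= E_lim) in the set")
    elif subset == "all":
        sel = slice(None)
    else:
        raise ValueError(f"unknown subset {subset!r}")
    coeff = refl.E[sel] * np.exp(1j * phi[sel])
    return _synthesize(refl.hkl[sel], coeff, refl.cell, dims, delta_grid)


def compute_c(refl: ReflectionSet) -> float:
    """Scale constant of the delta_M synthesis: c = sum|E|^2 / sum(|E|-<|E|>)^2.

    Makes the rho-component of delta_M unit-scaled (the A peaks of delta_M
    match the rho peaks) and makes SDEL identically equal to c.  For acentric
    Wilson data c -> 1/(1 - pi/4) ~ 4.66.
    """
    if len(refl) < 2:
        raise ValueError("need at least 2 reflections")
    dE = refl.E - refl.E_mean
    denom = float(np.sum(dE * dE))
    if denom <= 0:
        raise ValueError("all |E| equal: c undefined")
    return float(np.sum(refl.E**2)) / denom


def synthesize_delta_m(
    refl: ReflectionSet,
    alpha: np.ndarray,
    c: Optional[float] = None,
    dims: Optional[Sequence[int]] = None,
    delta_grid: Optional[float] = None,
) -> DensityMap:
    """delta_M(r) = (c/V) sum_{+-h} (|E_h| - <|E|>) cos(2 pi h.r - alpha_h).

    Always uses the full reflection set, whatever the rho subset of the
    current mode.  A reflection with |E| = <|E|> contributes nothing.
    """
    alpha = np.asarray(alpha, dtype=float)
    if len(alpha) != len(refl):
        raise ValueError("alpha must cover every reflection of the set")
    if c is None:
        c = compute_c(refl)
    if dims is None:
        dims = choose_grid(refl, delta_grid)
    if delta_grid is None:
        delta_grid = refl.d_min / 3.0
    coeff = c * (refl.E - refl.E_mean) * np.exp(1j * alpha)
    return _synthesize(refl.hkl, coeff, refl.cell, dims, delta_grid)


def forward_transform(
    dmap: DensityMap, refl: ReflectionSet
) -> Tuple[np.ndarray, np.ndarray]:
    """Moduli and phases of the map's Fourier coefficients at every reflection.

    Inverse of the synthesis scaling: a synthesize -> forward round trip on
    band-limited data returns (|E|, phi) exactly.
    """
    dims = np.asarray(dmap.dims)
    if np.any(2 * refl.h_max + 1 > dims):
        raise ValueError("reflection indices outside the grid's Nyquist range")
    F = dmap.cell.volume * np.fft.ifftn(dmap.values)
    idx = tuple((refl.hkl % dims).T)
    coeff = F[idx]
    return np.abs(coeff), np.angle(coeff)


def map_sigma(dmap_or_refl, subset: Literal["all", "strong"] = "all") -> float:
    """Phase-independent sigma of a rho synthesis, or grid sigma of a map.

    Called with a ReflectionSet, returns the Parseval value
    sigma = sqrt(2 * sum_half |E|^2) / V (exact, phase independent, and by
    contract always over the requested subset -- mask thresholds use 'all'
    even in fast mode).  Called with a DensityMap, returns the grid standard
    deviation (used for delta_M).
    """
    if isinstance(dmap_or_refl, DensityMap):
        return dmap_or_refl.sigma
    refl: ReflectionSet = dmap_or_refl
    sel = refl.strong_flags if subset == "strong" else slice(None)
    return float(np.sqrt(2.0 * np.sum(refl.E[sel] ** 2))) / refl.cell.volume


def core_radius(d_min: float) -> float:
    """Radius of the positive CORE of a series-terminated point-atom peak.

    The spherical termination kernel (sin u - u cos u)/u^3 first vanishes at
    u* ~ 4.4934 (first positive root of tan u = u); the CORE boundary lies at
    r = u*/(2 pi) * d_min ~ 0.72 d_min.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    u_star = brentq(lambda u: np.sin(u) - u * np.cos(u), np.pi, 1.5 * np.pi)
    return u_star / (2.0 * np.pi) * d_min
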