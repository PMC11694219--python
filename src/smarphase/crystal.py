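"""Synthetic equal-atom crystal structures and exact structure factors.

Structures live in P1: a triclinic unit cell plus a list of fractional atom
coordinates.  Structure factors are evaluated by direct summation over atoms
(F_h = sum_j exp(2*pi*i h.r_j) for point atoms), which makes this module the
oracle for every FFT-based transform elsewhere in the package.  Amplitudes are
normalized to E-values by |E| = |F|/sqrt(N), the equal-atom point-atom case in
which the normalized scattering factor is 1/sqrt(N).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "UnitCell",
    "CrystalStructure",
    "ReflectionSet",
    "generate_random_structure",
    "direct_structure_factors",
    "normalize_to_E",
]


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell; lengths in angstroms, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0 or not np.isfinite(self.volume):
            raise ValueError("degenerate cell (non-positive volume)")

    @property
    def volume(self) -> float:
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return -1.0
        return self.a * self.b * self.c * float(np.sqrt(arg))

    @property
    def orthogonalization(self) -> np.ndarray:
        """3x3 matrix mapping fractional to cartesian coordinates (PDB convention)."""
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        v = self.volume
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, v / (self.a * self.b * sg)],
            ]
        )

    @property
    def reciprocal_metric(self) -> np.ndarray:
        """Metric tensor of the reciprocal basis: 1/d^2 = h . G* . h."""
        g = self.orthogonalization.T @ self.orthogonalization
        return np.linalg.inv(g)

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        inv_d2 = np.einsum("ij,jk,ik->i", hkl, self.reciprocal_metric, hkl)
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(inv_d2)

    def min_image_distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Minimum periodic (wrap-around) cartesian distance between fractional points.

        Checks all 27 neighbour images, which is exact for separations below
        half the shortest cell height — always the case for packing floors of
        a few angstroms.
        """
        dx = np.atleast_2d(x) - np.atleast_2d(y)
        dx -= np.round(dx)
        shifts = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1])).T.reshape(-1, 3)
        cart = (dx[:, None, :] + shifts[None, :, :]) @ self.orthogonalization.T
        return np.sqrt((cart**2).sum(axis=-1)).min(axis=1)


@dataclass(frozen=True)
class CrystalStructure:
    """N equal point atoms at fractional positions in a P1 cell."""

    cell: UnitCell
    atoms: np.ndarray  # (N, 3) fractional, wrapped to [0, 1)
    label: str = ""

    def __post_init__(self) -> None:
        atoms = np.atleast_2d(np.asarray(self.atoms, dtype=float))
        if atoms.shape[1] != 3 or atoms.shape[0] < 1:
            raise ValueError("atoms must be a non-empty (N, 3) array")
        object.__setattr__(self, "atoms", np.mod(atoms, 1.0))

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    def translated(self, shift) -> "CrystalStructure":
        return replace(self, atoms=np.mod(self.atoms + np.asarray(shift), 1.0))

    def min_distance(self) -> float:
        """Smallest periodic inter-atom distance (inf for a single atom)."""
        n = self.n_atoms
        if n < 2:
            return np.inf
        i, j = np.triu_indices(n, k=1)
        return float(self.cell.min_image_distance(self.atoms[i], self.atoms[j]).min())


@dataclass
class ReflectionSet:
    """Unique half-set of reflections with amplitudes and optional phases.

    Friedel mates are implied (|E_-h| = |E_h|, phi_-h = -phi_h); (0,0,0) is
    never stored, so every synthesized map has zero mean.  Full-sphere sums
    are twice the stored half-set sums.
    """

    hkl: np.ndarray  # (n, 3) int
    E: np.ndarray  # (n,) nonnegative amplitudes
    cell: UnitCell
    d_min: float
    phi: Optional[np.ndarray] = None  # (n,) radians
    E_lim: float = 1.0
    d: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int)
        self.E = np.asarray(self.E, dtype=float)
        if self.hkl.ndim != 2 or self.hkl.shape[1] != 3:
            raise ValueError("hkl must be (n, 3)")
        if len(self.E) != len(self.hkl):
            raise ValueError("E and hkl length mismatch")
        if np.any(np.all(self.hkl == 0, axis=1)):
            raise ValueError("(0,0,0) must not be stored")
        if self.phi is not None:
            self.phi = np.asarray(self.phi, dtype=float)
            if len(self.phi) != len(self.hkl):
                raise ValueError("phi length mismatch")
        if self.d is None:
            self.d = self.cell.d_spacing(self.hkl)

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def E_mean(self) -> float:
        """<|E|> over the working set (half-set mean equals full-sphere mean)."""
        return float(self.E.mean())

    @property
    def strong_flags(self) -> np.ndarray:
        return self.E >= self.E_lim

    @property
    def h_max(self) -> np.ndarray:
        """Largest |index| per axis, used for Nyquist-sufficient grids."""
        return np.abs(self.hkl).max(axis=0)

    def with_phases(self, phi: np.ndarray) -> "ReflectionSet":
        return ReflectionSet(
            hkl=self.hkl, E=self.E, cell=self.cell, d_min=self.d_min,
            phi=np.asarray(phi, dtype=float), E_lim=self.E_lim, d=self.d,
        )


def canonical_half(hkl: np.ndarray) -> np.ndarray:
    """True for indices in the canonical half-sphere (h>0, or h=0,k>0, or h=k=0,l>0)."""
    h, k, l = hkl[:, 0], hkl[:, 1], hkl[:, 2]
    return (h > 0) | ((h == 0) & (k > 0)) | ((h == 0) & (k == 0) & (l > 0))


def generate_random_structure(
    n_atoms: int,
    cell: UnitCell,
    min_dist: float = 1.2,
    seed: int = 0,
    label: str = "",
    max_attempts_per_atom: int = 2000,
) -> CrystalStructure:
    """Place ``n_atoms`` uniformly at random with a periodic hard-core floor.

    Rejection sampling with the wrap-around metric; deterministic for a fixed
    seed.  Raises ``RuntimeError`` when packing is infeasible within the
    attempt budget.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if min_dist < 0:
        raise ValueError("min_dist must be >= 0")
    sphere = 4.0 / 3.0 * np.pi * min_dist**3
    if n_atoms * sphere > 0.55 * cell.volume:
        raise RuntimeError(
            f"packing infeasible: {n_atoms} spheres of radius {min_dist} A "
            f"exceed half the cell volume {cell.volume:.1f} A^3"
        )
    rng = np.random.default_rng(seed)
    placed = np.empty((0, 3))
    for _ in range(n_atoms):
        for attempt in range(max_attempts_per_atom):
            trial = rng.random(3)
            if len(placed) == 0:
                break
            dists = cell.min_image_distance(
                np.broadcast_to(trial, placed.shape), placed
            )
            if dists.min() >= min_dist:
                break
        else:
            raise RuntimeError(
                f"packing infeasible: could not place atom {len(placed) + 1} "
                f"of {n_atoms} after {max_attempts_per_atom} attempts"
            )
        placed = np.vstack([placed, trial])
    return CrystalStructure(cell=cell, atoms=placed, label=label or f"random-{n_atoms}")


def direct_structure_factors(
    structure: CrystalStructure,
    d_min: float,
    b_iso: float = 0.0,
) -> ReflectionSet:
    """Exact point-atom structure factors for the complete half-sphere to d_min.

    F_h = sum_j exp(2*pi*i h.r_j), evaluated by direct summation.  With
    ``b_iso`` > 0 a Gaussian (Debye-Waller) falloff exp(-B/(4 d^2)) is applied
    for map-visualisation realism; the default is sharp point atoms.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    cell = structure.cell
    # |h_i| <= |a_i|/d_min bounds the index range on every axis.
    lengths = np.array([cell.a, cell.b, cell.c])
    hmax = np.floor(lengths / d_min).astype(int)
    rng_h = [np.arange(-m, m + 1) for m in hmax]
    grid = np.array(np.meshgrid(*rng_h, indexing="ij")).reshape(3, -1).T
    grid = grid[~np.all(grid == 0, axis=1)]
    grid = grid[canonical_half(grid)]
    d = cell.d_spacing(grid)
    keep = d >= d_min
    hkl, d = grid[keep], d[keep]
    if len(hkl) == 0:
        raise ValueError("no reflections: d_min exceeds every lattice spacing")
    phase_matrix = 2.0 * np.pi * (hkl @ structure.atoms.T)
    F = np.exp(1j * phase_matrix).sum(axis=1)
    amp = np.abs(F)
    if b_iso > 0.0:
        amp = amp * np.exp(-b_iso / (4.0 * d * d))
    return ReflectionSet(
        hkl=hkl, E=amp, cell=cell, d_min=d_min, phi=np.angle(F), d=d
    )


def normalize_to_E(raw: ReflectionSet, n_atoms: int, E_lim: float = 1.0) -> ReflectionSet:
    """Normalize point-atom amplitudes to E-values: |E| = |F|/sqrt(N).

    For randomly placed equal atoms this yields Wilson statistics
    (<|E|^2> -> 1, acentric <|E|> -> sqrt(pi)/2) up to sampling noise.
    """
    if n_atoms <= 0:
        raise ValueError("n_atoms must be positive")
    if not np.all(np.isfinite(raw.E)):
        raise ValueError("non-finite amplitudes")
    return ReflectionSet(
        hkl=raw.hkl,
        E=raw.E / np.sqrt(n_atoms),
        cell=raw.cell,
        d_min=raw.d_min,
        phi=raw.phi,
        E_lim=E_lim,
        d=raw.d,
    )
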