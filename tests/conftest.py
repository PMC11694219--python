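"""Shared synthetic-structure fixtures.

Everything is generated at test time from fixed seeds; the session scope
keeps the direct-summation structure factors (the expensive oracle step)
computed once.
"""

import numpy as np
import pytest

from smarphase import (
    UnitCell,
    direct_structure_factors,
    generate_random_structure,
    normalize_to_E,
)


@pytest.fixture(scope="session")
def structure60():
    """~60 equal atoms in a triclinic P1 cell (~990 A^3), the workhorse fixture."""
    cell = UnitCell(10.3, 9.7, 10.1, 92.0, 101.5, 88.0)
    return generate_random_structure(60, cell, min_dist=1.2, seed=11)


@pytest.fixture(scope="session")
def refl60(structure60):
    """Exact E-value data for structure60 to 1.0 A (~2000 reflections)."""
    return normalize_to_E(direct_structure_factors(structure60, 1.0), 60)


@pytest.fixture(scope="session")
def structure40():
    """40-atom monoclinic P1 cell used for the end-to-end solves."""
    cell = UnitCell(9.1, 8.7, 8.9, 90.0, 95.0, 90.0)
    return generate_random_structure(40, cell, min_dist=1.2, seed=42)


@pytest.fixture(scope="session")
def refl40(structure40):
    return normalize_to_E(direct_structure_factors(structure40, 1.0), 40)


@pytest.fixture(scope="session")
def structure20():
    """20-atom cell for the tangent-formula recycling solves."""
    cell = UnitCell(7.3, 7.0, 7.1, 90.0, 93.0, 90.0)
    return generate_random_structure(20, cell, min_dist=1.2, seed=7)


@pytest.fixture(scope="session")
def refl20(structure20):
    return normalize_to_E(direct_structure_factors(structure20, 1.0), 20)


def naive_dft(dmap, hkl):
    """Independent forward-transform oracle: direct voxel summation.

    F_h = (V / N_vox) * sum_voxels map(x) exp(+2 pi i h.x/N).
    """
    dims = dmap.dims
    grids = np.meshgrid(*(np.arange(n) / n for n in dims), indexing="ij")
    out = np.empty(len(hkl), dtype=complex)
    for i, h in enumerate(hkl):
        phase = h[0] * grids[0] + h[1] * grids[1] + h[2] * grids[2]
        out[i] = np.sum(dmap.values * np.exp(2j * np.pi * phase))
    return out * dmap.cell.volume / dmap.n_vox
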