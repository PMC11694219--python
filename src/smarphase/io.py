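"""Reflection, phase, structure and map file I/O.

Reflection lists are accepted in free format (whitespace-separated
``h k l amplitude [sigma]``) or SHELX HKLF-4 fixed width (3I4, 2F8.2).
Amplitudes are interpreted as |E| unless the caller renormalizes.  Friedel
mates are folded onto the canonical half-set and duplicate indices merged by
averaging.  Angles are degrees in every file; radians internally.

Maps are written in the XPLOR/CNS ASCII format (values in synthesis units);
structures in a minimal fractional-coordinate XYZ-with-cell text format.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import numpy as np

from .crystal import CrystalStructure, ReflectionSet, UnitCell, canonical_half
from .maps import DensityMap

__all__ = [
    "read_reflections",
    "write_reflections",
    "write_phases",
    "read_phases",
    "write_map",
    "read_map_xplor",
    "write_structure",
    "read_structure",
    "write_peaks",
]


def _fold_half(hkl: np.ndarray, amp: np.ndarray, phi: Optional[np.ndarray] = None):
    """Map every index to the canonical half-sphere (phases negate with h)."""
    flip = ~canonical_half(hkl)
    hkl = np.where(flip[:, None], -hkl, hkl)
    if phi is not None:
        phi = np.where(flip, -phi, phi)
    return hkl, amp, phi


def read_reflections(
    path,
    cell: UnitCell,
    fmt: str = "auto",
    E_lim: float = 1.0,
) -> ReflectionSet:
    """Parse a reflection file into a folded, merged half-set.

    ``fmt`` is 'free', 'shelx' or 'auto' (free if every line whitespace-splits
    into 4-5 numeric tokens, fixed-width SHELX otherwise).  A 0 0 0 terminator
    line (SHELX convention) ends the file.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    rows = []
    mode = fmt
    for ln, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        if mode == "auto":
            toks = raw.split()
            mode = "free" if len(toks) in (4, 5) else "shelx"
        try:
            if mode == "free":
                toks = raw.split()
                if len(toks) < 4:
                    raise ValueError("expected 'h k l amplitude [sigma]'")
                h, k, l = int(toks[0]), int(toks[1]), int(toks[2])
                amp = float(toks[3])
            else:  # SHELX HKLF-4: 3I4, 2F8.2
                h, k, l = int(raw[0:4]), int(raw[4:8]), int(raw[8:12])
                amp = float(raw[12:20])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed reflection line {ln}: {raw!r}") from exc
        if h == k == l == 0:
            break  # SHELX terminator
        rows.append((h, k, l, amp))
    if not rows:
        raise ValueError(f"{path}: no reflections")
    arr = np.array(rows, dtype=float)
    hkl = arr[:, :3].astype(int)
    amp = arr[:, 3]
    hkl, amp, _ = _fold_half(hkl, amp)
    uniq, inverse, counts = np.unique(hkl, axis=0, return_inverse=True, return_counts=True)
    amp_m = np.zeros(len(uniq))
    np.add.at(amp_m, inverse, amp)
    amp_m /= counts
    if np.any(counts > 1):
        warnings.warn(f"{path}: duplicate (h,k,l) entries merged by averaging", stacklevel=2)
    d = cell.d_spacing(uniq)
    return ReflectionSet(
        hkl=uniq, E=amp_m, cell=cell, d_min=float(d.min()), E_lim=E_lim, d=d
    )


def write_reflections(refl: ReflectionSet, path) -> None:
    """Free-format ``h k l |E|`` list (four decimals)."""
    with open(path, "w") as fh:
        for (h, k, l), e in zip(refl.hkl, refl.E):
            fh.write(f"{h:4d} {k:4d} {l:4d} {e:10.4f}\n")


def write_phases(refl: ReflectionSet, path) -> None:
    """Text table ``h k l |E| phi_deg`` with phases in [0, 360), 2 decimals."""
    if refl.phi is None or len(refl) == 0:
        raise ValueError("no phases to write")
    deg = np.mod(np.degrees(refl.phi), 360.0)
    with open(path, "w") as fh:
        for (h, k, l), e, p in zip(refl.hkl, refl.E, deg):
            fh.write(f"{h:4d} {k:4d} {l:4d} {e:10.4f} {p:8.2f}\n")


def read_phases(path, cell: UnitCell, E_lim: float = 1.0) -> ReflectionSet:
    """Read a ``h k l |E| phi_deg`` table written by :func:`write_phases`."""
    path = Path(path)
    rows = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        toks = raw.split()
        if len(toks) != 5:
            raise ValueError(f"{path}: malformed phase line {ln}: {raw!r}")
        rows.append([float(t) for t in toks])
    if not rows:
        raise ValueError(f"{path}: empty phase file")
    arr = np.array(rows)
    hkl = arr[:, :3].astype(int)
    d = cell.d_spacing(hkl)
    return ReflectionSet(
        hkl=hkl, E=arr[:, 3], cell=cell, d_min=float(d.min()),
        phi=np.radians(arr[:, 4]), E_lim=E_lim, d=d,
    )


def write_map(dmap: DensityMap, path, title: str = "smarphase map") -> None:
    """XPLOR/CNS ASCII map covering the whole unit cell."""
    na, nb, nc = dmap.dims
    cell = dmap.cell
    with open(path, "w") as fh:
        fh.write("\n       2 !NTITLE\n")
        fh.write(f" REMARKS {title}\n")
        fh.write(" REMARKS written by smarphase\n")
        fh.write(
            f"{na:8d}{0:8d}{na - 1:8d}{nb:8d}{0:8d}{nb - 1:8d}{nc:8d}{0:8d}{nc - 1:8d}\n"
        )
        fh.write(
            "".join(f"{v:12.5E}" for v in (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma))
            + "\n"
        )
        fh.write("ZYX\n")
        for k in range(nc):
            fh.write(f"{k:8d}\n")
            section = dmap.values[:, :, k].T.ravel()  # a fastest, then b
            for i in range(0, len(section), 6):
                fh.write("".join(f"{v:12.5E}" for v in section[i : i + 6]) + "\n")
        fh.write(f"{-9999:8d}\n")
        fh.write(f"{dmap.values.mean():12.4E} {dmap.values.std():12.4E}\n")


def read_map_xplor(path) -> DensityMap:
    """Read back an XPLOR ASCII map written by :func:`write_map`."""
    lines = Path(path).read_text().splitlines()
    i = 1
    ntitle = int(lines[i].split()[0])
    i += 1 + ntitle
    g = [int(lines[i][j : j + 8]) for j in range(0, 72, 8)]
    na, nb, nc = g[0], g[3], g[6]
    i += 1
    cp = [float(lines[i][j : j + 12]) for j in range(0, 72, 12)]
    cell = UnitCell(*cp)
    i += 1
    assert lines[i].strip() == "ZYX"
    i += 1
    values = np.empty((na, nb, nc))
    per_section = na * nb
    for k in range(nc):
        i += 1  # section index line
        vals = []
        while len(vals) < per_section:
            row = lines[i]
            vals.extend(float(row[j : j + 12]) for j in range(0, len(row.rstrip()), 12))
            i += 1
        values[:, :, k] = np.array(vals).reshape(nb, na).T
    return DensityMap(values=values, cell=cell)


def write_structure(structure: CrystalStructure, path) -> None:
    """Minimal fractional-coordinate XYZ-with-cell text format."""
    cell = structure.cell
    with open(path, "w") as fh:
        fh.write(f"# {structure.label}\n")
        fh.write(
            f"{cell.a:.6f} {cell.b:.6f} {cell.c:.6f} "
            f"{cell.alpha:.4f} {cell.beta:.4f} {cell.gamma:.4f}\n"
        )
        fh.write(f"{structure.n_atoms}\n")
        for x, y, z in structure.atoms:
            fh.write(f"{x:.8f} {y:.8f} {z:.8f}\n")


def write_peaks(peaks, dims, path) -> None:
    """Fractional-coordinate peak table ``x y z height`` for inspection."""
    frac = peaks.fractional(dims)
    with open(path, "w") as fh:
        for (x, y, z), h in zip(frac, peaks.heights):
            fh.write(f"{x:.6f} {y:.6f} {z:.6f} {h:12.5g}\n")


def read_structure(path) -> CrystalStructure:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    label = lines[0].lstrip("# ").strip()
    cell = UnitCell(*(float(t) for t in lines[1].split()))
    n = int(lines[2])
    atoms = np.array([[float(t) for t in ln.split()] for ln in lines[3 : 3 + n]])
    return CrystalStructure(cell=cell, atoms=atoms, label=label)
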