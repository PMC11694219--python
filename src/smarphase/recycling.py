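"""The delta_M tangent-formula (delta recycling) algorithm.

A single phasing formula is recycled: from the current phases Phi, build the
delta_M synthesis with alpha := Phi, threshold it with the binary mask
m_delta (1 where delta_M >= t1 * sigma(delta_M)), and take

    phi_new = phase of FT{ delta_M * m_delta }

at every reflection.  Because only phases are extracted, the update is
invariant under any positive rescaling of delta_M (the scale constants K and
c drop out).  When the number N of expected atoms is known, the mask support
can be reduced to the N largest peaks of delta_M above the threshold, which
turns the transform into a structure-factor calculation over those peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .crystal import ReflectionSet
from .ipp import find_local_maxima
from .maps import DensityMap, choose_grid, compute_c, forward_transform, synthesize_delta_m
from .masks import compute_m_delta
from .smar import SmarConfig, TrialResult

__all__ = ["RecycleDiagnostics", "tangent_step", "run_recycling"]


@dataclass
class RecycleDiagnostics:
    """Light per-iteration record of a tangent-formula recycle."""

    iteration: int
    mean_phase_change_deg: float
    map_cc_prev: float  # correlation of the masked map with the previous one


def tangent_step(
    delta: DensityMap,
    m_delta: np.ndarray,
    refl: ReflectionSet,
) -> np.ndarray:
    """phi_new = phase of FT{delta_M * m_delta} at each reflection."""
    masked = delta.values * m_delta
    if not np.any(masked):
        raise ValueError("masked delta_M map is identically zero: phases undefined")
    _mod, phi_new = forward_transform(delta.like(masked), refl)
    return phi_new


def _peaks_mask(delta: DensityMap, n_peaks: int, threshold: float) -> np.ndarray:
    """Single-voxel support of the N largest peaks above the threshold."""
    peaks = find_local_maxima(delta)
    keep = peaks.heights >= threshold
    centers = peaks.centers[keep][:n_peaks]
    mask = np.zeros(delta.dims, dtype=np.int8)
    if len(centers):
        mask[tuple(centers.T)] = 1
    return mask


def run_recycling(
    refl: ReflectionSet,
    cfg: SmarConfig,
    seed: Optional[int] = None,
    tail_window: int = 20,
) -> TrialResult:
    """Iterate the tangent formula from uniform-random starting phases.

    The sparse m_delta support voxel-quantizes the atoms, so the recycle does
    not settle on a fixed point but oscillates around the solution; the final
    phase estimate is therefore the circular mean of the per-reflection
    phasors over the last ``tail_window`` iterations, which averages the
    quantization jitter away.

    Diagnostics are lighter than for the dual-space driver: per iteration the
    |E|-weighted mean phase change and the correlation of the masked map with
    the previous one.  Convergence is declared when the mean phase change
    stays below 0.5 degrees for three consecutive iterations (with the
    oscillating support this fires only on very clean solutions; bounded
    iteration is the normal stop).
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0.0, 2.0 * np.pi, len(refl))
    c = cfg.c if cfg.c is not None else compute_c(refl)
    dims = choose_grid(refl, cfg.delta_grid)
    w = refl.E
    history: List[RecycleDiagnostics] = []
    prev_masked: Optional[np.ndarray] = None
    small_changes = 0
    converged = False
    tail = np.zeros(len(refl), dtype=complex)
    n_tail = 0
    for it in range(1, cfg.iterations + 1):
        delta = synthesize_delta_m(refl, phi, c=c, dims=dims, delta_grid=cfg.delta_grid)
        if cfg.use_peaks:
            if cfg.n_atoms_expected is None:
                raise ValueError("peaks variant requires n_atoms_expected")
            m = _peaks_mask(delta, cfg.n_atoms_expected, cfg.t1 * delta.sigma)
            if not m.any():  # no peak clears the threshold: fall back this cycle
                m = compute_m_delta(delta, cfg.t1)
        else:
            m = compute_m_delta(delta, cfg.t1)
        phi_new = tangent_step(delta, m, refl)
        change = np.angle(np.exp(1j * (phi_new - phi)))
        mean_change = float(np.degrees(np.sum(w * np.abs(change)) / np.sum(w)))
        masked = delta.values * m
        if prev_masked is not None and masked.std() > 0 and prev_masked.std() > 0:
            cc = float(np.corrcoef(masked.ravel(), prev_masked.ravel())[0, 1])
        else:
            cc = np.nan
        history.append(RecycleDiagnostics(it, mean_change, cc))
        prev_masked = masked
        phi = phi_new
        if it > cfg.iterations - tail_window:
            tail += np.exp(1j * phi)
            n_tail += 1
        small_changes = small_changes + 1 if mean_change < 0.5 else 0
        if small_changes >= 3:
            converged = True
            break
    phi_final = np.angle(tail) if n_tail >= 2 else phi
    return TrialResult(
        phi_final=phi_final, chi_final=None, history=history,
        converged=converged, seed=seed,
    )
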