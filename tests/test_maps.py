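"""Fourier syntheses, transforms, sigma routes, scale constant, CORE radius."""

import numpy as np
import pytest

from smarphase import (
    CrystalStructure,
    DensityMap,
    ReflectionSet,
    UnitCell,
    choose_grid,
    compute_c,
    core_radius,
    direct_structure_factors,
    find_local_maxima,
    forward_transform,
    generate_random_structure,
    map_sigma,
    normalize_to_E,
    synthesize_delta_m,
    synthesize_rho,
)
from conftest import naive_dft


class TestSynthesizeRho:
    def test_zero_amplitudes_give_zero_map(self, refl60):
        refl = ReflectionSet(
            hkl=refl60.hkl, E=np.zeros(len(refl60)), cell=refl60.cell,
            d_min=refl60.d_min, phi=refl60.phi,
        )
        rho = synthesize_rho(refl)
        assert np.all(rho.values == 0.0)

    def test_round_trip_is_identity_on_band_limited_data(self, refl60):
        rho = synthesize_rho(refl60)
        mod, ph = forward_transform(rho, refl60)
        assert np.allclose(mod, refl60.E, atol=1e-10)
        assert np.allclose(np.angle(np.exp(1j * (ph - refl60.phi))), 0.0, atol=1e-10)

    def test_map_is_mean_zero(self, refl60):
        rho = synthesize_rho(refl60)
        assert abs(rho.values.mean()) < 1e-10

    def test_true_phases_peak_at_atom_positions(self, structure60, refl60):
        rho = synthesize_rho(refl60)
        peaks = find_local_maxima(rho)
        dims = np.array(rho.dims)
        top = peaks.fractional(dims)[: structure60.n_atoms]
        for atom in structure60.atoms:
            d = np.abs(top - atom)
            d = np.minimum(d, 1 - d) * dims  # voxel units, periodic
            assert np.max(d, axis=1).min() <= 1.0 + 1e-9

    def test_strong_subset_uses_only_strong_terms(self, refl60):
        rho_strong = synthesize_rho(refl60, subset="strong")
        sel = refl60.strong_flags
        manual = ReflectionSet(
            hkl=refl60.hkl[sel], E=refl60.E[sel], cell=refl60.cell,
            d_min=refl60.d_min, phi=refl60.phi[sel],
        )
        rho_manual = synthesize_rho(manual, dims=rho_strong.dims)
        assert np.allclose(rho_strong.values, rho_manual.values, atol=1e-12)

    def test_empty_strong_set_raises(self, refl60):
        weak = ReflectionSet(
            hkl=refl60.hkl, E=np.full(len(refl60), 0.5), cell=refl60.cell,
            d_min=refl60.d_min, phi=refl60.phi, E_lim=1.0,
        )
        with pytest.raises(ValueError, match="no strong"):
            synthesize_rho(weak, subset="strong")


class TestComputeC:
    def test_hand_arithmetic(self):
        refl = ReflectionSet(
            hkl=np.array([[1, 0, 0], [0, 1, 0]]), E=np.array([2.0, 0.0]),
            cell=UnitCell(5, 5, 5), d_min=1.0,
        )
        # <|E|> = 1, sum E^2 = 4, sum dE^2 = 2
        assert compute_c(refl) == pytest.approx(2.0)

    def test_acentric_wilson_value(self, refl60):
        # Rayleigh |E|: c -> 1/(1 - pi/4) = 4.66
        assert compute_c(refl60) == pytest.approx(1 / (1 - np.pi / 4), abs=0.1)

    def test_equal_amplitudes_rejected(self):
        refl = ReflectionSet(
            hkl=np.array([[1, 0, 0], [0, 1, 0]]), E=np.array([1.0, 1.0]),
            cell=UnitCell(5, 5, 5), d_min=1.0,
        )
        with pytest.raises(ValueError):
            compute_c(refl)


class TestSynthesizeDeltaM:
    def test_mean_amplitude_reflection_contributes_nothing(self, refl60):
        # a reflection whose |E| equals <|E|> has a zero difference coefficient
        E2 = refl60.E.copy()
        idx = 17
        E2[idx] = np.delete(E2, idx).mean()  # |E|_idx == <|E|> of the final set
        assert E2[idx] == pytest.approx(E2.mean(), abs=1e-12)
        refl2 = ReflectionSet(hkl=refl60.hkl, E=E2, cell=refl60.cell,
                              d_min=refl60.d_min, phi=refl60.phi)
        delta = synthesize_delta_m(refl2, refl2.phi, c=3.0)
        mod, _ = forward_transform(delta, refl2)
        assert mod[idx] == pytest.approx(0.0, abs=1e-10)

    def test_linearity_in_c(self, refl60):
        alpha = np.linspace(0, 2 * np.pi, len(refl60))
        d1 = synthesize_delta_m(refl60, alpha, c=2.0)
        d2 = synthesize_delta_m(refl60, alpha, c=4.0)
        assert np.allclose(d2.values, 2 * d1.values, atol=1e-12)
        _, p1 = forward_transform(d1, refl60)
        _, p2 = forward_transform(d2, refl60)
        assert np.allclose(np.angle(np.exp(1j * (p1 - p2))), 0.0, atol=1e-10)

    def test_alpha_must_cover_all_reflections(self, refl60):
        with pytest.raises(ValueError):
            synthesize_delta_m(refl60, refl60.phi[:-5])

    def test_a_peaks_match_rho_at_atoms(self, structure60, refl60):
        """delta_M with true phases equals rho at the atomic positions."""
        atoms = structure60.atoms
        c = compute_c(refl60)
        coeff_rho = refl60.E * np.exp(1j * refl60.phi)
        coeff_del = c * (refl60.E - refl60.E_mean) * np.exp(1j * refl60.phi)
        ph = refl60.hkl @ atoms.T
        V = refl60.cell.volume
        rho_at = 2 * np.real(coeff_rho[:, None] * np.exp(-2j * np.pi * ph)).sum(0) / V
        del_at = 2 * np.real(coeff_del[:, None] * np.exp(-2j * np.pi * ph)).sum(0) / V
        assert np.median(del_at / rho_at) == pytest.approx(1.0, abs=0.1)


def _cross_vector_positions(structure, min_sep=1.0):
    """Single-multiplicity cross vectors 2 r_j - r_m (j != m), isolated from atoms."""
    atoms = structure.atoms
    cell = structure.cell
    n = structure.n_atoms
    out = []
    for j in range(n):
        for m in range(n):
            if j == m:
                continue
            p = (2 * atoms[j] - atoms[m]) % 1.0
            d = cell.min_image_distance(np.tile(p, (n, 1)), atoms)
            if d.min() > min_sep:
                out.append(p)
    return np.array(out)


def test_b_peak_law_on_toy_structures():
    """The cross-vector (B-type) peaks of delta_M are ~1/(N-1) of the atom peaks.

    Checked by brute-force enumeration of the r_j + r_l - r_m positions on
    toy structures at near-full resolution, using positions generated by a
    single (j, l, m) triple so peak heights do not superpose.
    """
    for n, seed in [(3, 1), (4, 2)]:
        cell = UnitCell(6.0, 5.8, 6.2, 90, 92, 90)
        s = generate_random_structure(n, cell, 1.5, seed=seed)
        refl = normalize_to_E(direct_structure_factors(s, 0.7), n)
        c = compute_c(refl)
        coeff = c * (refl.E - refl.E_mean) * np.exp(1j * refl.phi)
        V = cell.volume

        def at(points):
            ph = refl.hkl @ points.T
            return 2 * np.real(coeff[:, None] * np.exp(-2j * np.pi * ph)).sum(0) / V

        a_heights = at(s.atoms)
        b_pos = _cross_vector_positions(s)
        assert len(b_pos) > 0
        ratio = np.median(at(b_pos)) / np.median(a_heights)
        assert 0.8 / (n - 1) <= ratio <= 1.2 / (n - 1)


class TestForwardTransform:
    def test_matches_naive_dft_band_limited(self, refl20):
        rho = synthesize_rho(refl20)
        sub = slice(0, len(refl20), 29)
        oracle = naive_dft(rho, refl20.hkl[sub])
        mod, ph = forward_transform(rho, refl20)
        assert np.allclose(np.abs(oracle), mod[sub], atol=1e-8)
        assert np.allclose(np.angle(oracle * np.exp(-1j * ph[sub])), 0.0, atol=1e-8)

    def test_matches_naive_dft_on_masked_map(self, refl20):
        # |rho| is not band limited; the contract is agreement with the naive
        # DFT on the same grid, aliasing included
        rho = synthesize_rho(refl20)
        amap = rho.like(np.abs(rho.values))
        sub = slice(0, len(refl20), 31)
        oracle = naive_dft(amap, refl20.hkl[sub])
        mod, ph = forward_transform(amap, refl20)
        assert np.allclose(np.abs(oracle), mod[sub], atol=1e-8)
        assert np.allclose(np.angle(oracle * np.exp(-1j * ph[sub])), 0.0, atol=1e-8)

    def test_nonnegative_map_is_fixed_by_absolute_value(self, refl20):
        # a map that is everywhere >= 0 satisfies |map| = map, so the phases
        # of FT(|map|) are exactly the phases of FT(map)
        rho = synthesize_rho(refl20)
        pos = rho.like(np.maximum(rho.values, 0.0))
        m1, p1 = forward_transform(pos, refl20)
        m2, p2 = forward_transform(pos.like(np.abs(pos.values)), refl20)
        assert np.allclose(m1, m2, atol=1e-12)
        assert np.allclose(np.angle(np.exp(1j * (p1 - p2))), 0.0, atol=1e-12)

    def test_out_of_nyquist_raises(self, refl20):
        rho = synthesize_rho(refl20)
        big = ReflectionSet(
            hkl=np.array([[50, 0, 0]]), E=np.array([1.0]),
            cell=refl20.cell, d_min=0.1,
        )
        with pytest.raises(ValueError):
            forward_transform(rho, big)


class TestMapSigma:
    def test_zero_map(self, refl60):
        z = DensityMap(np.zeros((8, 8, 8)), refl60.cell)
        assert map_sigma(z) == 0.0

    def test_parseval_equals_grid_route(self, refl60):
        rho = synthesize_rho(refl60)
        assert map_sigma(refl60, "all") == pytest.approx(rho.sigma, rel=1e-8)

    def test_scaling(self, refl60):
        rho = synthesize_rho(refl60)
        assert map_sigma(rho.like(-3.0 * rho.values)) == pytest.approx(3 * rho.sigma, rel=1e-12)

    def test_phase_independence(self, refl60):
        rng = np.random.default_rng(0)
        rho = synthesize_rho(refl60, rng.uniform(0, 2 * np.pi, len(refl60)))
        assert map_sigma(refl60, "all") == pytest.approx(rho.sigma, rel=1e-8)


class TestCoreRadius:
    def test_first_zero_of_termination_kernel(self):
        # independent dense-scan oracle for the first root of sin u = u cos u
        u = np.linspace(0.1, 6.0, 600001)
        f = np.sin(u) - u * np.cos(u)
        sign_change = np.nonzero(np.diff(np.sign(f)) != 0)[0]
        u_star = u[sign_change[0]]
        assert u_star == pytest.approx(4.4934, abs=1e-3)
        assert core_radius(1.0) == pytest.approx(u_star / (2 * np.pi), abs=1e-4)

    def test_value_is_0_72_dmin(self):
        assert round(core_radius(1.0), 2) == 0.72

    def test_linear_scaling(self):
        assert core_radius(2.6) == pytest.approx(2 * core_radius(1.3), rel=1e-12)


def test_grid_policy_is_nyquist_sufficient_and_smooth(refl60):
    dims = choose_grid(refl60)
    hmax = refl60.h_max
    for n, hm, edge in zip(dims, hmax, (10.3, 9.7, 10.1)):
        assert n >= 2 * hm + 2
        assert n >= edge / (refl60.d_min / 3.0) - 1
        m = n
        for p in (2, 3, 5):
            while m % p == 0:
                m //= p
        assert m == 1
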