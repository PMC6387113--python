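"""Quasi-harmonic mode extraction against analytic and sampled oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from thzmodes.constants import (GHZ_PER_INVCM, KB_AMU_A2_PS2,
                                MDYNE_PER_A_IN_AMU_PS2)
from thzmodes.quasiharmonic import (FluctuationMatrix, ModeSet, Topology,
                                    Trajectory, aggregate_replicas,
                                    align_frames, filter_strong_modes,
                                    fluctuation_matrix, mode_dipole,
                                    modes_from_fluctuations,
                                    oscillator_strength, rigid_body_basis,
                                    synthesize_spectrum, QuasiHarmonicModel)
from thzmodes.synthetic import (diatomic_system, gen_harmonic_trajectory,
                                random_harmonic_system)

TEMP = 298.0


def triatomic():
    return Topology(np.array([200.0, 250.0, 300.0]),
                    np.array([1.0, -2.0, 1.0]))


def triangle_coords():
    return np.array([[0.0, 0.0, 0.0], [8.0, 0.0, 0.0], [3.0, 7.0, 0.5]])


class TestAlignment:
    def test_identical_frames_unchanged_up_to_centering(self):
        topo = triatomic()
        x = np.repeat(triangle_coords()[None], 5, axis=0)
        out = align_frames(Trajectory(topo, x))
        assert np.allclose(out.coords, out.coords[0])
        # centered at the mass-weighted origin
        com = np.einsum("ni,n->i", out.coords[0], topo.masses_amu)
        assert np.allclose(com, 0.0, atol=1e-10)

    def test_rigid_motions_aligned_to_machine_precision(self, rng):
        topo = triatomic()
        base = triangle_coords()
        frames = []
        for _ in range(20):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.uniform(-5, 5, 3)
            frames.append(base @ rot.T + shift)
        out = align_frames(Trajectory(topo, np.array(frames)))
        rmsd = np.sqrt(((out.coords - out.coords[0]) ** 2).sum(axis=(1, 2)))
        assert rmsd.max() < 1e-8

    def test_alignment_is_an_isometry(self, rng):
        topo = triatomic()
        frames = triangle_coords()[None] + 0.3 * rng.standard_normal(
            (10, 3, 3))
        out = align_frames(Trajectory(topo, frames))
        for before, after in zip(frames, out.coords):
            d0 = np.linalg.norm(before[:, None] - before[None], axis=-1)
            d1 = np.linalg.norm(after[:, None] - after[None], axis=-1)
            assert np.allclose(d0, d1, atol=1e-10)

    def test_collinear_structure_warns_translation_only(self):
        topo = Topology(np.array([100.0, 100.0]), np.array([1.0, -1.0]))
        x = np.array([[[0, 0, 0], [5, 0, 0]], [[1, 0, 0], [6.2, 0, 0]]],
                     dtype=float)
        with pytest.warns(UserWarning, match="collinear"):
            align_frames(Trajectory(topo, x))


class TestFluctuationMatrix:
    def test_static_trajectory_gives_zero_matrix(self):
        topo = triatomic()
        x = np.repeat(triangle_coords()[None], 3, axis=0)
        fm = fluctuation_matrix(Trajectory(topo, x))
        assert np.allclose(fm.sigma, 0.0)

    def test_iid_gaussian_diagonal_matches_analytic_moment(self, rng):
        # coordinates ~ N(0, s²) per axis ⇒ mass-weighted variance m·s²
        m, s = 50.0, 0.3
        topo = Topology(np.array([m, m]), np.array([0.0, 0.0]))
        x = s * rng.standard_normal((10_000, 2, 3))
        x[:, 1] += 10.0  # keep atoms distinct
        fm = fluctuation_matrix(Trajectory(topo, x))
        assert np.allclose(np.diag(fm.sigma), m * s**2, rtol=0.1)

    def test_eigenvalues_invariant_under_atom_reordering(self, rng):
        topo = triatomic()
        x = triangle_coords()[None] + 0.2 * rng.standard_normal((500, 3, 3))
        fm = fluctuation_matrix(Trajectory(topo, x))
        perm = [2, 0, 1]
        topo_p = Topology(topo.masses_amu[perm], topo.charges_e[perm])
        fm_p = fluctuation_matrix(Trajectory(topo_p, x[:, perm]))
        assert np.allclose(np.linalg.eigvalsh(fm.sigma),
                           np.linalg.eigvalsh(fm_p.sigma), atol=1e-10)


def diatomic_analytic_fluctuations(k_mdyne=0.025, m=200.0, q=1.0, L=5.0):
    """Analytic σ for a diatomic stretch mode at temperature TEMP."""
    topo = Topology(np.array([m, m]), np.array([q, -q]))
    coords = np.array([[0.0, 0.0, 0.0], [L, 0.0, 0.0]])
    a = np.zeros(6)
    a[0], a[3] = 1 / np.sqrt(2), -1 / np.sqrt(2)  # mass-weighted stretch
    k = k_mdyne * MDYNE_PER_A_IN_AMU_PS2
    omega2 = k * 2.0 / m  # k/μ with μ = m/2
    lam = KB_AMU_A2_PS2 * TEMP / omega2
    sigma = lam * np.outer(a, a)
    return FluctuationMatrix(sigma, coords, topo), omega2, topo


class TestModesFromFluctuations:
    def test_identity_eigenvalue_scaling(self):
        # λ = k_B·T ⇒ ω = 1 rad/ps ⇒ ν = 1000/2π GHz
        fm, _, topo = diatomic_analytic_fluctuations()
        a = np.zeros(6)
        a[0], a[3] = 1 / np.sqrt(2), -1 / np.sqrt(2)
        sigma = (KB_AMU_A2_PS2 * TEMP) * np.outer(a, a)
        modes = modes_from_fluctuations(
            FluctuationMatrix(sigma, fm.mean_structure, topo), TEMP)
        assert modes.frequencies_ghz[0] == pytest.approx(1e3 / (2 * np.pi),
                                                         rel=1e-10)

    def test_diatomic_closed_form_strength_and_frequency(self):
        # with analytic covariance the pipeline reproduces S = q²/μ and
        # ν = √(k/μ)/2π exactly
        fm, omega2, topo = diatomic_analytic_fluctuations()
        modes = modes_from_fluctuations(fm, TEMP)
        assert len(modes) == 1
        assert modes.n_discarded_rigid == 5  # collinear molecule
        nu_expected = np.sqrt(omega2) / (2 * np.pi) * 1e3
        assert modes.frequencies_ghz[0] == pytest.approx(nu_expected,
                                                         rel=1e-12)
        mu = topo.masses_amu[0] / 2
        assert modes.strengths_au[0] == pytest.approx(1.0 / mu, rel=1e-12)

    def test_sampled_diatomic_recovers_618_ghz(self):
        system = diatomic_system(n_frames=10_000, seed=7)
        with pytest.warns(UserWarning, match="collinear"):
            res = QuasiHarmonicModel(gen_harmonic_trajectory(system)).fit()
        assert res.modesets[0].frequencies_ghz[0] == pytest.approx(617.5,
                                                                   rel=0.03)

    def test_mode_count_is_3n_minus_6(self):
        system = random_harmonic_system(6, seed=1, n_frames=2000)
        res = QuasiHarmonicModel(gen_harmonic_trajectory(system)).fit()
        modes = res.modesets[0]
        assert len(modes) == 3 * 6 - 6
        assert len(modes) + modes.n_discarded_rigid == 3 * 6

    def test_non_psd_matrix_rejected(self):
        fm, _, topo = diatomic_analytic_fluctuations()
        bad = fm.sigma - 0.5 * np.eye(6) * fm.sigma.max()
        with pytest.raises(ValueError, match="positive semi-definite"):
            modes_from_fluctuations(
                FluctuationMatrix(bad, fm.mean_structure, topo), TEMP)


class TestDipoleAndStrength:
    def test_zero_charges_zero_dipole(self):
        topo = Topology(np.array([10.0, 20.0]), np.array([0.0, 0.0]))
        a = np.ones(6) / np.sqrt(6)
        assert np.allclose(mode_dipole(a[:, None], topo), 0.0)

    def test_symmetric_pair_cancellation(self):
        # equal charges, antisymmetric displacements: contributions cancel
        topo = Topology(np.array([50.0, 50.0]), np.array([1.0, 1.0]))
        a = np.zeros((6, 1))
        a[0, 0], a[3, 0] = 1 / np.sqrt(2), -1 / np.sqrt(2)
        assert np.allclose(mode_dipole(a, topo), 0.0)

    def test_diatomic_two_term_sum(self):
        q, m = 2.0, 64.0
        topo = Topology(np.array([m, m]), np.array([q, -q]))
        a = np.zeros((6, 1))
        a[0, 0], a[3, 0] = 1 / np.sqrt(2), -1 / np.sqrt(2)
        p = mode_dipole(a, topo)
        assert np.linalg.norm(p) == pytest.approx(
            2 * q * (1 / np.sqrt(2)) / np.sqrt(m), rel=1e-12)

    def test_strength_invariant_under_sign_flip(self):
        topo = triatomic()
        rng = np.random.default_rng(1)
        a = rng.standard_normal((9, 1))
        a /= np.linalg.norm(a)
        s1 = oscillator_strength(mode_dipole(a, topo), a, topo)
        s2 = oscillator_strength(mode_dipole(-a, topo), -a, topo)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_strength_invariant_under_rigid_rotation(self, rng):
        topo = triatomic()
        a = rng.standard_normal((9, 2))
        a /= np.linalg.norm(a, axis=0)
        rot = Rotation.random(rng=rng).as_matrix()
        a_rot = (a.reshape(3, 3, 2).transpose(2, 0, 1) @ rot.T) \
            .transpose(1, 2, 0).reshape(9, 2)
        s = oscillator_strength(mode_dipole(a, topo), a, topo)
        s_rot = oscillator_strength(mode_dipole(a_rot, topo), a_rot, topo)
        assert np.allclose(s, s_rot, rtol=1e-12)


def modeset(freqs, strengths, topo=None):
    freqs = np.asarray(freqs, float)
    strengths = np.asarray(strengths, float)
    if topo is None:
        topo = Topology(np.array([100.0, 100.0]), np.array([1.0, -1.0]))
    k = freqs.size
    vecs = np.zeros((6, k))
    vecs[0] = 1.0
    return ModeSet(freqs, vecs, np.zeros((k, 3)), strengths, topo)


class TestSpectrumSynthesis:
    def test_empty_modeset_gives_zero_spectrum(self):
        grid = np.linspace(400, 1000, 100)
        assert np.allclose(synthesize_spectrum(modeset([], []), grid), 0.0)

    def test_single_mode_peak_height(self):
        grid = np.array([823.0])
        spec = synthesize_spectrum(modeset([823.0], [100.0]), grid,
                                   gamma_invcm=0.6)
        assert spec[0] == pytest.approx(100.0 / 0.6, rel=1e-12)

    def test_superposition_linearity(self):
        grid = np.linspace(400, 1000, 601)
        both = synthesize_spectrum(modeset([500, 900], [50, 80]), grid)
        separate = (synthesize_spectrum(modeset([500], [50]), grid)
                    + synthesize_spectrum(modeset([900], [80]), grid))
        assert np.allclose(both, separate, rtol=1e-12)


class TestFilterAndAggregate:
    def test_strict_threshold_rule(self):
        ms = modeset([500, 600, 700], [10.0, 30.0, 31.0])
        kept = filter_strong_modes(ms, 30.0)
        assert list(kept.strengths_au) == [31.0]

    def test_zero_threshold_keeps_positive_strengths(self):
        ms = modeset([500, 600], [0.0, 5.0])
        assert len(filter_strong_modes(ms, 0.0)) == 1

    def test_threshold_above_max_empties_set(self):
        ms = modeset([500], [10.0])
        assert len(filter_strong_modes(ms, 99.0)) == 0

    def test_identical_replicas_average_to_each(self):
        grid = np.linspace(400, 1000, 301)
        ms = modeset([823.0], [100.0])
        one = synthesize_spectrum(ms, grid)
        avg, _, strongest = aggregate_replicas([ms, ms, ms], grid,
                                               threshold_au=0.0)
        assert np.allclose(avg, one)
        assert strongest == pytest.approx(823.0, abs=grid[1] - grid[0])

    def test_disjoint_equal_modes_halve_in_the_average(self):
        grid = np.linspace(400, 1000, 1201)
        a, b = modeset([500.0], [100.0]), modeset([900.0], [100.0])
        avg, _, _ = aggregate_replicas([a, b], grid, threshold_au=0.0)
        single = synthesize_spectrum(a, grid)
        i500 = np.argmin(np.abs(grid - 500))
        assert avg[i500] == pytest.approx(single[i500] / 2, rel=1e-3)

    def test_averaging_commutes_with_grid_restriction(self):
        grid = np.linspace(400, 1000, 601)
        sub = grid[100:300]
        sets = [modeset([520.0], [40.0]), modeset([640.0], [70.0])]
        full, filt, _ = aggregate_replicas(sets, grid, threshold_au=10.0)
        full_sub, filt_sub, _ = aggregate_replicas(sets, sub,
                                                   threshold_au=10.0)
        assert np.allclose(full[100:300], full_sub)
        assert np.allclose(filt[100:300], filt_sub)

    def test_all_filtered_out_warns_and_reports_nan(self):
        grid = np.linspace(400, 1000, 61)
        with pytest.warns(UserWarning, match="threshold"):
            _, _, strongest = aggregate_replicas(
                [modeset([500.0], [1.0])], grid, threshold_au=50.0)
        assert np.isnan(strongest)


class TestEndToEndRecovery:
    def test_errors_shrink_with_more_frames(self):
        # frequency error decreases in expectation as sampling grows
        def mean_err(n_frames):
            errs = []
            for seed in range(4):
                system = random_harmonic_system(5, seed=seed,
                                                n_frames=n_frames)
                f0, _, _ = system.planted_modes()
                res = QuasiHarmonicModel(
                    gen_harmonic_trajectory(system)).fit()
                errs.append(np.abs(
                    res.modesets[0].frequencies_ghz - f0).mean())
            return np.mean(errs)

        assert mean_err(8000) < mean_err(500)
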