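"""Quasi-harmonic vibrational analysis of molecular trajectories.

The quasi-harmonic approximation treats configurational fluctuations
sampled by a trajectory as draws from an effective harmonic potential.  In
mass-weighted coordinates q_i = √m_i·r_i the fluctuation (covariance)
matrix

    σ = ⟨(q − ⟨q⟩)(q − ⟨q⟩)ᵀ⟩ = k_B·T·F⁻¹

determines the effective force-constant matrix F, so each eigenvalue λ_k
of σ yields a mode with angular frequency ω_k = √(k_B·T/λ_k) and a
mass-weighted eigenvector a_k.  The mode's dipole derivative and
oscillator strength follow from the atomic partial charges:

    p_k = Σ_i e_i·a_ki/√m_i          (Cartesian displacement a_ki/√m_i)
    S_k = |p_k|² / Σ_i m_i·(a_ki/√m_i)²   (= |p_k|² for unit-norm a_k)

Strengths are reported in e²/amu — the package's "a.u.".  Mode spectra are
synthesized by superimposing Lorentz profiles (zero background) with a
dissipative factor γ, 0.6 cm⁻¹ by default.

Frames are first superposed onto the iteratively refined mean structure by
mass-weighted least squares (Kabsch), and the six rigid-body degrees of
freedom (five for collinear structures) are removed by projecting σ onto
the orthogonal complement of the translation/rotation subspace built from
the mean structure, leaving exactly 3N−6 internal modes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import GHZ_PER_INVCM, KB_AMU_A2_PS2

__all__ = [
    "Topology",
    "Trajectory",
    "FluctuationMatrix",
    "ModeSet",
    "align_frames",
    "fluctuation_matrix",
    "rigid_body_basis",
    "modes_from_fluctuations",
    "mode_dipole",
    "oscillator_strength",
    "synthesize_spectrum",
    "filter_strong_modes",
    "aggregate_replicas",
    "QuasiHarmonicModel",
    "QuasiHarmonicResults",
    "DEFAULT_GAMMA_INVCM",
    "DEFAULT_STRENGTH_THRESHOLD_AU",
]

logger = logging.getLogger(__name__)

#: Default Lorentz broadening for synthesized mode spectra (cm⁻¹).
DEFAULT_GAMMA_INVCM = 0.6
#: Default reporting threshold for "strong" modes (e²/amu).
DEFAULT_STRENGTH_THRESHOLD_AU = 30.0
#: Eigenvalues below this fraction of the largest are numerically zero.
RIGID_EIGVAL_RTOL = 1e-12


@dataclass(frozen=True)
class Topology:
    """Per-atom masses (amu) and partial charges (elementary charges)."""

    masses_amu: np.ndarray
    charges_e: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.masses_amu, dtype=float)
        e = np.asarray(self.charges_e, dtype=float)
        if m.ndim != 1 or m.shape != e.shape:
            raise ValueError("masses and charges must be equal-length 1-D")
        if m.size < 2:
            raise ValueError("need at least 2 atoms")
        if np.any(m <= 0):
            raise ValueError("masses must be positive")
        object.__setattr__(self, "masses_amu", m)
        object.__setattr__(self, "charges_e", e)

    @property
    def n_atoms(self) -> int:
        return self.masses_amu.size


@dataclass(frozen=True)
class Trajectory:
    """Frames of Cartesian coordinates (Å) over a fixed topology."""

    topology: Topology
    coords: np.ndarray           # (n_frames, N, 3)
    dt_ps: float = 0.2
    temperature_k: float = 298.0

    def __post_init__(self):
        x = np.asarray(self.coords, dtype=float)
        if x.ndim != 3 or x.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if x.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if x.shape[1] != self.topology.n_atoms:
            raise ValueError("coordinate/topology atom count mismatch")
        object.__setattr__(self, "coords", x)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def _weighted_center(coords, masses):
    """Mass-weighted centroid; coords (..., N, 3)."""
    return np.einsum("...ni,n->...i", coords, masses) / masses.sum()


def _is_collinear(structure, masses, tol=1e-8):
    x = structure - _weighted_center(structure, masses)
    s = np.linalg.svd(np.sqrt(masses)[:, None] * x, compute_uv=False)
    return s[0] == 0 or s[1] < tol * s[0]


def _kabsch_rotations(frames_c, ref_c, masses):
    """Batched optimal rotations mapping each centered frame onto the
    centered reference (mass-weighted Kabsch via 3×3 SVDs)."""
    h = np.einsum("n,fni,nj->fij", masses, frames_c, ref_c)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("fij,fjk->fik", u, vt))
    vt[:, -1, :] *= np.sign(det)[:, None]
    # R_f maps frame coords onto the reference: x_aligned = R @ x
    return np.einsum("fji,fkj->fik", vt, u)


def align_frames(traj: Trajectory, max_iter: int = 10,
                 tol: float = 1e-10) -> Trajectory:
    """Superpose every frame onto the iteratively refined mean structure.

    Mass-weighted least-squares translation + rotation; after alignment the
    center of mass sits at the origin in every frame.  Degenerate
    (collinear) structures trigger a warning and translation-only
    alignment, since the rotation about the molecular axis is undefined.
    """
    m = traj.topology.masses_amu
    x = traj.coords - _weighted_center(traj.coords, m)[:, None, :]
    if _is_collinear(x.mean(axis=0), m):
        warnings.warn("collinear structure: translation-only alignment",
                      stacklevel=2)
        return replace(traj, coords=x)
    ref = x[0]
    for _ in range(max_iter):
        rot = _kabsch_rotations(x, ref, m)
        aligned = np.einsum("fij,fnj->fni", rot, x)
        new_ref = aligned.mean(axis=0)
        new_ref -= _weighted_center(new_ref, m)
        if np.max(np.abs(new_ref - ref)) < tol:
            ref = new_ref
            break
        ref = new_ref
    rot = _kabsch_rotations(x, ref, m)
    aligned = np.einsum("fij,fnj->fni", rot, x)
    return replace(traj, coords=aligned)


@dataclass(frozen=True)
class FluctuationMatrix:
    """Mass-weighted positional covariance σ (amu·Å²) and mean structure."""

    sigma: np.ndarray            # (3N, 3N)
    mean_structure: np.ndarray   # (N, 3), Cartesian Å
    topology: Topology

    def __post_init__(self):
        s = np.asarray(self.sigma, dtype=float)
        n = self.topology.n_atoms
        if s.shape != (3 * n, 3 * n):
            raise ValueError("sigma must be 3N×3N")
        if not np.allclose(s, s.T, atol=1e-8 * max(np.abs(s).max(), 1.0)):
            raise ValueError("sigma must be symmetric")
        object.__setattr__(self, "sigma", 0.5 * (s + s.T))


def fluctuation_matrix(traj: Trajectory) -> FluctuationMatrix:
    """Sample second-moment matrix of q − ⟨q⟩ with q_i = √m_i·r_i.

    The trajectory should be aligned first; residual rigid-body variance is
    in any case projected out during mode extraction.
    """
    m = traj.topology.masses_amu
    q = (traj.coords * np.sqrt(m)[None, :, None]).reshape(traj.n_frames, -1)
    mean_q = q.mean(axis=0)
    dq = q - mean_q
    sigma = dq.T @ dq / traj.n_frames
    mean_structure = mean_q.reshape(-1, 3) / np.sqrt(m)[:, None]
    return FluctuationMatrix(sigma, mean_structure, traj.topology)


def rigid_body_basis(structure, masses, tol: float = 1e-8) -> np.ndarray:
    """Orthonormal basis (3N×k) of mass-weighted rigid-body motions.

    Three translations plus the rotations about the mass-weighted centroid;
    k = 6 for a generic structure, 5 for a collinear one.
    """
    structure = np.asarray(structure, dtype=float)
    masses = np.asarray(masses, dtype=float)
    n = masses.size
    x = structure - _weighted_center(structure, masses)
    sm = np.sqrt(masses)
    vecs = []
    for d in range(3):
        t = np.zeros((n, 3))
        t[:, d] = sm
        vecs.append(t.ravel())
    for d in range(3):
        axis = np.zeros(3)
        axis[d] = 1.0
        r = sm[:, None] * np.cross(axis, x)
        vecs.append(r.ravel())
    b = np.column_stack(vecs)
    u, s, _ = np.linalg.svd(b, full_matrices=False)
    return u[:, s > tol * s[0]]


def mode_dipole(eigenvectors, topology: Topology) -> np.ndarray:
    """Dipole derivative p_k = Σ_i e_i·a_ki/√m_i for each mode.

    ``eigenvectors`` is (3N, K) in mass-weighted coordinates; returns
    (K, 3) in e·Å·amu^(−1/2)·(Å√amu)⁻¹ — i.e. e/√amu per unit mode
    coordinate.
    """
    a = np.asarray(eigenvectors, dtype=float)
    k = a.shape[1] if a.ndim == 2 else 1
    cart = a.reshape(topology.n_atoms, 3, k)
    w = topology.charges_e / np.sqrt(topology.masses_amu)
    return np.einsum("n,ndk->kd", w, cart)


def oscillator_strength(dipoles, eigenvectors, topology: Topology
                        ) -> np.ndarray:
    """S_k = |p_k|² / Σ_i m_i·(a_ki/√m_i)², in e²/amu.

    The denominator reduces to Σ a_ki² (=1 for unit-norm mass-weighted
    eigenvectors) but is kept explicit so alternative normalisations
    remain testable.
    """
    p = np.atleast_2d(np.asarray(dipoles, dtype=float))
    a = np.asarray(eigenvectors, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    cart = a.reshape(topology.n_atoms, 3, -1)
    denom = np.einsum("n,ndk,ndk->k", topology.masses_amu,
                      cart / np.sqrt(topology.masses_amu)[:, None, None],
                      cart / np.sqrt(topology.masses_amu)[:, None, None])
    return np.einsum("kd,kd->k", p, p) / denom


@dataclass(frozen=True)
class ModeSet:
    """Quasi-harmonic modes: frequencies, eigenvectors, dipoles, strengths."""

    frequencies_ghz: np.ndarray    # (K,), ascending
    eigenvectors: np.ndarray       # (3N, K), unit-norm mass-weighted
    dipoles: np.ndarray            # (K, 3)
    strengths_au: np.ndarray       # (K,), e²/amu
    topology: Topology
    replica: int | None = None
    n_discarded_rigid: int = 0

    def __len__(self) -> int:
        return self.frequencies_ghz.size

    def subset(self, mask) -> "ModeSet":
        mask = np.asarray(mask)
        return ModeSet(self.frequencies_ghz[mask],
                       self.eigenvectors[:, mask],
                       self.dipoles[mask], self.strengths_au[mask],
                       self.topology, self.replica, self.n_discarded_rigid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mode": np.arange(len(self)),
            "freq_ghz": self.frequencies_ghz,
            "strength_au": self.strengths_au,
            "replica": self.replica if self.replica is not None else -1,
        })


def modes_from_fluctuations(fm: FluctuationMatrix, temperature_k: float,
                            rigid_rtol: float = RIGID_EIGVAL_RTOL,
                            replica: int | None = None) -> ModeSet:
    """Eigendecompose σ in the internal subspace and build the mode set.

    The translation/rotation subspace of the mean structure is projected
    out before diagonalisation, so retained modes + discarded rigid-body
    degrees of freedom = 3N.  Eigenvalues below ``rigid_rtol`` of the
    largest are treated as numerically zero and dropped (with a warning if
    that leaves fewer than 3N−6 modes, e.g. for rank-deficient sampling).
    For eigenvalue λ_k the frequency is ν_k = √(k_B·T/λ_k)/2π, reported in
    GHz.
    """
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    sigma = fm.sigma
    eigval_bounds = np.linalg.eigvalsh(sigma)
    if eigval_bounds[0] < -1e-8 * max(eigval_bounds[-1], 1.0):
        raise ValueError("fluctuation matrix is not positive semi-definite")
    d = rigid_body_basis(fm.mean_structure, fm.topology.masses_amu)
    proj = np.eye(sigma.shape[0]) - d @ d.T
    sigma_int = proj @ sigma @ proj
    lam, vec = np.linalg.eigh(0.5 * (sigma_int + sigma_int.T))
    keep = lam > rigid_rtol * max(lam[-1], 0.0)
    n_internal = sigma.shape[0] - d.shape[1]
    if int(keep.sum()) < n_internal:
        warnings.warn(
            f"only {int(keep.sum())} of {n_internal} internal modes carry "
            "variance above tolerance (rank-deficient sampling?)",
            stacklevel=2)
    lam, vec = lam[keep], vec[:, keep]
    order = np.argsort(lam)[::-1]          # soft (large-λ) modes first
    lam, vec = lam[order], vec[:, order]
    omega = np.sqrt(KB_AMU_A2_PS2 * temperature_k / lam)   # rad/ps
    freq_ghz = omega / (2.0 * np.pi) * 1e3
    vec = vec / np.linalg.norm(vec, axis=0, keepdims=True)
    p = mode_dipole(vec, fm.topology)
    s = oscillator_strength(p, vec, fm.topology)
    return ModeSet(freq_ghz, vec, p, s, fm.topology, replica=replica,
                   n_discarded_rigid=sigma.shape[0] - lam.size)


def synthesize_spectrum(modes: ModeSet, grid_ghz,
                        gamma_invcm: float = DEFAULT_GAMMA_INVCM
                        ) -> np.ndarray:
    """Superimpose zero-background Lorentz profiles over all modes.

    Returns absorption in a.u. (strength units per cm⁻¹) on the GHz grid;
    an empty mode set yields the zero spectrum.
    """
    if gamma_invcm <= 0:
        raise ValueError("gamma must be positive")
    grid = np.asarray(grid_ghz, dtype=float)
    x = grid / GHZ_PER_INVCM
    out = np.zeros_like(x)
    g = gamma_invcm
    for nu_k, s_k in zip(modes.frequencies_ghz, modes.strengths_au):
        xk = nu_k / GHZ_PER_INVCM
        out += s_k * x**2 * g / ((x**2 - xk**2) ** 2 + x**2 * g**2)
    return out


def filter_strong_modes(modes: ModeSet,
                        threshold_au: float = DEFAULT_STRENGTH_THRESHOLD_AU
                        ) -> ModeSet:
    """Keep modes with S_k strictly above the threshold, order preserved."""
    if threshold_au < 0:
        raise ValueError("threshold must be ≥ 0")
    return modes.subset(modes.strengths_au > threshold_au)


def aggregate_replicas(replica_modes: list[ModeSet], grid_ghz,
                       gamma_invcm: float = DEFAULT_GAMMA_INVCM,
                       threshold_au: float = DEFAULT_STRENGTH_THRESHOLD_AU):
    """Average replica spectra and report the strongest-resonance frequency.

    Returns ``(avg_spectrum, avg_filtered_spectrum, strongest_ghz)`` where
    the spectra are means over replicas on the common grid and
    ``strongest_ghz`` is the argmax of the filtered-mode average (NaN, with
    a warning, if no mode anywhere passes the filter).
    """
    if not replica_modes:
        raise ValueError("need at least one replica")
    grid = np.asarray(grid_ghz, dtype=float)
    full = np.mean([synthesize_spectrum(m, grid, gamma_invcm)
                    for m in replica_modes], axis=0)
    filtered = np.mean(
        [synthesize_spectrum(filter_strong_modes(m, threshold_au), grid,
                             gamma_invcm) for m in replica_modes], axis=0)
    if np.all(filtered == 0.0):
        warnings.warn("no mode exceeds the strength threshold in any "
                      "replica; strongest resonance undefined", stacklevel=2)
        strongest = float("nan")
    else:
        strongest = float(grid[np.argmax(filtered)])
    return full, filtered, strongest


class QuasiHarmonicModel:
    """Quasi-harmonic mode model for one or more trajectory replicas.

    Parameters
    ----------
    trajectories : Trajectory or list of Trajectory
        Replica trajectories over the same topology.
    align : bool
        Superpose frames onto the mean structure first (default True).
    """

    def __init__(self, trajectories, align: bool = True):
        if isinstance(trajectories, Trajectory):
            trajectories = [trajectories]
        if not trajectories:
            raise ValueError("need at least one trajectory")
        n = trajectories[0].n_atoms
        if any(t.n_atoms != n for t in trajectories):
            raise ValueError("replicas must share a topology")
        self.trajectories = list(trajectories)
        self.align = align

    def fit(self, rigid_rtol: float = RIGID_EIGVAL_RTOL
            ) -> "QuasiHarmonicResults":
        modesets = []
        for i, traj in enumerate(self.trajectories):
            if self.align:
                traj = align_frames(traj)
            fm = fluctuation_matrix(traj)
            modesets.append(modes_from_fluctuations(
                fm, traj.temperature_k, rigid_rtol=rigid_rtol, replica=i))
        return QuasiHarmonicResults(self, modesets)


class QuasiHarmonicResults:
    """Per-replica mode sets plus spectrum synthesis and aggregation."""

    def __init__(self, model: QuasiHarmonicModel, modesets: list[ModeSet]):
        self.model = model
        self.modesets = modesets

    @property
    def n_replicas(self) -> int:
        return len(self.modesets)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([m.to_frame() for m in self.modesets],
                         ignore_index=True)

    def average_spectrum(self, grid_ghz,
                         gamma_invcm: float = DEFAULT_GAMMA_INVCM,
                         threshold_au: float = DEFAULT_STRENGTH_THRESHOLD_AU):
        return aggregate_replicas(self.modesets, grid_ghz, gamma_invcm,
                                  threshold_au)

    def strongest_resonance_ghz(
            self, grid_ghz, gamma_invcm: float = DEFAULT_GAMMA_INVCM,
            threshold_au: float = DEFAULT_STRENGTH_THRESHOLD_AU) -> float:
        return self.average_spectrum(grid_ghz, gamma_invcm, threshold_au)[2]

    def summary(self, threshold_au: float = DEFAULT_STRENGTH_THRESHOLD_AU
                ) -> str:
        lines = ["Quasi-harmonic mode analysis", "=" * 54,
                 f"replicas               {self.n_replicas}",
                 f"atoms                  {self.modesets[0].topology.n_atoms}"]
        for m in self.modesets:
            strong = filter_strong_modes(m, threshold_au)
            lines.append(
                f"replica {m.replica}: {len(m)} modes "
                f"({m.n_discarded_rigid} rigid-body dof removed), "
                f"{len(strong)} with S > {threshold_au:g} a.u.")
        return "\n".join(lines)

    def plot_spectrum(self, grid_ghz,
                      gamma_invcm: float = DEFAULT_GAMMA_INVCM,
                      threshold_au: float = DEFAULT_STRENGTH_THRESHOLD_AU,
                      ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        full, filtered, strongest = self.average_spectrum(
            grid_ghz, gamma_invcm, threshold_au)
        ax.plot(grid_ghz, full, label="all modes")
        ax.plot(grid_ghz, filtered,
                label=f"S > {threshold_au:g} a.u.")
        if np.isfinite(strongest):
            ax.axvline(strongest, color="r", ls="--",
                       label=f"strongest: {strongest:.0f} GHz")
        ax.set_xlabel("frequency (GHz)")
        ax.set_ylabel("absorption (a.u.)")
        ax.legend()
        return ax
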