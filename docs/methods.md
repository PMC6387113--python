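# Methods

## Measurement model and sign convention

The spectral branch models a frequency-swept THz beam crossing a grating
of liquid-filled channels (width `w`, pitch `p`, depth `d`).  Only the
fraction `f = w/(w+p)` of the beam path crosses liquid, so the effective
absorption path is `f·d` and the Lambert–Beer inversion reads
`α = −ln T/(f·d)` with `d` converted μm→cm at a single point
(`constants.UM_TO_CM`).  The relation is sometimes written without the
minus sign, with the sign folded into an inverted ratio; this package
adopts the explicit positive-absorption convention so that `T < 1` maps
to `α > 0`, and rejects fitted features whose *background* `α_b` comes
out negative — physical attenuation cannot be negative, so such fits are
baseline undulations masquerading as peaks.

Transmissivity ratios are only formed on identical frequency grids;
resampling is refused rather than applied silently, because ratio spectra
amplify interpolation artifacts.  Water-vapor windows (±20 GHz around
556, 752, 990 GHz, closed intervals — boundaries excluded, erring toward
exclusion) are masked, never deleted: curves keep the full instrument
grid and a validity mask that propagates to the fitter.

## Lorentz signature fitting

The four-parameter profile
`α(ν) = α_b + S ν² γ/((ν²−ν_k²)² + ν² γ²)` is evaluated with ν, ν_k, γ in
wavenumbers so the units close (S in cm⁻², α in cm⁻¹); centers and widths
are reported in GHz.  γ numerically equals the FWHM — exactly so for this
profile, which the `numeric_fwhm` root-finder confirms.

Fitting uses `lmfit` least squares (xtol/ftol/gtol 1e-14) with a
heuristic start (center at the window extremum, crude half-width, median
background, height·γ strength) and a 5-point jittered multi-start under a
fixed seed, so fits are deterministic.  One-sigma uncertainties are the
square root of the covariance diagonal scaled by reduced chi-square (the
most common convention).  Candidate windows default to ±6·γ_init around
detected peaks; both the windows and whether `α_b` floats are
configurable, since neither is uniquely dictated by the problem.  At
least 8 valid points are required per window; non-convergence is flagged,
never silently replaced.

## Quasi-harmonic analysis

Frames are superposed onto the iteratively refined mean structure by
mass-weighted least squares (Kabsch, implemented as batched 3×3 SVDs so
10⁵-frame trajectories align in seconds); collinear structures trigger
translation-only alignment with a warning.  The mass-weighted covariance
`σ` is then projected onto the orthogonal complement of the
translation/rotation basis built from the mean structure and
diagonalised there.  Projection removes exactly the rigid-body subspace
(6 dimensions, 5 for collinear molecules) regardless of how much residual
rigid variance alignment left behind, so retained modes + discarded
rigid degrees of freedom always equal 3N.  Eigenvalues below 10⁻¹² of the
largest are treated as numerically zero and dropped with a warning
(rank-deficient sampling).

Frequencies follow from `ω_k = √(k_B T/λ_k)`.  The internal unit system
is amu, Å, ps and elementary charge (`k_B = 0.8314 amu·Å²·ps⁻²·K⁻¹`);
frequencies are reported in GHz, with GHz↔cm⁻¹ via 29.9792458.  Default
temperature is 298 K.

Because the eigenvectors are unit-norm in mass-weighted coordinates, the
Cartesian displacement of atom i in mode k is `a_ki/√m_i`; the dipole
derivative is `p_k = Σ e_i a_ki/√m_i` and the oscillator strength
`S_k = |p_k|²/Σ m_i (a_ki/√m_i)²`, whose denominator reduces to 1 but is
kept explicit so alternative normalisations remain testable.  The
absolute normalisation of the strength unit ("a.u.") is conventional;
this package uses e²/amu and keeps the 30 a.u. strong-mode reporting
threshold configurable.  Mode spectra superimpose zero-background Lorentz
profiles with γ = 0.6 cm⁻¹ by default — the mean FWHM of the accepted
experimental fits (16.7 and 20.5 GHz → 0.62 cm⁻¹, rounding to 0.6).

## Synthetic data: what it emulates and what it does not

`gen_spectrometer_run` builds a smooth baseline pinned to the
spectrometer's dynamic-range anchors (61 dB at 400 GHz, 54 dB at
700 GHz, 43 dB at 1000 GHz over the noise floor, quadratic in between),
multiplies narrow vapor dips into *all three* runs (shared atmospheric
path: they cancel exactly in noiseless ratios and imperfectly once
per-run multiplicative noise is added, reproducing the characteristic
ratio fluctuations near the vapor lines), attenuates the buffer run by a
flat background α and the sample run by a full Lorentz resonance.  It
does not model phase, étalon fringes, or detector drift.

`gen_harmonic_trajectory` draws frames i.i.d. from the stationary
Gaussian with covariance `k_B T·F⁺` in mass-weighted coordinates — the
exact inverse of the relation the analysis assumes.  This is the key
idealisation: real production dynamics are time-correlated and
anharmonic, so passing tests demonstrate correctness of the estimator,
not fidelity of any force field.  Optional per-frame rigid-body jitter
(translation in Å, rotation in rad) exercises the alignment stage.  All
randomness flows from one master seed; replica seeds are the children of
`SeedSequence(master).spawn(n)`.

Benchmark systems use coarse-grained beads (~150–350 amu,
nucleotide-scale masses) rather than atomistic hydrogens so that 298 K
fluctuations stay small against the molecular extent and the Eckart-frame
alignment stays in its linear regime; this matches the physical picture
of the THz band, where the relevant oscillators are base-scale units
joined by hydrogen bonds (k ≈ 0.025 mdyne/Å, μ ≈ 100 amu → ≈618 GHz).
Two small-system subtleties are handled explicitly: for 3 atoms the
out-of-plane dipole pattern is purely rotational (an exact degeneracy),
so degenerate patterns are dropped and a 3-bead system has two active
modes; and near-collinear random geometries are rejection-sampled away
because they couple rotation and vibration beyond the harmonic picture.

In `random_harmonic_system` the dipole coupling is deliberately carried
by three infrared-active modes planted at well-separated spectral
positions, all other modes being exactly silent.  Real vibrational
spectra share this few-active-modes structure, and it keeps the planted
strengths statistically identifiable: with silent spectral neighbours,
sampling-induced eigenvector mixing perturbs an active mode's strength
only at second order.  Strength-recovery checks compare modes carrying at
least 10% of the maximum planted strength — below that, the planted
values sit at the estimator's noise floor and relative error is not
meaningful.

## Statistical resolution and chosen problem sizes

A sample-covariance eigenvalue estimated from n i.i.d. frames has
relative standard error √(2/n), so a mode frequency carries ~½·√(2/n).
At the 450-frame production scale this is ≈3.3% — ≈27 GHz at 823 GHz —
which is why a ten-replica averaged spectrum locates its strongest mode
only to a few tens of GHz at that scale (the test suite documents this
directly).  Planted-truth recovery tests that require grid-step accuracy
therefore use 10⁵ frames per replica (averaged-center error ≈0.6 GHz on
a 1 GHz synthesis grid) and 10⁴ frames where 3%/10% tolerances suffice;
these sizes were fixed by this error analysis.  The synthesis grid for
theoretical spectra defaults to 1 GHz steps over 400–1000 GHz, ample for
profiles with ≈18 GHz FWHM.

## Aptamer bookkeeping

Molecular weight uses the vendor-standard average-mass formula for
desalted synthetic ssDNA, `MW = 313.21·nA + 304.2·nT + 289.18·nC +
329.21·nG − 61.96` (no 5′-phosphate); the mass convention is an
assumption, chosen because it reproduces the vendor-quoted 18167 g/mol
for the packaged sequence to within 1 g/mol.  Under the same no-terminal-
phosphate convention an n-mer carries n−1 backbone charges, hence n−1
monovalent counterions for neutrality.

## Known limitations

* The quasi-harmonic branch analyses solute-only topologies; explicit
  solvent dipole contributions and anharmonic corrections are out of
  scope, as is running force-field MD itself.
* Single-peak fitting only; overlapping resonances or Drude/Debye
  backgrounds are not modelled.
* The spectrometer emulation is incoherent (power-only); phase and
  étalon effects present in real hardware are neither generated nor
  corrected.
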