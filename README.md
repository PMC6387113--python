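# thzmodes

Terahertz absorption signatures of biomolecules dissolved in aqueous
buffer, probed through a microfluidic channel array — and their
theoretical counterpart, quasi-harmonic vibrational modes computed from
molecular trajectories.

The package is aimed at spectroscopists and molecular modellers working on
label-free THz detection of nucleic acids in solution.  Its concrete
subject is a 60-nt single-stranded DNA aptamer against the cyanotoxin
microcystin (18167 g/mol, neutralised by 59 Na⁺), which shows a
reproducible absorption signature near 830 GHz when dissolved in TE
buffer inside 2.4 μm silicon microchannels.

## What it computes

**Spectral branch.**  Three power sweeps are recorded on one frequency
grid: blank chip `P_B(ν)`, buffer reference `P_R(ν)` and sample `P_S(ν)`.
Transmissivities `T = P/P_B` are formed pointwise, windows of ±20 GHz
around the atmospheric water-vapor lines (556, 752, 990 GHz) are masked,
and the absorption coefficient follows from the Lambert–Beer law for a
channel/pitch grating,

```
α(ν) = −ln T_S(ν) / (f·d),        f = w/(w+p) = 0.6,   d = 2.4 μm,
```

with `f` the liquid fill factor.  Candidate features are fitted with the
four-parameter Lorentz oscillator profile

```
α(ν) = α_b + S_k ν² γ / ((ν² − ν_k²)² + ν² γ²)
```

(all spectral quantities converted to cm⁻¹ inside the model; γ numerically
equals the FWHM).  A fit is accepted as a genuine resonance only if its
background attenuation `α_b` is non-negative; a negative background
violates the optical absorption law and marks a baseline artifact.

**Quasi-harmonic branch.**  From trajectory frames of an `N`-atom solute,
the mass-weighted fluctuation matrix `σ = ⟨(q−⟨q⟩)(q−⟨q⟩)ᵀ⟩ = k_B T·F⁻¹`
is diagonalised after removing the six rigid-body degrees of freedom; each
eigenvalue λ_k gives a mode frequency `ω_k = √(k_B T/λ_k)` and the
dipole-derivative oscillator strength

```
p_k = Σ_i e_i a_ki / √m_i,        S_k = |p_k|² / Σ_i m_i (a_ki/√m_i)².
```

Mode spectra are synthesized by superimposing Lorentz profiles with
γ = 0.6 cm⁻¹, strengths below 30 a.u. are filtered for reporting, and
replica-averaged spectra yield the strongest-resonance frequency.

**Synthetic data.**  `thzmodes.synthetic` emulates both instruments with
exactly known ground truth: a 0.4–1.0 THz sweep at 350 MHz steps with the
spectrometer's 61/54/43 dB dynamic-range anchors, vapor dips and an
embedded Lorentz resonance; and Boltzmann-exact harmonic trajectories
(450 frames at 0.2 ps by default, ten replicas) drawn from `k_B T·F⁺`.

## Worked example

```python
from thzmodes import run_spectral_pipeline
from thzmodes.synthetic import SpectrometerConfig, gen_spectrometer_run

blank, buffer, sample = gen_spectrometer_run(SpectrometerConfig(noise=0.001, seed=1))
report = run_spectral_pipeline(blank, buffer, sample)
print(report.fits[0].summary())
```

```
Lorentz oscillator fit
======================================================
window           730.7–929.6 GHz  (455 points)
center                829.3 ± 0.0 GHz
strength              376.4 ± 1.8 cm⁻²
background             95.1 ± 0.7 cm⁻¹
FWHM (γ)               16.6 ± 0.1 GHz
residual norm           218
resonance        accepted
γ in 10–50 GHz   True
```

The generator embedded a resonance at 829.3 GHz with strength
377.3 cm⁻², background 94.3 cm⁻¹ and FWHM 16.7 GHz under 0.1% power
noise; the fitter recovers all four parameters, and the positive
background marks the feature as a genuine resonance.  The same objects
are available from the command line (`thzmodes simulate-spectra`,
`thzmodes fit`, `thzmodes aptamer-info`, …).

The trajectory branch mirrors this: plant one strongly polar 823 GHz mode
among silent ones, generate ten replicas, and read the strongest resonance
off the filtered, replica-averaged spectrum:

```python
from thzmodes import run_qh_pipeline
from thzmodes.synthetic import planted_polar_system, gen_replica_set, sweep_grid

system = planted_polar_system(n_atoms=10, n_frames=20000,
                              rigid_jitter_ang=0.3, rigid_jitter_rad=0.01)
replicas = gen_replica_set(system, 10, master_seed=0)
report = run_qh_pipeline(replicas, sweep_grid(400, 1000, 1.0))
print(report.results.summary())
print(f"strongest filtered resonance: {report.strongest_ghz:.0f} GHz")
```

```
Quasi-harmonic mode analysis
======================================================
replicas               10
atoms                  10
replica 0: 24 modes (6 rigid-body dof removed), 3 with S > 30 a.u.
...
strongest filtered resonance: 826 GHz
```

At 20 000 frames per replica the averaged estimate sits 3 GHz from the
planted 823 GHz — the residual is finite-sampling error of the covariance
eigenvalues, which shrinks as frames grow (see `docs/methods.md`).

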