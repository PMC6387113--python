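"""Unit system and physical constants.

Internal unit system for the trajectory branch: amu, Å, ps, elementary
charge.  Spectral quantities are stored in GHz; absorption coefficients in
cm⁻¹; Lorentz oscillator strengths in cm⁻² (experimental branch) or e²/amu
(quasi-harmonic branch, the package's "a.u.").  All conversions happen
through the constants below — nowhere else.
"""

#: Speed of light in cm·GHz: ν[GHz] / GHZ_PER_INVCM = wavenumber[cm⁻¹].
GHZ_PER_INVCM = 29.9792458

#: Boltzmann constant in amu·Å²·ps⁻²·K⁻¹ (CODATA 2018 k_B and m_u).
KB_AMU_A2_PS2 = 1.380649e-23 / (1.66053906660e-27 * 1e-20 / 1e-24)

#: 1 mdyne/Å expressed in amu·ps⁻² (mass-weighted force constant unit):
#: 1 mdyne/Å = 100 N/m; 1 N/m = 602.214076 amu/ps².
MDYNE_PER_A_IN_AMU_PS2 = 100.0 * (1.0 / 1.66053906660e-27) * 1e-24

#: μm → cm, the single place channel depths change units.
UM_TO_CM = 1e-4


def ghz_to_invcm(nu_ghz):
    """Frequency in GHz → wavenumber in cm⁻¹."""
    return nu_ghz / GHZ_PER_INVCM


def invcm_to_ghz(wavenumber):
    """Wavenumber in cm⁻¹ → frequency in GHz."""
    return wavenumber * GHZ_PER_INVCM
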