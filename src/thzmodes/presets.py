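"""Published reference values for the microcystin-aptamer THz study.

The four Lorentz fits reported for the dissolved 60-nt microcystin aptamer
(two candidate features per concentration), the instrument sweep settings,
and the spectrometer dynamic-range anchors.  These are literature inputs —
printed numbers, not values computed by this package — and are used to
seed synthetic runs and as oracles in round-trip tests.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lorentz import LorentzParams

__all__ = [
    "ReportedFit",
    "APTAMER_SIGNATURE_FITS",
    "SWEEP_START_GHZ",
    "SWEEP_STOP_GHZ",
    "SWEEP_STEP_GHZ",
    "DYNAMIC_RANGE_DB",
    "SYNTHESIS_GAMMA_INVCM",
]

#: Frequency sweep of the coherent photomixing spectrometer.
SWEEP_START_GHZ = 400.0
SWEEP_STOP_GHZ = 1000.0
SWEEP_STEP_GHZ = 0.35  # 350 MHz

#: Power-to-noise-floor ratio anchors of the spectrometer (dB at GHz).
DYNAMIC_RANGE_DB = {400.0: 61.0, 700.0: 54.0, 1000.0: 43.0}

#: Dissipative factor used to broaden theoretical mode spectra — the mean
#: FWHM of the two accepted signature fits, in wavenumbers.
SYNTHESIS_GAMMA_INVCM = 0.6


@dataclass(frozen=True)
class ReportedFit:
    """One published Lorentz fit row with one-sigma uncertainties."""

    params: LorentzParams
    center_err_ghz: float
    strength_err_invcm2: float
    background_err_invcm: float
    fwhm_err_ghz: float
    concentration_ug_per_ul: float


#: Published fits: keys name the candidate feature and DNA concentration.
APTAMER_SIGNATURE_FITS: dict[str, ReportedFit] = {
    "449GHz@0.92": ReportedFit(
        LorentzParams(449.1, 890.1, -345.9, 27.6), 0.1, 109.0, 64.7, 1.7, 0.92),
    "829GHz@0.92": ReportedFit(
        LorentzParams(829.3, 377.3, 94.3, 16.7), 0.1, 46.1, 38.7, 1.3, 0.92),
    "728GHz@0.23": ReportedFit(
        LorentzParams(728.5, 890.4, -346.2, 18.4), 0.1, 93.7, 80.8, 1.0, 0.23),
    "828GHz@0.23": ReportedFit(
        LorentzParams(828.3, 600.1, 111.0, 20.5), 0.2, 144.6, 106.1, 2.8, 0.23),
}
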