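"""End-to-end orchestration of the two analysis branches.

Spectral branch: blank/buffer/sample power spectra → transmissivities →
water-vapor masking → Lambert–Beer absorption → candidate windows →
Lorentz fits → acceptance flags → tabular report.

Quasi-harmonic branch: trajectory replicas → alignment → fluctuation
matrices → mode sets → strength filtering → γ-broadened replica-averaged
spectrum → strongest-resonance frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_widths

from . import io as tio
from .lorentz import LorentzModel, LorentzResults
from .quasiharmonic import (DEFAULT_GAMMA_INVCM,
                            DEFAULT_STRENGTH_THRESHOLD_AU,
                            QuasiHarmonicModel, QuasiHarmonicResults,
                            Trajectory)
from .spectra import (AbsorptionCurve, ChipGeometry, PowerSpectrum,
                      DEFAULT_VAPOR_HALF_WIDTH_GHZ, WATER_VAPOR_LINES_GHZ,
                      absorption_coefficient, compute_transmissivity)

__all__ = [
    "candidate_windows",
    "run_spectral_pipeline",
    "run_qh_pipeline",
    "SpectralReport",
    "QHReport",
]

logger = logging.getLogger(__name__)


def candidate_windows(curve: AbsorptionCurve, max_candidates: int = 5,
                      prominence: float | None = None,
                      halfwidth_factor: float = 6.0) -> list[tuple[float,
                                                                   float]]:
    """Locate candidate resonance windows on the valid part of a curve.

    Peaks are found on the unmasked points; each window spans
    ±``halfwidth_factor`` times the crude half-maximum width around the
    peak.  Default prominence: 20% of the peak-to-median contrast.
    """
    nu = curve.frequencies_ghz[curve.valid]
    a = curve.alpha_invcm[curve.valid]
    if nu.size < 8:
        return []
    if prominence is None:
        contrast = float(np.max(a) - np.median(a))
        if contrast <= 0:
            return []
        prominence = 0.2 * contrast
    peaks, props = find_peaks(a, prominence=prominence)
    if peaks.size == 0:
        return []
    order = np.argsort(props["prominences"])[::-1][:max_candidates]
    peaks = peaks[order]
    widths_idx = peak_widths(a, peaks, rel_height=0.5)[0]
    step = float(np.median(np.diff(nu)))
    windows = []
    for p, w in zip(peaks, widths_idx):
        gamma_init = max(w * step, 2.0 * step)
        half = halfwidth_factor * gamma_init
        windows.append((float(nu[p] - half), float(nu[p] + half)))
    return windows


@dataclass
class SpectralReport:
    """Products of the spectral pipeline."""

    transmissivity_reference: object
    transmissivity_sample: object
    absorption: AbsorptionCurve
    fits: list[LorentzResults]
    table: pd.DataFrame

    @property
    def accepted(self) -> list[LorentzResults]:
        return [f for f in self.fits if f.accepted]


def run_spectral_pipeline(blank: PowerSpectrum, buffer: PowerSpectrum,
                          sample: PowerSpectrum,
                          geometry: ChipGeometry = ChipGeometry(),
                          vapor_lines=WATER_VAPOR_LINES_GHZ,
                          vapor_half_width: float =
                          DEFAULT_VAPOR_HALF_WIDTH_GHZ,
                          windows: list[tuple[float, float]] | None = None,
                          max_candidates: int = 5,
                          outdir=None) -> SpectralReport:
    """Run the full signature-recognition chain and assemble the report.

    ``windows`` overrides automatic candidate detection.  If ``outdir`` is
    given, the absorption curve and the fit report are written there.
    """
    logger.info("spectral pipeline: geometry f=%.3f d=%.2f μm, vapor "
                "lines %s ± %.0f GHz", geometry.fill_factor,
                geometry.depth_um, tuple(vapor_lines), vapor_half_width)
    t_r = compute_transmissivity(buffer, blank).mask_vapor(
        vapor_lines, vapor_half_width)
    t_s = compute_transmissivity(sample, blank).mask_vapor(
        vapor_lines, vapor_half_width)
    curve = absorption_coefficient(t_s, geometry)
    if windows is None:
        windows = candidate_windows(curve, max_candidates=max_candidates)
        logger.info("detected %d candidate window(s)", len(windows))
    fits = []
    for win in windows:
        try:
            res = LorentzModel(curve, win).fit()
        except (ValueError, RuntimeError) as exc:
            logger.warning("fit stage failed in window %s: %s", win, exc)
            continue
        logger.info("window %.1f–%.1f GHz: center %.1f GHz, %s", *win,
                    res.params.center_ghz,
                    "accepted" if res.accepted else
                    f"rejected ({res.rejection_reason})")
        fits.append(res)
    table = pd.DataFrame([f.to_dict() for f in fits])
    report = SpectralReport(t_r, t_s, curve, fits, table)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tio.write_fit_report(outdir / "fit_report.csv", fits)
        pd.DataFrame({
            "frequency_ghz": curve.frequencies_ghz,
            "alpha_invcm": curve.alpha_invcm,
            "valid": curve.valid.astype(int),
        }).to_csv(outdir / "absorption.csv", index=False,
                  float_format="%.10g")
    return report


@dataclass
class QHReport:
    """Products of the quasi-harmonic pipeline."""

    results: QuasiHarmonicResults
    mode_table: pd.DataFrame
    grid_ghz: np.ndarray
    average_spectrum: np.ndarray
    filtered_spectrum: np.ndarray
    strongest_ghz: float


def run_qh_pipeline(trajectories: list[Trajectory], grid_ghz,
                    gamma_invcm: float = DEFAULT_GAMMA_INVCM,
                    threshold_au: float = DEFAULT_STRENGTH_THRESHOLD_AU,
                    align: bool = True, outdir=None) -> QHReport:
    """Quasi-harmonic mode analysis over replicas with spectrum synthesis.

    Writes the per-replica mode table and the averaged spectra (with a
    provenance header) when ``outdir`` is given.  If the strength filter
    removes every mode, a warning is logged and the unfiltered spectrum is
    still produced.
    """
    grid = np.asarray(grid_ghz, dtype=float)
    results = QuasiHarmonicModel(trajectories, align=align).fit()
    full, filtered, strongest = results.average_spectrum(
        grid, gamma_invcm, threshold_au)
    if not np.isfinite(strongest):
        logger.warning("strength threshold %.3g a.u. removed every mode; "
                       "unfiltered spectrum still written", threshold_au)
    else:
        logger.info("strongest filtered resonance at %.1f GHz", strongest)
    report = QHReport(results, results.to_frame(), grid, full, filtered,
                      strongest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = (f"# quasi-harmonic pipeline: replicas="
                  f"{results.n_replicas} gamma_invcm={gamma_invcm:g} "
                  f"threshold_au={threshold_au:g}\n")
        with open(outdir / "modes.csv", "w") as fh:
            fh.write(header)
            report.mode_table.to_csv(fh, index=False, float_format="%.10g")
        with open(outdir / "spectrum.csv", "w") as fh:
            fh.write(header)
            pd.DataFrame({
                "frequency_ghz": grid,
                "absorption_au": full,
                "absorption_filtered_au": filtered,
            }).to_csv(fh, index=False, float_format="%.10g")
    return report
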