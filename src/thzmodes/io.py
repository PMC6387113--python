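"""Readers and writers for the plain-text formats the pipelines exchange.

Power spectra: two-column CSV (frequency_GHz, power), optional header.
Topology: delimited table with columns atom, mass_amu, charge_e.
Coordinates: multi-frame XYZ in Å (via MDAnalysis).
Mode tables and fit reports: CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .quasiharmonic import ModeSet, Topology, Trajectory
from .spectra import PowerSpectrum

__all__ = [
    "read_power_spectrum",
    "write_power_spectrum",
    "read_topology",
    "write_topology",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "write_mode_table",
    "write_fit_report",
]


def read_power_spectrum(path, role: str = "sample") -> PowerSpectrum:
    """Read a two-column (frequency_GHz, power) CSV; header optional."""
    df = pd.read_csv(path, comment="#", header=None, skip_blank_lines=True)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    # tolerate a header row of non-numeric labels
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    df = df.astype(float)
    return PowerSpectrum(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                         role)


def write_power_spectrum(path, spectrum: PowerSpectrum) -> None:
    df = pd.DataFrame({"frequency_ghz": spectrum.frequencies_ghz,
                       "power": spectrum.power})
    with open(path, "w") as fh:
        fh.write(f"# role: {spectrum.role}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_topology(path) -> Topology:
    """Read a delimited table with columns atom, mass_amu, charge_e."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        m = df[cols["mass_amu"]].to_numpy(dtype=float)
        q = df[cols["charge_e"]].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(
            f"{path}: need columns mass_amu and charge_e") from exc
    return Topology(m, q)


def write_topology(path, topology: Topology, names=None) -> None:
    n = topology.n_atoms
    df = pd.DataFrame({
        "atom": names if names is not None else [f"B{i}" for i in range(n)],
        "mass_amu": topology.masses_amu,
        "charge_e": topology.charges_e,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_xyz_trajectory(path, traj: Trajectory, names=None) -> None:
    """Write frames as multi-frame XYZ (Å)."""
    import MDAnalysis as mda

    n = traj.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("names",
                       names if names is not None else ["C"] * n)
    u.load_new(np.asarray(traj.coords, dtype=np.float32), order="fac")
    with mda.Writer(str(path), n) as writer:
        for _ in u.trajectory:
            writer.write(u.atoms)


def read_xyz_trajectory(path, topology: Topology, dt_ps: float = 0.2,
                        temperature_k: float = 298.0) -> Trajectory:
    """Read a multi-frame XYZ file onto an existing topology."""
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    coords = np.stack([u.atoms.positions.copy().astype(float)
                       for _ in u.trajectory])
    return Trajectory(topology, coords, dt_ps=dt_ps,
                      temperature_k=temperature_k)


def write_mode_table(path, modesets: list[ModeSet]) -> None:
    """CSV mode table: mode index, freq_GHz, strength_au, replica."""
    df = pd.concat([m.to_frame() for m in modesets], ignore_index=True)
    df.to_csv(path, index=False, float_format="%.10g")


def write_fit_report(path, results, fmt: str | None = None) -> None:
    """Serialise Lorentz fit results as CSV or JSON (by extension)."""
    rows = [r.to_dict() for r in results]
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "json":
        path.write_text(json.dumps(rows, indent=2) + "\n")
    else:
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
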