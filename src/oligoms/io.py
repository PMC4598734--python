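"""Readers and writers for the plain-text formats the pipeline speaks.

Peak lists, mobilograms, calibrant tables and reports travel as
delimited text with mandatory header rows (units in the headers);
species definitions and pipeline settings as YAML; profile spectra may
optionally arrive as mzML. Malformed rows are reported with their line
number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrantIon
from .ion_grid import PeptideSpecies
from .mobility import Mobilogram

__all__ = [
    "read_peaks",
    "write_peaks",
    "read_mobilogram",
    "write_mobilogram",
    "read_calibrants",
    "write_calibrants",
    "read_species_config",
    "read_profile_mzml",
    "centroid_profile",
]


def read_peaks(path: str | Path) -> list[tuple[float, float, float | None]]:
    """Peak list: columns ``mz,intensity[,spacing]``, one header row.

    An empty spacing field (or a missing column) means the isotopologue
    spacing was not resolved for that peak.
    """
    path = Path(path)
    rows: list[tuple[float, float, float | None]] = []
    with open(path) as fh:
        header = fh.readline()
        sep = "\t" if "\t" in header else ","
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep)
            try:
                mz = float(parts[0])
                intensity = float(parts[1])
                spacing = (
                    float(parts[2])
                    if len(parts) > 2 and parts[2].strip() != ""
                    else None
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed peak row {line!r}"
                ) from exc
            rows.append((mz, intensity, spacing))
    return rows


def write_peaks(
    path: str | Path, peaks: Sequence[tuple[float, float, float | None]]
) -> None:
    with open(path, "w") as fh:
        fh.write("mz_Th,intensity_counts,spacing_Th\n")
        for mz, inten, spacing in peaks:
            s = "" if spacing is None else f"{spacing:.6f}"
            fh.write(f"{mz:.6f},{inten:.6f},{s}\n")


def read_mobilogram(path: str | Path) -> Mobilogram:
    """Mobilogram: ``# channel: <label>`` comment, then drift_ms,intensity."""
    path = Path(path)
    channel = ""
    drift, inten = [], []
    spacings: list[tuple[float, float]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "channel:" in line:
                    channel = line.split("channel:", 1)[1].strip()
                elif "peak_spacing:" in line:
                    td_s, sp_s = line.split("peak_spacing:", 1)[1].split(",")
                    spacings.append((float(td_s), float(sp_s)))
                continue
            if line[0].isalpha():
                if not header_seen:  # the single column-header row
                    header_seen = True
                    continue
                raise ValueError(
                    f"{path}:{lineno}: malformed mobilogram row {line!r}"
                )
            parts = line.replace("\t", ",").split(",")
            try:
                drift.append(float(parts[0]))
                inten.append(float(parts[1]))
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed mobilogram row {line!r}"
                ) from exc
    return Mobilogram(np.array(drift), np.array(inten), channel=channel,
                      peak_spacings=spacings or None)


def write_mobilogram(path: str | Path, mob: Mobilogram) -> None:
    with open(path, "w") as fh:
        fh.write(f"# channel: {mob.channel}\n")
        for td, spacing in mob.peak_spacings or []:
            fh.write(f"# peak_spacing: {td:.6f},{spacing:.6f}\n")
        fh.write("drift_ms,intensity_counts\n")
        for t, y in zip(mob.drift_time, mob.intensity):
            fh.write(f"{t:.6f},{y:.6f}\n")


def read_calibrants(path: str | Path) -> list[CalibrantIon]:
    """Calibrant CSV: protein,charge,mass,ccs_ref,drift_time."""
    df = pd.read_csv(path)
    required = {"protein", "charge", "mass", "ccs_ref", "drift_time"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        CalibrantIon(
            protein=str(r.protein), charge=int(r.charge), mass=float(r.mass),
            ccs_ref=float(r.ccs_ref), drift_time=float(r.drift_time),
        )
        for r in df.itertuples()
    ]


def write_calibrants(path: str | Path, ions: Sequence[CalibrantIon]) -> None:
    pd.DataFrame(
        [
            {
                "protein": i.protein, "charge": i.charge, "mass": i.mass,
                "ccs_ref": i.ccs_ref, "drift_time": i.drift_time,
            }
            for i in ions
        ]
    ).to_csv(path, index=False)


def read_species_config(path: str | Path) -> list[PeptideSpecies]:
    """YAML species definitions: ``species: [{id:, sequence:}, ...]``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc.get("species", doc) if isinstance(doc, dict) else doc
    out = []
    for entry in entries:
        out.append(PeptideSpecies.from_sequence(entry["id"], entry["sequence"]))
    if not out:
        raise ValueError(f"{path}: no species defined")
    return out


def read_profile_mzml(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """First spectrum of an mzML file as (m/z, intensity) arrays."""
    from pyteomics import mzml

    with mzml.read(str(path)) as reader:
        for spectrum in reader:
            return (
                np.asarray(spectrum["m/z array"], dtype=float),
                np.asarray(spectrum["intensity array"], dtype=float),
            )
    raise ValueError(f"{path}: no spectra found")


def centroid_profile(
    mz: np.ndarray,
    intensity: np.ndarray,
    min_rel_height: float = 0.01,
) -> list[tuple[float, float]]:
    """Local-maximum centroiding of a profile spectrum (utility).

    Returns (m/z, height) of maxima above ``min_rel_height`` of the base
    peak, with a parabolic refinement of the apex position.
    """
    from scipy.signal import find_peaks

    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    idx, _ = find_peaks(intensity, height=min_rel_height * intensity.max())
    out = []
    for i in idx:
        if 0 < i < len(mz) - 1:
            y0, y1, y2 = intensity[i - 1 : i + 2]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            dm = (mz[i + 1] - mz[i - 1]) / 2
            out.append((float(mz[i] + shift * dm), float(y1)))
        else:
            out.append((float(mz[i]), float(intensity[i])))
    return out
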