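"""Theoretical ion grids and peak assignment for peptide oligomers.

Native ESI of an aggregating peptide produces ions ``[nM + zH]z+`` for
oligomer order ``n`` and charge ``z``. Ions sharing the ratio ``n/z`` fall
on (nearly) the same m/z channel, so a peak near a degenerate channel
(e.g. monomer 2+, dimer 4+, trimer 6+, tetramer 8+ of the same peptide)
cannot be assigned from its position alone. Two rules resolve this:

1. the spacing of the 13C isotopologue cluster equals
   ``(m13C - m12C) / z`` and therefore reveals the charge directly;
2. when the isotopologues are not resolved, a species is accepted only if
   ions of at least two consecutive charge states of that species are
   observed.

Covalent cross-linking shifts oligomer masses down by two hydrogen atoms
per bond formed, which this module models explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .constants import (
    C13_C12_DELTA,
    H_MASS_AVG,
    H_MASS_MONO,
    PROTON_MASS,
)

__all__ = [
    "PeptideSpecies",
    "OligomerIon",
    "PeakAssignment",
    "composition_from_sequence",
    "oligomer_mass",
    "oligomer_mz",
    "isotope_pattern",
    "infer_charge",
    "assign_peaks",
    "build_grid",
    "grid_to_frame",
]

_VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

# Conventional single-letter oligomer-order labels used in figure
# annotation: monomer, dimer, trimer, tetramer, pentamer, hexamer.
ORDER_LABELS = {1: "M", 2: "D", 3: "Tr", 4: "Te", 5: "P", 6: "Hx"}


def composition_from_sequence(sequence: str) -> dict[str, int]:
    """Elemental composition of an intact (free) peptide.

    Sums residue compositions and adds one water for the termini.

    Parameters
    ----------
    sequence : str
        One-letter amino-acid codes, canonical residues only.

    Returns
    -------
    dict mapping element symbol to atom count.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for pos, ch in enumerate(sequence):
        if ch not in _VALID_RESIDUES:
            raise ValueError(
                f"unknown residue code {ch!r} at position {pos} "
                f"(1-based {pos + 1}) in sequence"
            )
    comp = _pmass.Composition(sequence=sequence)
    return {el: int(n) for el, n in comp.items() if n}


@dataclass(frozen=True)
class PeptideSpecies:
    """A peptide with its elemental composition and masses.

    Use :meth:`from_sequence` to build one; masses are computed from the
    composition so the stored values are always self-consistent.
    """

    id: str
    sequence: str
    composition: dict[str, int]
    mono_mass: float
    avg_mass: float

    @classmethod
    def from_sequence(cls, id: str, sequence: str) -> "PeptideSpecies":
        comp = composition_from_sequence(sequence)
        mono = _pmass.calculate_mass(composition=_pmass.Composition(comp))
        avg = _pmass.calculate_mass(
            composition=_pmass.Composition(comp), average=True
        )
        return cls(id=id, sequence=sequence, composition=comp,
                   mono_mass=mono, avg_mass=avg)

    def __post_init__(self) -> None:
        if self.mono_mass <= 0 or self.avg_mass <= 0:
            raise ValueError("masses must be positive")
        if self.mono_mass >= self.avg_mass:
            raise ValueError("monoisotopic mass must be below average mass")
        if any(n < 0 for n in self.composition.values()):
            raise ValueError("composition counts must be non-negative")


def oligomer_mass(
    species: PeptideSpecies,
    order_n: int,
    *,
    crosslinked: bool = False,
    n_bonds: int = 0,
    mass_basis: str = "mono",
) -> float:
    """Neutral mass of an oligomer, Da.

    A covalently cross-linked oligomer loses two hydrogen atoms per bond
    formed, so its mass is ``n*M - n_bonds*2*m_H``.
    """
    if order_n < 1:
        raise ValueError("order_n must be >= 1")
    if crosslinked:
        if n_bonds < order_n - 1:
            raise ValueError(
                "a cross-linked n-mer needs at least n-1 bonds to be connected"
            )
    elif n_bonds != 0:
        raise ValueError("n_bonds must be 0 for a non-cross-linked oligomer")
    if mass_basis == "mono":
        m, m_h = species.mono_mass, H_MASS_MONO
    elif mass_basis == "avg":
        m, m_h = species.avg_mass, H_MASS_AVG
    else:
        raise ValueError(f"mass_basis must be 'mono' or 'avg', got {mass_basis!r}")
    return order_n * m - (n_bonds * 2 * m_h if crosslinked else 0.0)


def oligomer_mz(
    species: PeptideSpecies,
    order_n: int,
    charge_z: int,
    *,
    crosslinked: bool = False,
    n_bonds: int = 0,
    mass_basis: str = "mono",
) -> float:
    """Theoretical m/z of ``[nM - 2*n_bonds*H + zH+]z+``, Th."""
    if charge_z < 1:
        raise ValueError("charge_z must be >= 1")
    neutral = oligomer_mass(
        species, order_n, crosslinked=crosslinked, n_bonds=n_bonds,
        mass_basis=mass_basis,
    )
    return (neutral + charge_z * PROTON_MASS) / charge_z


@dataclass(frozen=True)
class OligomerIon:
    """A specific (order, charge) ion of a peptide species."""

    species: PeptideSpecies
    order_n: int
    charge_z: int
    crosslinked: bool = False
    n_bonds: int = 0
    mz_mono: float = field(default=0.0)
    mz_avg: float = field(default=0.0)
    isotope_spacing: float = field(default=0.0)

    @classmethod
    def create(
        cls,
        species: PeptideSpecies,
        order_n: int,
        charge_z: int,
        *,
        crosslinked: bool = False,
        n_bonds: int | None = None,
    ) -> "OligomerIon":
        if n_bonds is None:
            # minimally connected topology by default
            n_bonds = order_n - 1 if crosslinked else 0
        return cls(
            species=species,
            order_n=order_n,
            charge_z=charge_z,
            crosslinked=crosslinked,
            n_bonds=n_bonds,
            mz_mono=oligomer_mz(
                species, order_n, charge_z, crosslinked=crosslinked,
                n_bonds=n_bonds, mass_basis="mono",
            ),
            mz_avg=oligomer_mz(
                species, order_n, charge_z, crosslinked=crosslinked,
                n_bonds=n_bonds, mass_basis="avg",
            ),
            isotope_spacing=C13_C12_DELTA / charge_z,
        )

    @property
    def label(self) -> str:
        base = ORDER_LABELS.get(self.order_n, f"{self.order_n}-mer")
        return f"{self.species.id}:{base}+{self.charge_z}"

    @property
    def species_key(self) -> tuple[str, int, bool]:
        """Identity of the oligomer species, charge excluded."""
        return (self.species.id, self.order_n, self.crosslinked)


def build_grid(
    species: PeptideSpecies | Sequence[PeptideSpecies],
    max_order: int = 6,
    charge_range: tuple[int, int] = (1, 10),
    *,
    crosslinked: bool = False,
    n_bonds: dict[int, int] | None = None,
) -> list[OligomerIon]:
    """Enumerate theoretical ions for orders 1..max_order over a z range.

    ``n_bonds`` optionally overrides the default (minimally connected,
    n-1 bonds) cross-link count per oligomer order.
    """
    if isinstance(species, PeptideSpecies):
        species = [species]
    ions = []
    for sp in species:
        for n in range(1, max_order + 1):
            nb = None
            if crosslinked and n_bonds is not None:
                nb = n_bonds.get(n, n - 1)
            cl = crosslinked and n > 1
            for z in range(charge_range[0], charge_range[1] + 1):
                ions.append(
                    OligomerIon.create(sp, n, z, crosslinked=cl,
                                       n_bonds=nb if cl else None)
                )
    return ions


def grid_to_frame(ions: Iterable[OligomerIon]) -> pd.DataFrame:
    """Tabulate a grid for CSV export."""
    return pd.DataFrame(
        [
            {
                "species": ion.species.id,
                "n": ion.order_n,
                "z": ion.charge_z,
                "crosslinked": ion.crosslinked,
                "n_bonds": ion.n_bonds,
                "mz_mono": ion.mz_mono,
                "mz_avg": ion.mz_avg,
                "spacing": ion.isotope_spacing,
            }
            for ion in ions
        ]
    )


# ---------------------------------------------------------------------------
# Isotope patterns


def _element_neutron_pmf(element: str) -> np.ndarray:
    """Single-atom probability distribution over added neutron count."""
    isotopes = _pmass.nist_mass[element]
    base_mass = isotopes[0][0]
    pmf: dict[int, float] = {}
    for key, (iso_mass, abundance) in isotopes.items():
        if key == 0 or abundance == 0:
            continue
        k = int(round(iso_mass - base_mass))
        pmf[k] = pmf.get(k, 0.0) + abundance
    size = max(pmf) + 1
    out = np.zeros(size)
    for k, p in pmf.items():
        out[k] = p
    return out / out.sum()


def _pmf_power(pmf: np.ndarray, n: int, tol: float = 1e-12) -> np.ndarray:
    """n-fold self-convolution by binary exponentiation."""
    result = np.array([1.0])
    base = pmf
    while n:
        if n & 1:
            result = np.convolve(result, base)
            result = result[: np.max(np.nonzero(result > tol)) + 1]
        n >>= 1
        if n:
            base = np.convolve(base, base)
            base = base[: np.max(np.nonzero(base > tol)) + 1]
    return result


def isotope_pattern(
    composition: dict[str, int],
    charge_z: int = 1,
    resolution: float = 10000.0,
    *,
    min_abundance: float = 1e-4,
) -> list[tuple[float, float]]:
    """Aggregated (nominal-neutron) isotopologue pattern of an ion.

    Convolves per-element isotope distributions over added-neutron count
    and places isotopologue ``k`` at ``mz_mono + k * 1.003355 / z``; for
    peptides the spacing is dominated by 13C and this aggregated
    treatment is the standard approximation. Abundances are normalised to
    a maximum of 1 and the tail below ``min_abundance`` is dropped.

    ``resolution`` (m/dm at FWHM) is carried for profile synthesis and
    resolvability checks; it does not alter the centroid pattern.
    """
    if not composition or all(n == 0 for n in composition.values()):
        raise ValueError("composition must be non-empty")
    if charge_z < 1:
        raise ValueError("charge_z must be >= 1")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    dist = np.array([1.0])
    for element, count in composition.items():
        if count == 0:
            continue
        if count < 0:
            raise ValueError(f"negative count for element {element}")
        dist = np.convolve(dist, _pmf_power(_element_neutron_pmf(element), count))
    dist = dist / dist.max()
    mono_mz = (
        _pmass.calculate_mass(composition=_pmass.Composition(composition))
        + charge_z * PROTON_MASS
    ) / charge_z
    spacing = C13_C12_DELTA / charge_z
    pattern = [
        (mono_mz + k * spacing, a)
        for k, a in enumerate(dist)
        if a >= min_abundance
    ]
    return pattern


def spacing_resolvable(mz: float, charge_z: int, resolution: float) -> bool:
    """Whether adjacent isotopologues are separated at this resolution.

    The cluster peak FWHM is ``mz / resolution``; the isotopologue
    spacing must exceed it for the charge state to be readable.
    """
    return C13_C12_DELTA / charge_z > mz / resolution


# ---------------------------------------------------------------------------
# Peak assignment


def infer_charge(spacing: float, max_rel_dev: float = 0.15) -> int | None:
    """Charge state from isotopologue spacing, or None if implausible.

    The implied charge ``1.003355 / spacing`` must round to an integer
    within ``max_rel_dev`` relative deviation.
    """
    if spacing <= 0:
        return None
    z_est = C13_C12_DELTA / spacing
    z = int(round(z_est))
    if z < 1:
        return None
    if abs(z_est - z) / z > max_rel_dev:
        return None
    return z


@dataclass
class PeakAssignment:
    """Outcome of assigning one observed peak against an ion grid."""

    observed_mz: float
    observed_spacing: float | None
    candidates: list[OligomerIon]
    accepted: OligomerIon | None
    rule_used: str  # isotope_spacing | consecutive_charge_states | unassigned

    def __post_init__(self) -> None:
        if self.accepted is not None and self.accepted not in self.candidates:
            raise ValueError("accepted ion must be among the candidates")
        if self.rule_used == "isotope_spacing" and self.observed_spacing is None:
            raise ValueError(
                "isotope_spacing rule requires an observed spacing"
            )


def _ppm_match(observed: float, theoretical: float, tol_ppm: float) -> bool:
    return abs(observed - theoretical) <= theoretical * tol_ppm * 1e-6


def assign_peaks(
    peaks: Sequence[tuple],
    grid: Sequence[OligomerIon],
    tol_ppm: float = 20.0,
) -> list[PeakAssignment]:
    """Assign observed peaks to oligomer ions.

    Each peak is ``(mz, intensity)`` or ``(mz, intensity, spacing)``; a
    spacing of None means the isotopologues were not resolved.

    Assignment rules, applied per peak:

    * spacing measurable -> the charge is ``round(1.003355 / spacing)``
      and the candidate ion with that charge matching in m/z within
      ``tol_ppm`` is accepted (lowest order on ties);
    * spacing absent -> a candidate is accepted only if ions of at least
      two consecutive charge states of the same oligomer species are
      m/z-matched somewhere in the peak list (lowest order on ties);
    * otherwise the peak is left unassigned.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")

    # which (species, order, crosslinked, z) ions are m/z-matched anywhere
    matched_ions: set[tuple[tuple, int]] = set()
    for peak in peaks:
        mz = peak[0]
        for ion in grid:
            if _ppm_match(mz, ion.mz_mono, tol_ppm):
                matched_ions.add((ion.species_key, ion.charge_z))

    def has_consecutive(ion: OligomerIon) -> bool:
        key = ion.species_key
        z = ion.charge_z
        return ((key, z - 1) in matched_ions) or ((key, z + 1) in matched_ions)

    assignments = []
    for peak in peaks:
        mz = peak[0]
        spacing = peak[2] if len(peak) > 2 else None
        candidates = [
            ion for ion in grid if _ppm_match(mz, ion.mz_mono, tol_ppm)
        ]
        candidates.sort(key=lambda ion: (ion.order_n, ion.charge_z))
        accepted = None
        rule = "unassigned"
        z_inferred = infer_charge(spacing) if spacing is not None else None
        if z_inferred is not None:
            for ion in candidates:
                if ion.charge_z == z_inferred:
                    accepted = ion
                    rule = "isotope_spacing"
                    break
        if accepted is None:
            # spacing absent or uninformative: consecutive charge states
            for ion in candidates:
                if has_consecutive(ion):
                    accepted = ion
                    rule = "consecutive_charge_states"
                    break
        if accepted is None and spacing is not None and z_inferred is None:
            warnings.warn(
                f"peak at m/z {mz:.3f}: spacing {spacing:.5f} implies a "
                "non-integer charge; treated as absent",
                stacklevel=2,
            )
        assignments.append(
            PeakAssignment(
                observed_mz=mz,
                observed_spacing=spacing if z_inferred is not None else None,
                candidates=candidates,
                accepted=accepted,
                rule_used=rule if accepted is not None else "unassigned",
            )
        )
    return assignments
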