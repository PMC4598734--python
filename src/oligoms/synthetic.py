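"""Synthetic ESI-IM-MS data with known ground truth.

Every input the analysis pipeline consumes can be generated here with
its truth recorded alongside: centroid peak lists with isotopologue
spacing (including deliberately n/z-degenerate channels), mobilograms
for mobility-shared channels, T-wave calibrant tables, and toy atom
clouds with known cross-section properties. All generators are
deterministic given a seed.

The default ground truth emulates a low-molecular-weight sample of an
aggregating peptide: a monomer-dominated distribution with appreciable
dimer and trimer, trace tetramer through hexamer, three charge states
per order, and globular size scaling (Omega ~ n^(2/3)) linking oligomer
order to drift time through the same power-law model the calibration
stage fits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .calibration import CalibrantIon
from .constants import C13_C12_DELTA, PROTON_MASS, ABETA40_SEQUENCE
from .ion_grid import (
    ORDER_LABELS,
    OligomerIon,
    PeptideSpecies,
    spacing_resolvable,
)
from .mobility import GaussianComponent, Mobilogram, gaussian_fwhm
from .structure import AtomCloud

__all__ = [
    "GroundTruth",
    "default_ground_truth",
    "SyntheticChannel",
    "SyntheticSpectrum",
    "make_spectrum",
    "make_mobilogram",
    "make_calibration_set",
    "make_cluster",
]

_LABEL_TO_ORDER = {v: k for k, v in ORDER_LABELS.items()}


@dataclass
class GroundTruth:
    """Everything the generators need, and everything tests may check."""

    species_id: str = "Abeta40"
    sequence: str = ABETA40_SEQUENCE
    # species label -> population fraction (sums to 1)
    distribution: dict[str, float] = field(default_factory=dict)
    # species label -> {charge: weight} (weights sum to 1 per species)
    charge_weights: dict[str, dict[int, float]] = field(default_factory=dict)
    # calibration power law and drift-time correction
    cal_scale: float = 450.0
    cal_exponent: float = 0.55
    cal_c: float = 1.41
    gas: str = "N2"
    # globular size scaling: Omega(n) = ccs_monomer * n^(2/3), Angstrom^2
    ccs_monomer: float = 630.0
    # mobility peak width (FWHM, ms)
    peak_fwhm_ms: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.distribution:
            self.distribution = {
                "M": 0.45, "D": 0.30, "Tr": 0.15,
                "Te": 0.07, "P": 0.02, "Hx": 0.01,
            }
        total = sum(self.distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("distribution must sum to 1")
        if not self.charge_weights:
            self.charge_weights = {}
            for label in self.distribution:
                n = _LABEL_TO_ORDER[label]
                zs = [2, 3, 4] if n == 1 else [n + 2, n + 3, n + 4]
                self.charge_weights[label] = {
                    zs[0]: 0.25, zs[1]: 0.5, zs[2]: 0.25
                }
        for label, weights in self.charge_weights.items():
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"negative charge weight for {label}")

    @property
    def species(self) -> PeptideSpecies:
        return PeptideSpecies.from_sequence(self.species_id, self.sequence)

    def oligomer_ccs(self, order_n: int) -> float:
        return self.ccs_monomer * order_n ** (2.0 / 3.0)

    def drift_time_for(self, order_n: int, charge_z: int, mz: float) -> float:
        """Invert the truth power law: the t_d the instrument would show."""
        from .constants import GAS_MASS

        gas_mass = GAS_MASS[self.gas]
        ion_mass = mz * charge_z - charge_z * PROTON_MASS
        mu = ion_mass * gas_mass / (ion_mass + gas_mass)
        omega_prime = self.oligomer_ccs(order_n) / (
            charge_z * np.sqrt(1.0 / mu)
        )
        td_corr = (omega_prime / self.cal_scale) ** (1.0 / self.cal_exponent)
        return float(td_corr + self.cal_c * np.sqrt(mz) / 1000.0)

    def to_json(self) -> str:
        d = asdict(self)
        d["charge_weights"] = {
            k: {str(z): w for z, w in v.items()}
            for k, v in self.charge_weights.items()
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["charge_weights"] = {
            k: {int(z): w for z, w in v.items()}
            for k, v in d["charge_weights"].items()
        }
        return cls(**d)


def default_ground_truth(seed: int = 0) -> GroundTruth:
    return GroundTruth(seed=seed)


@dataclass
class SyntheticChannel:
    """One observed m/z channel with its generating truth."""

    mz: float
    intensity: float
    spacing: float | None
    # truth: species label -> fraction of this channel's intensity
    contributors: dict[str, float]
    # truth: contributing (label, order, charge) tuples
    ions: list[tuple[str, int, int]]

    @property
    def degenerate(self) -> bool:
        return len(self.contributors) > 1


@dataclass
class SyntheticSpectrum:
    channels: list[SyntheticChannel]
    truth: GroundTruth
    resolution: float

    def peak_list(self) -> list[tuple[float, float, float | None]]:
        """(mz, intensity, spacing) rows as the assignment stage expects."""
        return [(c.mz, c.intensity, c.spacing) for c in self.channels]


def make_spectrum(
    truth: GroundTruth,
    resolution: float = 10000.0,
    noise_frac: float = 0.05,
    mz_range: tuple[float, float] = (500.0, 5000.0),
    rng: np.random.Generator | None = None,
) -> SyntheticSpectrum:
    """Centroid peak list for one acquisition, degeneracies included.

    Each (species, charge) ion with positive weight produces a channel
    of intensity ``population * charge_weight`` with multiplicative
    log-normal noise. Channels closer in m/z than the instrument peak
    width (m/z / resolution) are merged: their intensities add, their
    isotopologue spacing becomes unreadable, and the truth records each
    contributor's share — exactly the situation that forces assignment
    into the mobility dimension. Spacing is reported only where the
    resolution separates adjacent isotopologues.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if not truth.distribution:
        raise ValueError("empty distribution")
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    sp = truth.species
    raw: list[tuple[float, float, str, int, int]] = []
    for label, pop in truth.distribution.items():
        if pop <= 0:
            continue
        n = _LABEL_TO_ORDER[label]
        for z, weight in truth.charge_weights[label].items():
            if weight <= 0:
                continue
            ion = OligomerIon.create(sp, n, z)
            if not mz_range[0] <= ion.mz_mono <= mz_range[1]:
                continue
            intensity = pop * weight * float(
                np.exp(rng.normal(0.0, noise_frac))
            )
            raw.append((ion.mz_mono, intensity, label, n, z))
    raw.sort(key=lambda r: r[0])
    channels: list[SyntheticChannel] = []
    i = 0
    while i < len(raw):
        group = [raw[i]]
        fwhm = raw[i][0] / resolution
        j = i + 1
        while j < len(raw) and raw[j][0] - group[-1][0] <= fwhm:
            group.append(raw[j])
            j += 1
        total = sum(g[1] for g in group)
        mz = sum(g[0] * g[1] for g in group) / total
        if len(group) == 1:
            _, _, label, n, z = group[0]
            spacing = (
                C13_C12_DELTA / z
                if spacing_resolvable(mz, z, resolution)
                else None
            )
            channels.append(
                SyntheticChannel(mz, total, spacing, {label: 1.0},
                                 [(label, n, z)])
            )
        else:
            contributors: dict[str, float] = {}
            for _, inten, label, _, _ in group:
                contributors[label] = contributors.get(label, 0.0) + inten / total
            channels.append(
                SyntheticChannel(
                    mz, total, None, contributors,
                    [(g[2], g[3], g[4]) for g in group],
                )
            )
        i = j
    return SyntheticSpectrum(channels=channels, truth=truth,
                             resolution=resolution)


def make_mobilogram(
    components: Sequence[GaussianComponent],
    k_im: float = 0.0,
    noise_sd: float = 0.0,
    axis: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    channel: str = "",
) -> Mobilogram:
    """Evaluate ``f_im`` on a drift-time axis and add Gaussian noise."""
    if axis is None:
        axis = np.arange(0.0, 14.0, 0.05)
    axis = np.asarray(axis, dtype=float)
    if not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be strictly increasing")
    y = np.full_like(axis, float(k_im))
    for comp in components:
        y = y + gaussian_fwhm(axis, comp.x_c, comp.w, comp.A)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        y = y + rng.normal(0.0, noise_sd, size=axis.size)
    return Mobilogram(axis, np.clip(y, 0.0, None), channel=channel)


def mobilogram_for_channel(
    truth: GroundTruth,
    channel: SyntheticChannel,
    noise_frac: float = 0.01,
    rng: np.random.Generator | None = None,
    axis: np.ndarray | None = None,
    resolution: float = 10000.0,
) -> tuple[Mobilogram, list[GaussianComponent]]:
    """Mobilogram of a (possibly shared) channel, truth components returned.

    Each contributing species gets a Gaussian at the drift time its size
    implies under the truth calibration, with area proportional to its
    intensity share. Noise s.d. is ``noise_frac`` of the tallest peak.

    The per-mobility-peak m/z spectra are emulated through the
    ``peak_spacings`` record: mobility separation leaves a clean
    single-species isotopologue cluster, so its spacing is taken as
    measurable down to half the instrument peak width (a congested
    summed spectrum requires a full peak width); peaks below that limit
    carry no spacing and force the downstream fallback rules.
    """
    comps = []
    spacings: list[tuple[float, float]] = []
    for label, n, z in channel.ions:
        frac = channel.contributors[label]
        # several ions of one species in a channel share its fraction
        n_same = sum(1 for l2, _, _ in channel.ions if l2 == label)
        x_c = truth.drift_time_for(n, z, channel.mz)
        comps.append(
            GaussianComponent(
                x_c=x_c,
                w=truth.peak_fwhm_ms,
                A=channel.intensity * frac / n_same,
                label=label,
            )
        )
        spacing = C13_C12_DELTA / z
        if spacing > 0.5 * channel.mz / resolution:
            spacings.append((x_c, spacing))
    peak_height = max(
        c.A * 2 * np.sqrt(np.log(2)) / (c.w * np.sqrt(np.pi)) for c in comps
    )
    mob = make_mobilogram(
        comps,
        k_im=0.0,
        noise_sd=noise_frac * peak_height,
        axis=axis,
        rng=rng,
        channel=f"mz={channel.mz:.1f}",
    )
    mob.peak_spacings = spacings or None
    return mob, comps


def make_calibration_set(
    scale: float,
    exponent: float,
    c: float,
    calibrant_table=None,
    noise_frac: float = 0.0,
    gas: str = "N2",
    rng: np.random.Generator | None = None,
) -> list[CalibrantIon]:
    """Calibrant ions whose drift times follow a known power law.

    Inverts ``Omega' = scale * t_d'^exponent`` for each reference ion,
    adds the mass-dependent time back, and applies multiplicative
    Gaussian noise of relative s.d. ``noise_frac`` to the drift times.
    """
    from .calibration import load_default_calibrants
    from .constants import GAS_MASS

    if calibrant_table is None:
        calibrant_table = load_default_calibrants()
    if len(calibrant_table) == 0:
        raise ValueError("calibrant table is empty")
    rng = rng if rng is not None else np.random.default_rng(0)
    gas_mass = GAS_MASS[gas]
    ions = []
    for row in calibrant_table.itertuples():
        mu = row.mass * gas_mass / (row.mass + gas_mass)
        omega_prime = row.ccs_ref / (row.charge * np.sqrt(1.0 / mu))
        td_corr = (omega_prime / scale) ** (1.0 / exponent)
        mz = (row.mass + row.charge * PROTON_MASS) / row.charge
        td = td_corr + c * np.sqrt(mz) / 1000.0
        if noise_frac > 0:
            td *= float(np.exp(rng.normal(0.0, noise_frac)))
        ions.append(
            CalibrantIon(
                protein=row.protein, charge=int(row.charge),
                mass=float(row.mass), ccs_ref=float(row.ccs_ref),
                drift_time=float(td),
            )
        )
    return ions


def make_cluster(
    kind: str,
    n_atoms: int = 50,
    scale: float = 5.0,
    seed: int = 0,
    atom_radius: float = 1.7,
) -> tuple[AtomCloud, float | None]:
    """Toy atom clouds with known cross-section behaviour.

    kinds:
      ``sphere``   — a single atom; analytic Omega = pi*(r + r_probe)^2
                     is returned (for the default helium probe).
      ``convex``   — overlapping atoms on a spherical shell, a
                     near-convex body (EHSS ~ PA).
      ``two_lobe`` — two well-separated dense lobes joined by a neck,
                     a concave body (EHSS > PA).

    Returns the cloud and the analytic Omega where one exists.
    """
    rng = np.random.default_rng(seed)
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if kind == "sphere":
        coords = np.zeros((1, 3))
        radii = np.full(1, atom_radius)
        from .constants import HELIUM_PROBE_RADIUS

        analytic = float(np.pi * (atom_radius + HELIUM_PROBE_RADIUS) ** 2)
        return AtomCloud(["C"], coords, radii, name="sphere"), analytic
    if kind == "convex":
        # Fibonacci shell: dense overlapping coverage of a sphere surface
        idx = np.arange(n_atoms) + 0.5
        phi = np.arccos(1 - 2 * idx / n_atoms)
        theta = np.pi * (1 + 5**0.5) * idx
        coords = scale * np.column_stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta),
             np.cos(phi)]
        )
    elif kind == "two_lobe":
        half = max(n_atoms // 2, 1)
        lobe_a = rng.normal(0.0, scale / 3, size=(half, 3))
        lobe_b = rng.normal(0.0, scale / 3, size=(n_atoms - half, 3))
        lobe_a[:, 0] -= 1.6 * scale
        lobe_b[:, 0] += 1.6 * scale
        coords = np.vstack([lobe_a, lobe_b])
    else:
        raise ValueError(f"unknown cluster kind {kind!r}")
    radii = np.full(len(coords), atom_radius)
    return AtomCloud(["C"] * len(coords), coords, radii, name=kind), None
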