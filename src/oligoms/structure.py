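"""Collision cross-sections of structural models by hard-sphere methods.

Two Monte Carlo estimators of the orientation-averaged collision
cross-section Omega of an atomic model, both treating atoms as hard
spheres of van der Waals radius inflated by the buffer-gas probe radius:

* projection approximation (PA): the average shadow area of the model
  over random orientations — a strict lower bound;
* exact hard-sphere scattering (EHSS): a trajectory calculation in which
  each incoming gas atom reflects specularly off the spheres, possibly
  several times, and contributes the momentum-transfer weight
  ``1 - cos(chi)`` with chi its total deflection angle. Multiple
  scattering in concave regions makes EHSS >= PA, with equality for
  convex bodies.

Both estimators report a Monte Carlo standard error and are reproducible
given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.spatial.transform import Rotation

from .constants import BONDI_VDW_RADIUS, DEFAULT_VDW_RADIUS, HELIUM_PROBE_RADIUS

__all__ = [
    "AtomCloud",
    "read_structure",
    "ccs_projection",
    "ccs_ehss",
    "ensemble_ccs",
    "compare_models",
]


@dataclass
class AtomCloud:
    """Atomic coordinates with hard-sphere radii."""

    elements: list[str]
    coords: np.ndarray  # (N, 3) Angstrom
    radii: np.ndarray  # (N,) Angstrom
    name: str = "model"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        if len(self.coords) < 1:
            raise ValueError("cloud needs at least one atom")
        if len(self.radii) != len(self.coords):
            raise ValueError("radii and coordinates length mismatch")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.coords)

    def translated(self, shift: np.ndarray) -> "AtomCloud":
        return AtomCloud(self.elements, self.coords + np.asarray(shift),
                         self.radii, self.name)

    def rotated(self, rotation: Rotation) -> "AtomCloud":
        return AtomCloud(self.elements, rotation.apply(self.coords),
                         self.radii, self.name)


def radius_for_element(element: str,
                       table: dict[str, float] | None = None) -> float:
    table = table if table is not None else BONDI_VDW_RADIUS
    key = element.strip().upper()
    if key in table:
        return table[key]
    warnings.warn(
        f"no van der Waals radius for element {element!r}; "
        f"using default {DEFAULT_VDW_RADIUS} A",
        stacklevel=2,
    )
    return DEFAULT_VDW_RADIUS


def read_structure(
    pdb_path: str | Path,
    name: str | None = None,
    radii_table: dict[str, float] | None = None,
    include_hetatm: bool = True,
) -> AtomCloud:
    """Parse a PDB file into an AtomCloud.

    Keeps one location per atom (the blank or 'A' altloc, Biopython's
    convention of the highest-occupancy conformer); hydrogens are kept
    if present. Radii come from the Bondi table unless overridden.
    """
    path = Path(pdb_path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(name or path.stem, str(path))
    elements, coords, radii = [], [], []
    for atom in structure.get_atoms():
        if not include_hetatm and atom.get_parent().id[0] != " ":
            continue
        el = atom.element or atom.get_name()[:1]
        elements.append(el)
        coords.append(atom.get_coord())
        radii.append(radius_for_element(el, radii_table))
    if not coords:
        raise ValueError(f"no ATOM/HETATM records found in {path}")
    return AtomCloud(elements, np.array(coords, dtype=float),
                     np.array(radii, dtype=float), name=name or path.stem)


# ---------------------------------------------------------------------------
# Monte Carlo machinery


def _projected_disk(coords2d: np.ndarray, radii: np.ndarray):
    """Bounding disk (center, radius) of projected atom circles."""
    center = coords2d.mean(axis=0)
    reach = np.linalg.norm(coords2d - center, axis=1) + radii
    return center, float(reach.max())


def _combine_orientations(est: np.ndarray, var_within: np.ndarray):
    """Mean and s.e. over per-orientation MC estimates."""
    n = len(est)
    mean = float(est.mean())
    between = float(est.var(ddof=1)) / n if n > 1 else 0.0
    within = float(var_within.mean()) / n
    return mean, float(np.sqrt(between + within))


def ccs_projection(
    cloud: AtomCloud,
    probe_radius: float = HELIUM_PROBE_RADIUS,
    n_orientations: int = 32,
    n_rays: int = 4000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Projection-approximation Omega (Angstrom^2) with MC standard error.

    Averages, over uniformly random orientations, the area of the shadow
    cast by spheres of radius ``r_vdw + probe_radius``; the area is
    estimated by uniform sampling of a bounding disk.
    """
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    if n_orientations < 1 or n_rays < 1:
        raise ValueError("n_orientations and n_rays must be >= 1")
    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_orientations, random_state=rng)
    radii = cloud.radii + probe_radius
    est = np.empty(n_orientations)
    var_within = np.empty(n_orientations)
    for k in range(n_orientations):
        xy = rots[k].apply(cloud.coords)[:, :2]
        center, disk_r = _projected_disk(xy, radii)
        pts = _sample_disk(rng, n_rays, center, disk_r)
        d2 = ((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        hit = (d2 <= radii[None, :] ** 2).any(axis=1)
        area = np.pi * disk_r**2
        p = hit.mean()
        est[k] = area * p
        var_within[k] = area**2 * p * (1 - p) / n_rays
    return _combine_orientations(est, var_within)


def _sample_disk(rng, n, center, radius):
    r = radius * np.sqrt(rng.random(n))
    theta = 2 * np.pi * rng.random(n)
    return center + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _trace_batch(
    start: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    max_bounces: int,
) -> np.ndarray:
    """Specular-reflection trajectories; returns final directions.

    Rays start travelling along -z. Each bounce reflects the direction
    about the sphere normal at the nearest intersection. A ray exceeding
    ``max_bounces`` keeps its accumulated deflection.
    """
    n = len(start)
    pos = start.copy()
    dirs = np.tile([0.0, 0.0, -1.0], (n, 1))
    active = np.ones(n, dtype=bool)
    eps = 1e-9
    n_clipped = 0
    for bounce in range(max_bounces):
        if not active.any():
            break
        p = pos[active]
        d = dirs[active]
        oc = p[:, None, :] - centers[None, :, :]
        b = np.einsum("ij,ikj->ik", d, oc)
        c = (oc**2).sum(axis=2) - radii[None, :] ** 2
        disc = b**2 - c
        t = np.where(disc >= 0, -b - np.sqrt(np.maximum(disc, 0.0)), np.inf)
        t = np.where(t > eps, t, np.inf)
        t_min = t.min(axis=1)
        hit = np.isfinite(t_min)
        if not hit.any():
            active[active] = False
            break
        which = t.argmin(axis=1)
        p_hit = p[hit] + d[hit] * t_min[hit, None]
        normal = p_hit - centers[which[hit]]
        normal /= np.linalg.norm(normal, axis=1, keepdims=True)
        d_new = d[hit] - 2 * np.einsum("ij,ij->i", d[hit], normal)[:, None] * normal
        idx = np.flatnonzero(active)
        pos[idx[hit]] = p_hit + d_new * eps * 10
        dirs[idx[hit]] = d_new
        still = np.zeros(active.sum(), dtype=bool)
        still[hit] = True
        active[idx] = still
    else:
        n_clipped = int(active.sum())
    if n_clipped:
        warnings.warn(
            f"{n_clipped} trajectories exceeded max_bounces={max_bounces}; "
            "counted with their accumulated deflection",
            stacklevel=2,
        )
    return dirs


def ccs_ehss(
    cloud: AtomCloud,
    probe_radius: float = HELIUM_PROBE_RADIUS,
    n_orientations: int = 32,
    n_impact: int = 4000,
    seed: int | None = None,
    max_bounces: int = 30,
) -> tuple[float, float]:
    """Exact hard-sphere scattering Omega (Angstrom^2) with MC s.e.

    The momentum-transfer cross-section: each trajectory contributes
    ``1 - cos(chi)`` with chi the angle between its incoming and
    outgoing directions, averaged over impact points on a bounding disk
    and over uniformly random orientations.
    """
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    if n_orientations < 1 or n_impact < 1 or max_bounces < 1:
        raise ValueError("sampling parameters must be >= 1")
    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_orientations, random_state=rng)
    radii = cloud.radii + probe_radius
    est = np.empty(n_orientations)
    var_within = np.empty(n_orientations)
    for k in range(n_orientations):
        xyz = rots[k].apply(cloud.coords)
        center, disk_r = _projected_disk(xyz[:, :2], radii)
        pts2d = _sample_disk(rng, n_impact, center, disk_r)
        z0 = xyz[:, 2].max() + radii.max() + 1.0
        start = np.column_stack([pts2d, np.full(n_impact, z0)])
        final_dirs = _trace_batch(start, xyz, radii, max_bounces)
        cos_chi = -final_dirs[:, 2]  # dot with initial (0,0,-1)
        weights = 1.0 - cos_chi
        area = np.pi * disk_r**2
        est[k] = area * weights.mean()
        var_within[k] = area**2 * weights.var() / n_impact
    return _combine_orientations(est, var_within)


def ensemble_ccs(
    pdb_paths: Iterable[str | Path],
    method: str = "ehss",
    **kwargs,
) -> tuple[float, float]:
    """Average Omega over an ensemble of coordinate files.

    Returns the ensemble mean and the sample s.d. across members (not
    the per-member MC error).
    """
    fn = {"ehss": ccs_ehss, "pa": ccs_projection}[method]
    values = [fn(read_structure(p), **kwargs)[0] for p in pdb_paths]
    if not values:
        raise ValueError("empty ensemble")
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def compare_models(
    experimental: Sequence[float],
    models: dict[str, float],
) -> pd.DataFrame:
    """Rank structural models by agreement with experimental Omega.

    Deviation is against the mean of the experimental values; ties are
    broken deterministically by model name order.
    """
    if len(experimental) == 0 or not models:
        raise ValueError("experimental and model lists must be non-empty")
    exp_mean = float(np.mean(experimental))
    rows = [
        {
            "model": name,
            "ccs_model": omega,
            "ccs_experimental_mean": exp_mean,
            "abs_deviation": abs(omega - exp_mean),
        }
        for name, omega in models.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["abs_deviation", "model"], kind="mergesort"
    )
    df["rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)
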