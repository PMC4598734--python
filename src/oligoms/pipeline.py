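"""End-to-end pipeline: grid -> assignment -> deconvolution -> populations.

The pipeline reproduces the analysis chain of a native ESI-IM-MS
oligomer experiment: enumerate the theoretical ion grid, assign each
observed peak (isotope spacing first, consecutive charge states as the
fallback), resolve mobility-shared channels by Gaussian deconvolution of
their mobilograms, and accumulate the charge-state-weighted oligomer
distribution. Every output bundle carries the configuration, seeds and
package version it was produced with, and rerunning with identical
inputs and seeds reproduces the numeric tables exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abundance import (
    ChargeStateObservation,
    OligomerDistribution,
    species_population,
)
from .ion_grid import (
    OligomerIon,
    PeakAssignment,
    PeptideSpecies,
    assign_peaks,
    build_grid,
    grid_to_frame,
)
from .mobility import Mobilogram, MobilogramFit, fit_mobilogram, relative_contributions

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "label_components"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending record."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    """Validated settings for a pipeline run."""

    species: list[dict] = field(
        default_factory=lambda: [
            {"id": "Abeta40",
             "sequence": "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV"}
        ]
    )
    tol_ppm: float = 20.0
    mass_basis: str = "mono"
    max_order: int = 6
    charge_range: tuple[int, int] = (1, 10)
    crosslinked: bool = False
    # mobilogram fitting
    fit_max_iter: int = 5000
    fit_tol: float = 1e-10
    # calibration
    gas: str = "N2"
    edc_c: float = 1.41
    # acquisition
    mz_range: tuple[float, float] = (500.0, 5000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        if self.mass_basis not in ("mono", "avg"):
            raise ValueError("mass_basis must be 'mono' or 'avg'")
        if self.mz_range[0] >= self.mz_range[1]:
            raise ValueError("mz_range must have min < max")
        self.charge_range = tuple(self.charge_range)  # type: ignore[assignment]
        self.mz_range = tuple(self.mz_range)  # type: ignore[assignment]
        if not self.species:
            raise ValueError("at least one species must be defined")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["charge_range"] = list(self.charge_range)
        d["mz_range"] = list(self.mz_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def species_objects(self) -> list[PeptideSpecies]:
        return [
            PeptideSpecies.from_sequence(s["id"], s["sequence"])
            for s in self.species
        ]


def label_components(
    fit: MobilogramFit,
    candidates: list[OligomerIon],
    peak_spacings: list[tuple[float, float]] | None = None,
    ccs_ranker=None,
) -> MobilogramFit:
    """Attach species labels to fitted mobility components.

    For n/z-degenerate channels the co-located candidate ions are known
    from the grid; what remains is deciding which mobility peak belongs
    to which candidate. Three rules, in order of trust:

    1. isotope spacing of the per-mobility-peak m/z spectrum
       (``peak_spacings`` rows of (drift time, spacing)): the peak's
       charge is inferred from the spacing and the candidate with that
       charge takes the label;
    2. cross-section plausibility: when a ``ccs_ranker`` is available
       (a calibration plus a size-scaling prior), each unlabelled
       component takes the unclaimed candidate whose implied Omega best
       matches the expected size for its oligomer order;
    3. parsimony: the lowest unclaimed oligomer orders are assumed
       present, and since at fixed m/z the higher-order ion has the
       smaller charge-normalised cross-section and hence the shorter
       drift time, unlabelled components in ascending drift time take
       the chosen candidates in descending order.

    Components beyond the candidate list stay unlabelled and are
    excluded downstream.
    """
    from .ion_grid import infer_charge

    by_charge = {ion.charge_z: ion for ion in candidates}
    claimed: set[int] = set()
    labelled_ids: set[int] = set()
    # each anchor claims the nearest free component, so a small spurious
    # component near an anchored peak cannot steal its label
    for td, spacing in peak_spacings or []:
        z = infer_charge(spacing)
        if z is None or z not in by_charge or z in claimed:
            continue
        free = [c for c in fit.components if id(c) not in labelled_ids]
        if not free:
            break
        comp = min(free, key=lambda c: abs(c.x_c - td))
        if abs(td - comp.x_c) > max(comp.w, 0.5):
            continue
        ion = by_charge[z]
        claimed.add(z)
        labelled_ids.add(id(comp))
        comp.label = ion.species.id + ":" + _order_label(ion.order_n)
    unlabelled = [c for c in fit.components if id(c) not in labelled_ids]
    if ccs_ranker is not None:
        still = []
        for comp in unlabelled:
            scored = []
            for ion in candidates:
                if ion.charge_z in claimed:
                    continue
                score = ccs_ranker(comp.x_c, ion)
                if score is not None:
                    scored.append((score, ion.order_n, ion))
            if scored:
                scored.sort(key=lambda s: (s[0], s[1]))
                ion = scored[0][2]
                claimed.add(ion.charge_z)
                comp.label = ion.species.id + ":" + _order_label(ion.order_n)
            else:
                still.append(comp)
        unlabelled = still
    remaining = sorted(
        (ion for ion in candidates if ion.charge_z not in claimed),
        key=lambda ion: ion.order_n,
    )[: len(unlabelled)]
    # ascending drift time <-> descending oligomer order
    for comp, ion in zip(unlabelled, sorted(remaining, key=lambda i: -i.order_n)):
        comp.label = ion.species.id + ":" + _order_label(ion.order_n)
    return fit


def _order_label(n: int) -> str:
    from .ion_grid import ORDER_LABELS

    return ORDER_LABELS.get(n, f"{n}-mer")


def _ion_neutral_mass(ion: OligomerIon) -> float:
    from .constants import PROTON_MASS

    return ion.mz_mono * ion.charge_z - ion.charge_z * PROTON_MASS


def _make_ccs_ranker(anchors, calibration, ccs_exponent):
    """Score candidate ions by cross-section plausibility.

    ``anchors`` are (order_n, charge_z, mass, drift_time) tuples from
    positively assigned components. The size-scaling prefactor Omega_1
    of ``Omega(n) = Omega_1 * n^ccs_exponent`` (globular scaling,
    exponent 2/3) is estimated from them; a candidate's score is the
    absolute log-ratio between the Omega its (z, mass) imply at the
    component's drift time and the Omega its order predicts. Lower is
    better; None when the drift time falls outside the calibration.
    """
    import numpy as np

    from .calibration import ccs_from_drift

    logs = []
    for n, z, mass, td in anchors:
        try:
            omega = ccs_from_drift(calibration, td, z, mass)
        except ValueError:
            continue
        logs.append(np.log(omega) - ccs_exponent * np.log(n))
    if not logs:
        return None
    omega_1 = float(np.exp(np.mean(logs)))
    logger.info("size-scaling prefactor Omega_1 = %.1f A^2 from %d anchors",
                omega_1, len(logs))

    def ranker(td: float, ion: OligomerIon) -> float | None:
        # extrapolated Omega is used for plausibility ranking only,
        # never reported as a measurement
        try:
            omega = ccs_from_drift(
                calibration, td, ion.charge_z, _ion_neutral_mass(ion),
                extrapolate=True,
            )
        except ValueError:
            return None
        expected = omega_1 * ion.order_n**ccs_exponent
        return abs(float(np.log(omega / expected)))

    return ranker


def _channel_init(
    mob: Mobilogram, n: int, anchor_tds: list[float]
) -> list[tuple[float, float, float]]:
    """Initial (x_c, w, A) guesses seeded at the anchored drift times."""
    import numpy as np

    from .mobility import _initial_components

    x, y = mob.drift_time, mob.intensity
    span = float(x[-1] - x[0])
    w0 = span / 30
    init: list[tuple[float, float, float]] = []
    for td in anchor_tds[:n]:
        height = float(np.interp(td, x, y))
        init.append((td, w0, max(height * w0, 1e-9)))
    if len(init) < n:
        for guess in _initial_components(mob, n):
            if all(abs(guess[0] - g[0]) > 2 * w0 for g in init):
                init.append(guess)
            if len(init) == n:
                break
    k = len(init)
    while len(init) < n:  # quantile fill as a last resort
        q = (len(init) - k + 1) / (n - k + 1)
        init.append((float(x[0] + q * span), w0,
                     max(float(np.ptp(y)) * w0, 1e-9)))
    return init


def _fit_channel(
    mob: Mobilogram,
    a: PeakAssignment,
    config: PipelineConfig,
    max_components: int = 4,
    min_area_frac: float = 0.01,
):
    """Deconvolve one channel.

    The number of spacing-anchored mobility peaks is a lower bound on
    the component count; the count is selected by corrected AIC from
    that bound up to ``max_components``. Components carrying less than
    ``min_area_frac`` of the total area are treated as noise pickup and
    pruned (the surviving model is refit).
    """
    anchor_tds = [td for td, _ in (mob.peak_spacings or [])]
    n_min = max(1, len(anchor_tds))
    best = None
    for n in range(n_min, max_components + 1):
        try:
            fit = fit_mobilogram(
                mob, n_components=n, init=_channel_init(mob, n, anchor_tds),
                max_iter=config.fit_max_iter, tol=config.fit_tol,
            )
        except ValueError:
            break  # data cannot support more parameters
        if best is None or fit.aicc < best.aicc:
            best = fit
    if best is None:
        raise PipelineError(
            "deconvolve",
            f"no supportable fit for channel m/z {a.observed_mz:.2f}",
        )
    total = sum(c.A for c in best.components)
    keep = [c for c in best.components if c.A >= min_area_frac * total]
    if keep and len(keep) < len(best.components):
        best = fit_mobilogram(
            mob, n_components=len(keep),
            init=[(c.x_c, c.w, c.A) for c in keep],
            max_iter=config.fit_max_iter, tol=config.fit_tol,
        )
    if not best.converged:
        raise PipelineError(
            "deconvolve",
            f"fit did not converge for channel m/z {a.observed_mz:.2f}",
        )
    return best


def _observations_from_assignments(
    assignments: list[PeakAssignment],
    intensities: list[float],
    mobilograms: dict[float, Mobilogram],
    config: PipelineConfig,
    calibration=None,
    ccs_exponent: float = 2.0 / 3.0,
) -> tuple[list[ChargeStateObservation], list[dict]]:
    from .ion_grid import infer_charge

    # pass 1: fit every channel that has a mobilogram; collect anchors
    # (positively identified components) for the size-scaling prior
    fits: dict[int, MobilogramFit] = {}
    anchors: list[tuple[int, int, float, float]] = []
    for i, a in enumerate(assignments):
        mob = _lookup_mobilogram(mobilograms, a.observed_mz)
        if mob is None:
            continue
        fit = _fit_channel(mob, a, config)
        fits[i] = fit
        unique = {c.species_key: c for c in a.candidates}
        if len(unique) == 1 and a.accepted is not None:
            # unambiguous channel: its dominant mobility peak anchors
            # the accepted ion
            comp = max(fit.components, key=lambda c: c.A)
            ion = a.accepted
            anchors.append(
                (ion.order_n, ion.charge_z, _ion_neutral_mass(ion), comp.x_c)
            )
        elif mob.peak_spacings:
            by_charge = {ion.charge_z: ion for ion in a.candidates}
            for td, spacing in mob.peak_spacings:
                z = infer_charge(spacing)
                if z is not None and z in by_charge:
                    ion = by_charge[z]
                    anchors.append(
                        (ion.order_n, z, _ion_neutral_mass(ion), td)
                    )

    ranker = (
        _make_ccs_ranker(anchors, calibration, ccs_exponent)
        if calibration is not None and anchors
        else None
    )

    # pass 2: build per-channel contributor maps
    observations = []
    fit_records = []
    for i, (a, intensity) in enumerate(zip(assignments, intensities)):
        mob = _lookup_mobilogram(mobilograms, a.observed_mz)
        unique = list({c.species_key: c for c in a.candidates}.values())
        if mob is not None and len(unique) > 1:
            # mobility-shared channel: deconvolve and split the intensity
            fit = fits[i]
            label_components(fit, unique, mob.peak_spacings, ranker)
            labelled = [c for c in fit.components if c.label is not None]
            total_area = sum(c.A for c in fit.components)
            labelled_area = sum(c.A for c in labelled)
            if labelled and labelled_area > 0:
                contributors: dict[str, float] = {}
                for c in labelled:
                    contributors[c.label] = (
                        contributors.get(c.label, 0.0) + c.A / labelled_area
                    )
                # exact renormalisation
                s = sum(contributors.values())
                contributors = {k: v / s for k, v in contributors.items()}
                intensity = intensity * labelled_area / total_area
            else:
                contributors = {}
            fit_records.append(
                {
                    "channel_mz": a.observed_mz,
                    "k_im": fit.k_im,
                    "rss": fit.rss,
                    "components": [
                        {"x_c": c.x_c, "w": c.w, "A": c.A, "label": c.label}
                        for c in fit.components
                    ],
                }
            )
        elif a.accepted is not None:
            contributors = {
                a.accepted.species.id + ":" + _order_label(a.accepted.order_n): 1.0
            }
        else:
            contributors = {}
        observations.append(
            ChargeStateObservation(
                channel_mz=a.observed_mz,
                total_intensity=intensity,
                contributors=contributors,
            )
        )
    return observations, fit_records


def _lookup_mobilogram(
    mobilograms: dict[float, Mobilogram], mz: float, tol: float = 1.0
) -> Mobilogram | None:
    for key, mob in mobilograms.items():
        if abs(key - mz) <= tol:
            return mob
    return None


def run_pipeline(
    config: PipelineConfig,
    peaks: list[tuple[float, float, float | None]],
    mobilograms: dict[float, Mobilogram] | None = None,
    out_dir: str | Path | None = None,
    sample_id: str = "sample",
    calibration=None,
    ccs_exponent: float = 2.0 / 3.0,
) -> dict:
    """Run grid -> assignment -> deconvolution -> population.

    ``peaks`` are (mz, intensity, spacing-or-None) rows;
    ``mobilograms`` maps channel m/z to its drift-time trace (channels
    shared by several species require one to be split). When a fitted
    :class:`~oligoms.calibration.CcsCalibration` is supplied, mobility
    components that neither isotope spacing nor uniqueness can identify
    are resolved by cross-section plausibility against a globular size
    scaling ``Omega_1 * n**ccs_exponent`` whose prefactor is estimated
    from the positively identified components. Returns a report dict;
    when ``out_dir`` is given, writes the report bundle (grid,
    assignments, fits, distribution, config, provenance) there. A stage
    failure raises :class:`PipelineError` naming the stage; partial
    outputs are kept under ``<out_dir>/failed``.
    """
    mobilograms = mobilograms or {}
    out_path = Path(out_dir) if out_dir is not None else None
    try:
        if not peaks:
            raise PipelineError("assign", "empty peak list")
        species = config.species_objects()
        grid = build_grid(
            species,
            max_order=config.max_order,
            charge_range=config.charge_range,
            crosslinked=config.crosslinked,
        )
        assignments = assign_peaks(peaks, grid, tol_ppm=config.tol_ppm)
        intensities = [peak[1] for peak in peaks]
        observations, fit_records = _observations_from_assignments(
            assignments, intensities, mobilograms, config,
            calibration=calibration, ccs_exponent=ccs_exponent,
        )
        distribution = species_population(observations, sample_id=sample_id)
    except PipelineError:
        if out_path is not None:
            (out_path / "failed").mkdir(parents=True, exist_ok=True)
        raise
    except Exception as exc:  # annotate unexpected stage errors
        if out_path is not None:
            (out_path / "failed").mkdir(parents=True, exist_ok=True)
        raise PipelineError("pipeline", str(exc)) from exc

    report = {
        "sample_id": sample_id,
        "distribution": distribution.population,
        "excluded_intensity": distribution.excluded_intensity,
        "n_peaks": len(peaks),
        "n_assigned": sum(1 for a in assignments if a.rule_used != "unassigned"),
        "fits": fit_records,
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "tol_ppm": config.tol_ppm,
            "mass_basis": config.mass_basis,
            "note": "channels without established contributors are excluded "
                    "from the population denominator",
        },
    }
    if out_path is not None:
        _write_bundle(out_path, config, grid, assignments, intensities,
                      report, distribution)
    return report


def _write_bundle(
    out_path: Path,
    config: PipelineConfig,
    grid,
    assignments,
    intensities,
    report: dict,
    distribution: OligomerDistribution,
) -> None:
    out_path.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_path / "config.yaml")
    grid_to_frame(grid).to_csv(out_path / "grid.csv", index=False,
                               float_format="%.6f")
    pd.DataFrame(
        [
            {
                "observed_mz": a.observed_mz,
                "intensity": inten,
                "spacing": a.observed_spacing,
                "accepted": a.accepted.label if a.accepted else "",
                "rule": a.rule_used,
            }
            for a, inten in zip(assignments, intensities)
        ]
    ).to_csv(out_path / "assignments.csv", index=False, float_format="%.6f")
    rows = [
        {
            "species": sp,
            "population": pop,
            "sd": distribution.replicate_sd.get(sp, float("nan")),
        }
        for sp, pop in sorted(distribution.population.items())
    ]
    pd.DataFrame(rows).to_csv(out_path / "distribution.csv", index=False,
                              float_format="%.9f")
    with open(out_path / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
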