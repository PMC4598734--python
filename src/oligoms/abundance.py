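"""Oligomer population statistics from assigned charge-state intensities.

The population of an oligomer species is the summed intensity of all its
charge-state ions divided by the summed intensity of every assigned
charge-state ion in the spectrum. Channels shared by several species in
the mobility dimension contribute to each species in proportion to the
mobilogram-resolved area fractions. Channels whose contributors cannot
be established are excluded from both the numerator and the denominator;
their summed intensity is reported so the exclusion is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ChargeStateObservation",
    "OligomerDistribution",
    "species_population",
    "compare_distributions",
]

logger = logging.getLogger(__name__)


@dataclass
class ChargeStateObservation:
    """Total intensity of one charge-state channel and who contributes.

    ``contributors`` maps species label to its fraction of the channel
    intensity — mobilogram-derived for shared channels, ``{species: 1}``
    for unambiguous ones.
    """

    channel_mz: float
    total_intensity: float
    contributors: dict[str, float]

    def __post_init__(self) -> None:
        if self.total_intensity < 0:
            raise ValueError("total_intensity must be >= 0")
        if self.contributors:
            s = sum(self.contributors.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(
                    f"contributor fractions must sum to 1, got {s}"
                )


@dataclass
class OligomerDistribution:
    """Normalised species populations for one sample."""

    sample_id: str
    population: dict[str, float]
    replicate_sd: dict[str, float] = field(default_factory=dict)
    excluded_intensity: float = 0.0

    def __post_init__(self) -> None:
        s = sum(self.population.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"populations must sum to 1, got {s}")
        if any(not 0.0 <= p <= 1.0 for p in self.population.values()):
            raise ValueError("populations must lie in [0, 1]")


def species_population(
    observations: Sequence[ChargeStateObservation],
    sample_id: str = "sample",
) -> OligomerDistribution:
    """Charge-state-weighted oligomer distribution of one acquisition.

    population(s) = sum_channels I_ch * fraction_ch(s) / sum_channels I_ch,
    summing over channels with established contributors only.
    """
    if not observations:
        raise ValueError("need at least one observation")
    totals: dict[str, float] = {}
    denom = 0.0
    excluded = 0.0
    for obs in observations:
        if not obs.contributors:
            excluded += obs.total_intensity
            continue
        denom += obs.total_intensity
        for sp, frac in obs.contributors.items():
            totals[sp] = totals.get(sp, 0.0) + obs.total_intensity * frac
    if denom <= 0:
        raise ValueError("all assigned channel intensities are zero")
    if excluded:
        logger.info(
            "excluded %.3g counts of unassigned channel intensity "
            "from the population denominator", excluded,
        )
    pops = {sp: v / denom for sp, v in totals.items()}
    # exact renormalisation against accumulated float error
    s = sum(pops.values())
    pops = {sp: v / s for sp, v in pops.items()}
    return OligomerDistribution(
        sample_id=sample_id, population=pops, excluded_intensity=excluded
    )


def aggregate_replicates(
    replicates: Sequence[OligomerDistribution], sample_id: str
) -> OligomerDistribution:
    """Mean +/- sample s.d. across independent acquisitions."""
    if len(replicates) < 1:
        raise ValueError("need at least one replicate")
    species = sorted({sp for r in replicates for sp in r.population})
    mat = np.array(
        [[r.population.get(sp, 0.0) for sp in species] for r in replicates]
    )
    mean = mat.mean(axis=0)
    mean = mean / mean.sum()
    sd = mat.std(axis=0, ddof=1) if len(replicates) > 1 else np.zeros(len(species))
    return OligomerDistribution(
        sample_id=sample_id,
        population=dict(zip(species, mean.tolist())),
        replicate_sd=dict(zip(species, sd.tolist())),
    )


def compare_distributions(
    replicates_a: Sequence[OligomerDistribution],
    replicates_b: Sequence[OligomerDistribution],
    alpha: float = 0.05,
) -> dict[str, dict[str, float]]:
    """Per-species comparison of two samples' oligomer distributions.

    Runs an unpaired two-tailed t-test on the replicate populations of
    each species. Raw p-values are reported alongside Holm-adjusted ones
    (several species are tested at once). Species missing from one
    sample's replicates are imputed as population 0 with a warning.
    """
    if len(replicates_a) < 2 or len(replicates_b) < 2:
        raise ValueError("need >= 2 replicates per sample")
    sp_a = {sp for r in replicates_a for sp in r.population}
    sp_b = {sp for r in replicates_b for sp in r.population}
    if sp_a != sp_b:
        logger.warning(
            "species sets differ (%s vs %s); missing species imputed as 0",
            sorted(sp_a), sorted(sp_b),
        )
    species = sorted(sp_a | sp_b)
    results: dict[str, dict[str, float]] = {}
    pvals = []
    for sp in species:
        a = np.array([r.population.get(sp, 0.0) for r in replicates_a])
        b = np.array([r.population.get(sp, 0.0) for r in replicates_b])
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(a, b)
        results[sp] = {
            "delta": float(b.mean() - a.mean()),
            "t": float(t_stat),
            "p_raw": float(p),
        }
        pvals.append(float(p))
    reject, p_holm, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    for sp, ph, rej in zip(species, p_holm, reject):
        results[sp]["p_holm"] = float(ph)
        results[sp]["significant_holm"] = bool(rej)
    return results
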