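"""Plots of oligomer distributions and mobilogram fits."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .abundance import OligomerDistribution
from .mobility import Mobilogram, MobilogramFit

__all__ = ["plot_distributions", "plot_mobilogram_fit"]

_SPECIES_ORDER = ["M", "D", "Tr", "Te", "P", "Hx"]


def _species_sort_key(name: str) -> tuple[int, str]:
    short = name.split(":")[-1]
    return (_SPECIES_ORDER.index(short) if short in _SPECIES_ORDER else 99, name)


def plot_distributions(
    distributions: Sequence[OligomerDistribution],
    path: str | Path,
) -> None:
    """Grouped bar chart of species populations with replicate error bars."""
    species = sorted(
        {sp for d in distributions for sp in d.population},
        key=_species_sort_key,
    )
    x = np.arange(len(species))
    width = 0.8 / max(len(distributions), 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, dist in enumerate(distributions):
        vals = [dist.population.get(sp, 0.0) for sp in species]
        errs = [dist.replicate_sd.get(sp, 0.0) for sp in species]
        ax.bar(x + i * width, vals, width, yerr=errs, capsize=3,
               label=dist.sample_id)
    ax.set_xticks(x + width * (len(distributions) - 1) / 2)
    ax.set_xticklabels(species)
    ax.set_ylabel("relative population")
    ax.set_xlabel("oligomer species")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mobilogram_fit(
    mob: Mobilogram, fit: MobilogramFit, path: str | Path
) -> None:
    """Data, fitted curve and individual Gaussian components."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(mob.drift_time, mob.intensity, ".", ms=3, color="0.5", label="data")
    ax.plot(mob.drift_time, fit.predict(mob.drift_time), "k-", label="fit")
    for comp in fit.components:
        ax.plot(mob.drift_time, fit.k_im + comp(mob.drift_time), "--",
                label=comp.label or f"x_c={comp.x_c:.2f} ms")
    ax.set_xlabel("drift time (ms)")
    ax.set_ylabel("intensity (counts)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
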