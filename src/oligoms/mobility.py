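"""Gaussian deconvolution of ion-mobility arrival-time distributions.

A mobilogram (intensity vs drift time for one m/z channel) is modelled
as a constant baseline plus a sum of Gaussian components,

    f_im(x) = k_im + sum_N g(x; x_c_N, w_N, A_N),

with each component parameterised by its center ``x_c`` (ms), full width
at half height ``w`` (ms) and area ``A`` (counts*ms):

    g(x) = A * (2*sqrt(ln 2) / (w*sqrt(pi))) * exp(-4*ln(2)*(x-x_c)^2 / w^2).

Component areas are the quantities that propagate downstream: within a
charge-state channel shared by several species (or conformers), each
component's share of the summed area is that species' relative
contribution to the channel intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
from scipy import signal, stats

__all__ = [
    "Mobilogram",
    "GaussianComponent",
    "MobilogramFit",
    "gaussian_fwhm",
    "fit_mobilogram",
    "relative_contributions",
    "peak_width_stats",
]

_FWHM_NORM = 2.0 * math.sqrt(math.log(2.0)) / math.sqrt(math.pi)
_4LN2 = 4.0 * math.log(2.0)


def gaussian_fwhm(x: np.ndarray, x_c: float, w: float, A: float) -> np.ndarray:
    """Gaussian with unit-area normalisation expressed via FWHM ``w``."""
    return A * (_FWHM_NORM / w) * np.exp(-_4LN2 * (x - x_c) ** 2 / w**2)


@dataclass
class Mobilogram:
    """Drift-time trace for one m/z channel.

    ``peak_spacings`` optionally carries the isotopologue spacing
    measured in the m/z spectrum associated with each mobility peak
    (drift time, spacing in Th): mobility separation yields a clean
    per-peak spectrum whose 13C spacing reveals that peak's charge even
    when the summed spectrum is congested.
    """

    drift_time: np.ndarray  # ms, strictly increasing
    intensity: np.ndarray  # counts, >= 0
    channel: str = ""  # e.g. "mz=1732 wh=7"
    peak_spacings: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.drift_time = np.asarray(self.drift_time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.drift_time.size < 8:
            raise ValueError("mobilogram needs at least 8 samples")
        if self.drift_time.size != self.intensity.size:
            raise ValueError("drift_time and intensity lengths differ")
        if not np.all(np.diff(self.drift_time) > 0):
            raise ValueError("drift_time must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and non-negative")


@dataclass
class GaussianComponent:
    x_c: float  # center, ms
    w: float  # full width at half height, ms
    A: float  # area, counts*ms
    label: str | None = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return gaussian_fwhm(np.asarray(x, dtype=float), self.x_c, self.w, self.A)


@dataclass
class MobilogramFit:
    """Result of fitting ``f_im = k_im + sum of Gaussians``."""

    k_im: float
    components: list[GaussianComponent]
    rss: float
    converged: bool
    n_points: int = 0
    aicc: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.components = sorted(self.components, key=lambda c: c.x_c)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.full_like(x, self.k_im)
        for comp in self.components:
            y = y + comp(x)
        return y

    @property
    def n_free_params(self) -> int:
        return 3 * len(self.components) + 1


def _initial_components(
    mob: Mobilogram, n_components: int
) -> list[tuple[float, float, float]]:
    """Deterministic (x_c, w, A) guesses from prominence-ranked maxima."""
    x, y = mob.drift_time, mob.intensity
    smooth = signal.savgol_filter(y, min(7, len(y) // 2 * 2 - 1), 2)
    baseline = float(np.percentile(smooth, 10))
    peaks, props = signal.find_peaks(smooth, prominence=0.0)
    order = np.lexsort((x[peaks], -props["prominences"])) if peaks.size else []
    span = x[-1] - x[0]
    guesses = []
    for idx in order[:n_components]:
        p = peaks[idx]
        height = max(smooth[p] - baseline, 1e-12)
        # half-height crossing width around the maximum
        half = baseline + height / 2
        left = p
        while left > 0 and smooth[left] > half:
            left -= 1
        right = p
        while right < len(x) - 1 and smooth[right] > half:
            right += 1
        w = max(x[right] - x[left], span / len(x) * 2)
        guesses.append((float(x[p]), float(w), float(height * w / _FWHM_NORM)))
    # pad with quantile-spaced centers when too few maxima are found
    k = len(guesses)
    while len(guesses) < n_components:
        q = (len(guesses) - k + 1) / (n_components - k + 1)
        guesses.append(
            (float(x[0] + q * span), span / 10,
             float(max(np.ptp(y), 1e-9) * span / 10))
        )
    return guesses


def _fit_n(
    mob: Mobilogram,
    n_components: int,
    init: Sequence[tuple[float, float, float]] | None,
    max_iter: int,
    tol: float,
) -> MobilogramFit:
    x, y = mob.drift_time, mob.intensity
    if len(x) < 4 * (3 * n_components + 1):
        raise ValueError(
            f"{n_components} components need >= {4 * (3 * n_components + 1)} "
            f"points (4 per free parameter); got {len(x)}"
        )
    guesses = list(init) if init is not None else _initial_components(mob, n_components)
    if len(guesses) != n_components:
        raise ValueError("number of initial guesses must equal n_components")
    span = x[-1] - x[0]
    dx_min = float(np.min(np.diff(x)))
    params = lmfit.Parameters()
    params.add("k", value=float(max(np.percentile(y, 10), 0.0)), min=0.0)
    for i, (xc, w, A) in enumerate(guesses):
        if not (x[0] <= xc <= x[-1]):
            raise ValueError(f"initial center {xc} outside the drift-time axis")
        params.add(f"xc{i}", value=xc, min=float(x[0]), max=float(x[-1]))
        params.add(f"w{i}", value=max(w, dx_min), min=dx_min / 10, max=2 * span)
        params.add(f"A{i}", value=max(A, 1e-12), min=1e-12)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = np.full_like(x, p["k"].value)
        for i in range(n_components):
            model = model + gaussian_fwhm(
                x, p[f"xc{i}"].value, p[f"w{i}"].value, p[f"A{i}"].value
            )
        return model - y

    # trust-region-reflective backend: handles parameters starting at a
    # bound (k_im = 0 on baseline-free data) without stalling. Parameter
    # uncertainties are not used downstream, but lmfit's least_squares
    # backend estimates them regardless of calc_covar; silence the
    # invalid-sqrt noise from near-singular covariance diagonals.
    with np.errstate(invalid="ignore"):
        result = lmfit.minimize(
            residual, params, method="least_squares", calc_covar=False,
            max_nfev=max_iter, xtol=tol, ftol=tol, gtol=tol,
        )
    comps = [
        GaussianComponent(
            x_c=result.params[f"xc{i}"].value,
            w=result.params[f"w{i}"].value,
            A=result.params[f"A{i}"].value,
        )
        for i in range(n_components)
    ]
    rss = float(np.sum(np.asarray(result.residual) ** 2))
    n = len(x)
    k_free = 3 * n_components + 1
    # corrected AIC for least squares with unknown noise variance
    aicc = n * math.log(max(rss, 1e-300) / n) + 2 * k_free
    if n - k_free - 1 > 0:
        aicc += 2 * k_free * (k_free + 1) / (n - k_free - 1)
    return MobilogramFit(
        k_im=float(result.params["k"].value),
        components=comps,
        rss=rss,
        converged=bool(result.success),
        n_points=n,
        aicc=aicc,
    )


def fit_mobilogram(
    mob: Mobilogram,
    n_components: int | None = None,
    init: Sequence[tuple[float, float, float]] | None = None,
    max_iter: int = 5000,
    tol: float = 1e-10,
    max_auto_components: int = 4,
) -> MobilogramFit:
    """Least-squares fit of a constant baseline plus N Gaussians.

    When ``n_components`` is None the component count is chosen by
    minimum corrected AIC over 1..``max_auto_components``. Initial
    guesses default to prominence-ranked local maxima of a lightly
    smoothed trace (ties broken by earlier drift time), which makes the
    fit deterministic. Non-convergence is reported through the
    ``converged`` flag, never silently.
    """
    if n_components is not None:
        if not 1 <= n_components <= 6:
            raise ValueError("n_components must be between 1 and 6")
        return _fit_n(mob, n_components, init, max_iter, tol)
    best: MobilogramFit | None = None
    for n in range(1, max_auto_components + 1):
        try:
            fit = _fit_n(mob, n, None, max_iter, tol)
        except ValueError:
            break  # data cannot support more parameters
        if best is None or fit.aicc < best.aicc:
            best = fit
    if best is None:
        raise ValueError("no component count is supported by the data")
    return best


def relative_contributions(fit: MobilogramFit) -> dict[str, float]:
    """Per-component area fractions of a fitted channel.

    The fraction of a species in a charge-state channel is its component
    area divided by the summed area of all components in that channel.
    Unlabelled components are keyed ``g1``, ``g2``, ... in center order.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; contributions undefined")
    areas = np.array([c.A for c in fit.components])
    if not np.all(np.isfinite(areas)):
        raise ValueError("component areas must be finite")
    total = areas.sum()
    if total <= 0:
        raise ValueError("total component area is zero")
    out: dict[str, float] = {}
    for i, comp in enumerate(fit.components):
        key = comp.label if comp.label is not None else f"g{i + 1}"
        out[key] = out.get(key, 0.0) + float(comp.A / total)
    return out


def peak_width_stats(
    fits_a: Sequence[MobilogramFit],
    fits_b: Sequence[MobilogramFit],
    species: str,
) -> dict:
    """Compare mobility-peak widths of one species between two groups.

    Collects the FWHM of every component labelled ``species`` in each
    group of fits and runs an unpaired two-tailed t-test. Wider peaks
    indicate that the ion samples more conformations during the mobility
    separation (e.g. non-covalent vs cross-linked oligomers).
    """
    def widths(fits: Sequence[MobilogramFit], name: str) -> np.ndarray:
        vals = [
            c.w for f in fits for c in f.components if c.label == species
        ]
        if not vals:
            raise ValueError(f"species {species!r} absent from group {name}")
        return np.array(vals)

    wa, wb = widths(fits_a, "A"), widths(fits_b, "B")
    if len(wa) < 2 or len(wb) < 2:
        raise ValueError("need >= 2 width observations per group")
    if np.ptp(wa) == 0 and np.ptp(wb) == 0 and wa[0] == wb[0]:
        t_stat, p = 0.0, 1.0  # degenerate identical groups
    else:
        t_stat, p = stats.ttest_ind(wa, wb)
    return {
        "species": species,
        "mean_w_a": float(wa.mean()),
        "sd_w_a": float(wa.std(ddof=1)),
        "mean_w_b": float(wb.mean()),
        "sd_w_b": float(wb.std(ddof=1)),
        "t": float(t_stat),
        "p": float(p),
        "n_a": len(wa),
        "n_b": len(wb),
    }
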