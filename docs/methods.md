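# Methods

This note records the models, algorithms and numerical choices behind
`oligoms`, plus the conditions of the synthetic study data and known
limitations.

## Ion grid and peak assignment

A peptide species is defined by its sequence; elemental composition and
monoisotopic/average masses come from standard residue tables
(pyteomics). An oligomer ion `[nM + zH]z+` has

```
m/z = (n*M - 2*b*m_H + z*m_p) / z
```

with `b` the number of covalent cross-link bonds (zero for non-covalent
assemblies; photochemical cross-linking removes two hydrogen atoms per
bond, and a connected n-mer needs at least n−1 bonds). Monoisotopic
masses are the default basis; nominal figure labels of broad envelopes
are better matched by the average basis, which is why the degenerate
monomer-2+ channel is reported on it.

Ions with equal `n/z` are exactly co-located on the monoisotopic basis
(the m/z formula depends on n and z only through `n/z`), so a peak
position alone never identifies the species. Assignment applies two
rules in order of trust:

1. **Isotope spacing.** Adjacent ¹³C isotopologues are spaced
   `1.003355/z` Th; a measured spacing whose implied charge rounds to
   an integer within 15% relative deviation fixes `z` and thereby the
   candidate. The isotope pattern itself is computed by convolving
   per-element added-neutron distributions (binary-exponentiation
   convolution, truncation at 1e-12 probability mass, tail cut at 1e-4
   relative abundance) and placing isotopologue k at
   `mz_mono + k*1.003355/z` — the standard aggregated approximation,
   accurate to well below instrument precision for peptides.
2. **Consecutive charge states.** Without readable spacing, a species
   is accepted only if ions of at least two consecutive charge states
   of that species are matched (20 ppm default) somewhere in the peak
   list. A single charge state without spacing is never accepted.

Ties among remaining candidates go to the lowest oligomer order
(parsimony).

## Mobilogram deconvolution

A drift-time trace is modelled as

```
f_im(x) = k_im + Σ_N A_N * (2*sqrt(ln 2)/(w_N*sqrt(pi))) * exp(-4*ln2*(x-x_cN)^2 / w_N^2)
```

i.e. a constant baseline plus Gaussians parameterised by center `x_c`
(ms), full width at half height `w` (ms) and area `A`. Fitting is
nonlinear least squares (lmfit, trust-region-reflective backend, which
tolerates parameters starting on a bound; tolerances 1e-10, bounds keep
centers on the axis and widths/areas positive). Initial guesses are
prominence-ranked local maxima of a lightly smoothed trace, making fits
deterministic. When the component count is not fixed it is chosen by
corrected AIC (least-squares form, unknown noise variance), with a
four-points-per-free-parameter floor.

Component areas are the quantities that matter downstream: within a
shared channel, each species' contribution is its component area over
the summed component area.

Peak widths of a given species can be compared between samples
(unpaired two-tailed t-test); wider mobility peaks indicate a broader
conformational ensemble during the separation.

## Population statistic

For channels `c` with intensity `I_c` and contributor fractions
`f_c(s)` (mobilogram-derived for shared channels, `{s: 1}` for
unambiguous ones):

```
population(s) = Σ_c I_c f_c(s) / Σ_c I_c
```

summing only over channels whose contributors are established;
channels that cannot be assigned are excluded from numerator **and**
denominator, and their summed intensity is reported so the exclusion is
auditable. The statistic is scale invariant; intensities are arbitrary
counts. Replicates are aggregated as mean ± sample s.d.; samples are
compared per species by unpaired two-tailed t-tests with Holm
adjustment across species.

Implicit assumption (inherited from the underlying protocol): summed
charge-state intensity is proportional to solution abundance, i.e.
ionisation/transmission efficiency does not vary systematically with
oligomer order. This is a known approximation of the method, not of
this implementation.

## T-wave CCS calibration

Traveling-wave drift times have no closed-form mobility relation, so Ω
is calibrated against denatured protein standards:

```
t_d' = t_d - c*sqrt(m/z)/1000          (mass-dependent flight correction)
Ω'   = Ω_ref / (z*sqrt(1/μ)),  μ = m*M_gas/(m+M_gas)
ln Ω' = ln A + X ln t_d'               (ordinary least squares in log space)
```

An unknown's Ω is `A * t_d'^X * z * sqrt(1/μ)`, derived **only** for
corrected drift times inside the calibrated range — a power law fitted
over a finite span has no quantitative meaning outside it, so
out-of-range queries raise. An explicit `extrapolate=True` flag exists
solely for qualitative candidate ranking (below) and must never be
reported as a measurement. The calibration record carries `c`, `A`,
`X`, r², the gas and the validity range.

The shipped calibrant table (denatured ubiquitin +9…+11, myoglobin
+15…+22, cytochrome C +11…+18; 19 ions) carries literature-derived
helium reference cross-sections and is documented as a replaceable
default; quantitative work should supply its own table.

## Mobility-informed assignment of shared channels

For an n/z-degenerate channel the grid lists the co-located candidates;
deciding which fitted mobility component belongs to which candidate
uses three rules in order of trust:

1. **Per-peak isotope spacing.** Mobility separation yields a clean
   m/z spectrum for each mobility peak, whose isotopologue spacing
   reveals that peak's charge even when the summed spectrum is
   congested. Each spacing anchor claims the *nearest* fitted
   component (within `max(w, 0.5 ms)`); anchor-centric matching
   prevents a small spurious component adjacent to an anchored peak
   from stealing its label.
2. **Cross-section plausibility.** When a calibration is available,
   the size-scaling prefactor Ω₁ of a globular prior
   `Ω(n) = Ω₁ n^(2/3)` is estimated from all positively identified
   components (log-mean). An unlabelled component then takes the
   unclaimed candidate whose implied Ω (extrapolation permitted here,
   qualitatively) best matches its order's expectation, by absolute
   log-ratio.
3. **Parsimony.** Remaining components assume the lowest unclaimed
   orders; since at fixed m/z the higher-order ion has the smaller
   charge-normalised cross-section and hence the shorter drift time,
   components in ascending drift time take candidates in descending
   order.

Channel fitting uses the number of spacing anchors as a *lower* bound
on the component count (scanning up to four by corrected AIC, initial
centers seeded at the anchor drift times), and components carrying
less than 1% of the channel area are pruned as noise pickup with the
surviving model refit.

## Hard-sphere cross-sections

Atoms are hard spheres of Bondi van der Waals radius plus a probe
radius (helium, 1.0 Å by default; unknown elements fall back to 1.70 Å
with a warning).

* **Projection approximation (PA):** the shadow area averaged over
  uniformly random orientations, estimated by uniform sampling of a
  bounding disk. A strict lower bound on Ω.
* **Exact hard-sphere scattering (EHSS):** specular-reflection
  trajectories (vectorised nearest-intersection ray tracing, bounce cap
  30 with warning); each trajectory contributes the momentum-transfer
  weight `1 − cos χ` with χ its total deflection. Multiple scattering
  in concave regions makes EHSS ≥ PA, equal for convex bodies; for a
  single sphere both equal `π (r + r_gas)²` exactly.

Both report a Monte Carlo standard error combining between-orientation
variance and within-orientation binomial/weight variance, and are
reproducible given a seed. Model ensembles are averaged with the
between-member s.d.; model ranking against experimental Ω is by
absolute deviation from the experimental mean with name-order tie
breaks.

## Synthetic study conditions

The default ground truth emulates a low-molecular-weight sample of an
aggregating 40-residue peptide and is used as-is by the tests — its
parameters are study conditions, not tuning knobs:

* distribution M 0.45, D 0.30, Tr 0.15, Te 0.07, P 0.02, Hx 0.01;
* three charge states per order (z ∈ {n+2, n+3, n+4}, monomer
  {2, 3, 4}) weighted 0.25/0.50/0.25;
* globular size scaling Ω(n) = 630 Å² · n^(2/3), linked to drift times
  by inverting the *same* power law the calibration stage fits
  (A = 450, X = 0.55, c = 1.41, N₂), so calibration and assignment can
  be tested round-trip;
* instrument resolution 10 000 (m/Δm FWHM): channels closer than one
  peak width merge, their summed-spectrum spacing becomes unreadable,
  and each contributor's share is recorded as truth;
* mobility peaks of FWHM 0.8 ms; intensity noise log-normal (5%
  relative by default), mobilogram noise 1% of the tallest peak;
* per-mobility-peak spacing anchors are emitted when the spacing
  exceeds **half** a peak width — mobility separation leaves a clean
  single-species isotopologue cluster, so a finer spacing is readable
  there than in the congested summed spectrum (which needs a full peak
  width); peaks below that limit carry no anchor and exercise the
  fallback rules.

## Limitations

* The aggregated isotope model places isotopologues on an exact
  `1.003355/z` ladder; fine structure (e.g. ¹⁵N vs ¹³C mass defects)
  is not modelled — irrelevant at resolution 10⁴, visible at FT-class
  resolution.
* Ω extrapolation beyond the calibrant range is qualitative by design;
  oligomer ions far outside the denatured-calibrant mobility range get
  plausibility ranks, never reported cross-sections.
* The population statistic assumes order-independent ionisation
  efficiency (see above).
* Replicate-shared peak widths (fitting one width per species across
  replicates) are a possible extension, not implemented.
* EHSS treats collisions as elastic specular hard-sphere events; no
  long-range potential or diffuse scattering (trajectory-method
  refinements) is included.
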