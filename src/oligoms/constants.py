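"""Physical constants and element data used throughout the package.

All masses are in daltons (Da), m/z in thomson (Th), lengths in angstrom,
drift times in milliseconds. Every unit conversion in the package goes
through the values defined here.
"""

from __future__ import annotations

# Mass of a proton (charge carrier in positive ESI), Da.
PROTON_MASS = 1.007276

# Mass difference between carbon-13 and carbon-12, Da. Adjacent
# isotopologues of a peptide ion are spaced by this value divided by the
# charge, which is what makes the charge state readable off the raw
# spectrum.
C13_C12_DELTA = 1.003355

# Hydrogen atom masses, Da. Covalent cross-linking (e.g. PICUP dityrosine
# chemistry) removes two hydrogen atoms per bond formed.
H_MASS_MONO = 1.007825
H_MASS_AVG = 1.00794

# Drift gas molecular masses, Da, for the reduced-mass term of the
# traveling-wave CCS calibration.
GAS_MASS = {
    "N2": 28.0134,
    "He": 4.0026,
}

# Bondi van der Waals radii by element, angstrom. Used as hard-sphere
# radii in the projection-approximation and EHSS cross-section
# calculations. Elements missing from the table fall back to
# DEFAULT_VDW_RADIUS with a warning.
BONDI_VDW_RADIUS = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "ZN": 1.39,
    "FE": 1.63,
    "CU": 1.40,
}
DEFAULT_VDW_RADIUS = 1.70

# Default probe (buffer-gas) radius for hard-sphere CCS, angstrom.
# Helium is the conventional gas of the EHSS literature.
HELIUM_PROBE_RADIUS = 1.0

# Canonical amyloid-beta sequences (one-letter codes).
ABETA40_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV"
ABETA42_SEQUENCE = ABETA40_SEQUENCE + "IA"
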