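"""Embedded atomic data: monoisotopic masses and isotope abundances.

Values follow the 2021 IUPAC/CIAAW recommendations (representative
abundances, rounded as commonly tabulated).  Isotope distributions are
stored per element as relative abundances indexed by nominal-mass offset
from the most abundant (lightest listed) isotope; gaps (e.g. the missing
A+1 isotope of chlorine) are explicit zeros so that offsets line up under
convolution.
"""

from __future__ import annotations

# Monoisotopic (most abundant isotope) masses in Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984031700,
    "S": 31.9720706900,
    "P": 30.9737615100,
    "Cl": 34.9688527100,
    "Br": 78.9183376000,
    "Si": 27.9769265327,
}

# Relative isotope abundance by nominal mass offset (index 0 = monoisotopic),
# normalised to sum 1 per element.
ISOTOPE_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "H": (0.999885, 0.000115),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "F": (1.0,),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "P": (1.0,),
    "Cl": (0.7576, 0.0, 0.2424),
    "Br": (0.5069, 0.0, 0.4931),
    "Si": (0.92223, 0.04685, 0.03092),
}

# Standard atomic weights (for molar-mass conversion in quantitation).
ATOMIC_WEIGHT: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "S": 32.06,
    "P": 30.973761998,
    "Cl": 35.45,
    "Br": 79.904,
    "Si": 28.085,
}

KNOWN_ELEMENTS: tuple[str, ...] = tuple(MONOISOTOPIC_MASS)

# Default formula alphabet for this workflow: the four parent pharmaceuticals
# contain C/H/N/O/S/F only, and oxidative phototransformation does not
# introduce new heteroatoms.  Cl/Br/Si/P stay available for candidate
# filtering but are excluded from formula generation by default.
DEFAULT_ALPHABET: tuple[str, ...] = ("C", "H", "N", "O", "S", "F")

# Proton mass relevant for [M+H]+ adducts (electron mass subtracted).
PROTON_MASS = 1.007276
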