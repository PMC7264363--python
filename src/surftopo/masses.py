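"""Monoisotopic mass arithmetic for the label and artefact modifications.

The reduced Sulfo-NHS-SS-biotin remnant left on a labelled primary amine after
DTT elution is a thioacyl group (+87.9983 Da); iodoacetamide alkylation of its
free thiol adds a carbamidomethyl group, giving CAMthiopropanoyl (+145.0198 Da).
Spontaneous (or PNGaseF-induced) asparagine deamidation (+0.984 Da) is a
confounding modification that must never be counted as label evidence.

Atomic masses are embedded as constants (IUPAC monoisotopic values) so the mass
arithmetic is self-contained and testable without external tables.
"""

from __future__ import annotations

import re

#: Monoisotopic atomic masses (Da) for the elements occurring in the
#: modifications handled here.
MONOISOTOPIC_ELEMENT_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental composition string such as ``"C3H4OS"``.

    Returns a dict of element -> count.  Raises ``ValueError`` for unknown
    element symbols or malformed input.
    """
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(
                f"malformed formula {formula!r} at position {pos}"
            )
        pos = match.end()
        element, digits = match.groups()
        if element not in MONOISOTOPIC_ELEMENT_MASS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r} at position {pos}")
    return counts


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of an elemental composition string.

    >>> round(monoisotopic_mass("C3H4OS"), 4)
    87.9983
    """
    return sum(
        count * MONOISOTOPIC_ELEMENT_MASS[element]
        for element, count in parse_formula(formula).items()
    )


# Elemental compositions of the label remnants.  The thioacyl remnant is
# C3H4OS; alkylation adds a carbamidomethyl group (C2H3NO).
THIOACYL_FORMULA = "C3H4OS"
CARBAMIDOMETHYL_FORMULA = "C2H3NO"
CAMTHIOPROPANOYL_FORMULA = "C5H7NO2S"

THIOACYL_MASS = monoisotopic_mass(THIOACYL_FORMULA)
CARBAMIDOMETHYL_MASS = monoisotopic_mass(CARBAMIDOMETHYL_FORMULA)
CAMTHIOPROPANOYL_MASS = monoisotopic_mass(CAMTHIOPROPANOYL_FORMULA)

#: Deamidation replaces an amide NH with OH: net O - N - H.
DEAMIDATION_MASS = (
    MONOISOTOPIC_ELEMENT_MASS["O"]
    - MONOISOTOPIC_ELEMENT_MASS["N"]
    - MONOISOTOPIC_ELEMENT_MASS["H"]
)

#: Label masses as printed in search-engine configurations (4 decimals).
DEFAULT_LABEL_MASSES: tuple[float, float] = (87.9983, 145.0198)
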