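"""Fusion-tag mass arithmetic and glycosylation-shift calls.

Expected molecular masses of epitope-tagged fusion proteins are
computed from sequence using standard average (isotope-abundance
weighted) amino-acid residue masses, uncharged and without
post-translational modifications — the quantity compared against
SDS-PAGE mobility. The N-terminal appendage of the library is the 3xHA
epitope tag followed by the L2 linker; its mass is a constant of the
library.

A PNGase mobility-shift call flags a protein as glycosylated when the
apparent mass drops by at least a threshold (default 1 kDa) after
enzymatic glycan removal.

Residue masses are the standard average masses of the 20 amino-acid
residues (monomer minus one water), as tabulated in the ExPASy/IUPAC
reference data; adding one water (18.0153 Da) per chain gives the
peptide mass.
"""

from __future__ import annotations

from dataclasses import dataclass

WATER_DA = 18.0153

# average residue masses (Da): amino acid minus one water
AVERAGE_RESIDUE_MASS_DA: dict[str, float] = {
    "G": 57.0519,
    "A": 71.0788,
    "S": 87.0782,
    "P": 97.1167,
    "V": 99.1326,
    "T": 101.1051,
    "C": 103.1388,
    "L": 113.1594,
    "I": 113.1594,
    "N": 114.1038,
    "D": 115.0886,
    "Q": 128.1307,
    "K": 128.1741,
    "E": 129.1155,
    "M": 131.1926,
    "H": 137.1411,
    "F": 147.1766,
    "R": 156.1875,
    "Y": 163.1760,
    "W": 186.2132,
}

HA3_TAG = "MYPYDVPDYAGYPYDVPDYAGSYPYDVPDYA"  # 3x YPYDVPDYA epitope
L2_LINKER = "GGSSGGGGATENSS"
FUSION_APPENDAGE = HA3_TAG + L2_LINKER


def peptide_average_mass(sequence: str) -> float:
    """Average molecular mass of a peptide in Da.

    Sum of average residue masses plus one water. Raises ``ValueError``
    on an empty sequence or any character outside the 20 one-letter
    codes.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = WATER_DA
    for i, aa in enumerate(sequence):
        try:
            total += AVERAGE_RESIDUE_MASS_DA[aa]
        except KeyError:
            raise ValueError(
                f"invalid amino-acid code {aa!r} at position {i + 1}"
            ) from None
    return total


def fusion_appendage_mass() -> float:
    """Mass of the 3xHA tag + L2 linker appendage, in kDa (one decimal)."""
    return round(peptide_average_mass(FUSION_APPENDAGE) / 1000.0, 1)


@dataclass(frozen=True)
class BandPair:
    """Apparent masses of one protein with and without PNGase treatment."""

    protein_id: str
    mass_untreated: float  # kDa
    mass_treated: float  # kDa

    def __post_init__(self) -> None:
        if self.mass_untreated <= 0 or self.mass_treated <= 0:
            raise ValueError("band masses must be positive")


def call_glyco_shift(band: BandPair, min_shift: float = 1.0) -> tuple[bool, float]:
    """Call a PNGase-induced mobility shift.

    Returns ``(shifted, delta)`` with delta = untreated - treated (kDa);
    shifted iff delta >= min_shift.
    """
    if min_shift <= 0:
        raise ValueError("min_shift must be positive")
    delta = band.mass_untreated - band.mass_treated
    return delta >= min_shift, delta
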