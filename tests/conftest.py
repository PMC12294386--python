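"""Shared fixtures: bundled reference data, golden values, independent oracles."""

from __future__ import annotations

import pytest

from hydropep import refio

#: the six consolidated bioactive peptides of the hydrolysate study
SIX_BAPS = (
    "TNVPRASVPDGFLS",
    "TNVPRASVPDGFLSEL",
    "DAVEDLESVGK",
    "EGIPPDQQRLIFAGK",
    "TITLEVEPSDTIENVK",
    "VHVVPDQLMAF",
)

#: published frequency-of-bioactive-fragment scores, 4 decimals
GOLDEN_BF = (
    ("TNVPRASVPDGFLS", "ACE-inhibitor", 0.4286),
    ("TNVPRASVPDGFLS", "DPP-IV-inhibitor", 0.6429),
    ("TNVPRASVPDGFLSEL", "ACE-inhibitor", 0.3750),
    ("TNVPRASVPDGFLSEL", "DPP-IV-inhibitor", 0.5625),
    ("DAVEDLESVGK", "ACE-inhibitor", 0.5455),
    ("DAVEDLESVGK", "DPP-IV-inhibitor", 0.4545),
    ("EGIPPDQQRLIFAGK", "DPP-IV-inhibitor", 0.6667),
    ("EGIPPDQQRLIFAGK", "ACE-inhibitor", 0.6000),
    ("TITLEVEPSDTIENVK", "DPP-IV-inhibitor", 0.5625),
    ("TITLEVEPSDTIENVK", "ACE-inhibitor", 0.2500),
    ("VHVVPDQLMAF", "DPP-IV-inhibitor", 0.8182),
    ("VHVVPDQLMAF", "ACE-inhibitor", 0.1818),
)

#: independently transcribed monoisotopic residue masses (Da)
RESIDUE_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_MONO = 18.010565


def mass_oracle(sequence: str) -> float:
    """Independent residue-table mass sum (monoisotopic, +water)."""
    return sum(RESIDUE_MONO[aa] for aa in sequence) + WATER_MONO


def count_oracle(sequence: str, motifs) -> int:
    """Quadratic brute-force occurrence count over all start positions."""
    total = 0
    for motif in motifs:
        for i in range(len(sequence) - len(motif) + 1):
            if sequence[i:i + len(motif)] == motif:
                total += 1
    return total


@pytest.fixture(scope="session")
def motif_sets():
    return refio.bundled_motifs()


@pytest.fixture(scope="session")
def bioactive_entries():
    return refio.bundled_bioactive_entries()


@pytest.fixture(scope="session")
def parent_proteins():
    return refio.bundled_parent_proteins()
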