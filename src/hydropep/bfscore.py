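"""Frequency-of-bioactive-fragments (BF, BIOPEP-style A index) scoring.

For a peptide of N residues and an activity-specific motif set, the score is

    BF = a / N

where ``a`` is the total number of motif occurrences in the peptide:
occurrences may overlap, each start position of each motif counts once, and
distinct motifs starting at the same position each count.  This per-position,
per-motif convention is the one under which the pinned motif snapshot
reproduces published frequency values for hydrolysate peptides.

Band interpretation: BF >= 0.5 marks a high frequency of bioactive motifs
(more than half the residues lie under known functional fragments), 0.2 <=
BF < 0.5 a moderate one, and BF < 0.2 a low density of bioactive fragments.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .refio import MotifSet, ValidationError, bundled_motifs  # noqa: F401

#: decimals used for BF in reports; full precision is kept internally
REPORT_DECIMALS = 4


class Band(enum.Enum):
    HIGH = "high"
    MODERATE = "moderate"
    LOW = "low"


@dataclass(frozen=True)
class BFResult:
    peptide: str
    activity: str
    a: int
    N: int
    bf: float
    band: Band

    @property
    def bf_rounded(self) -> float:
        # round-half-even, matching the precision of published tables
        return round(self.bf, REPORT_DECIMALS)


def count_occurrences(sequence: str, motifs: MotifSet) -> int:
    """Total (overlapping) motif occurrences of the set in ``sequence``."""
    if not sequence:
        raise ValidationError("empty sequence")
    sequence = sequence.upper()
    total = 0
    for motif in motifs.motifs:
        start = sequence.find(motif)
        while start != -1:
            total += 1
            start = sequence.find(motif, start + 1)
    return total


def bf(sequence: str, motifs: MotifSet) -> BFResult:
    """Score ``sequence`` against one activity's motif set."""
    a = count_occurrences(sequence, motifs)
    n = len(sequence)
    value = a / n
    return BFResult(
        peptide=sequence.upper(),
        activity=motifs.activity,
        a=a,
        N=n,
        bf=value,
        band=band(value),
    )


def band(bf_value: float) -> Band:
    """Band a BF value: >=0.5 HIGH, [0.2, 0.5) MODERATE, <0.2 LOW."""
    if bf_value < 0:
        raise ValidationError(f"negative BF value {bf_value}")
    if bf_value >= 0.5:
        return Band.HIGH
    if bf_value >= 0.2:
        return Band.MODERATE
    return Band.LOW


def score_peptides(
    peptides: list[str], motif_sets: dict[str, MotifSet]
) -> list[BFResult]:
    """BF of every peptide against every activity, in stable order."""
    return [
        bf(p, motif_sets[activity])
        for p in peptides
        for activity in sorted(motif_sets)
    ]
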