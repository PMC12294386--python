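"""Absolute quantification from spiked heavy-isotope (AQUA) peptide standards.

A synthetic heavy-labelled analogue of each target peptide is spiked at a
known amount H (pmol) and co-analysed with the endogenous light peptide.  The
endogenous amount follows from the chromatographic peak-area ratio,

    L = (area_light / area_heavy) * H        [pmol]

and is normalised to the composition as picograms of peptide per microgram of
total peptide on column,

    pg/ug = L * M / m_total

since 1 pmol of a peptide of monoisotopic mass M Da weighs M pg.  The heavy
label's mass shift only separates the chromatogram channels; it never enters
the arithmetic.  Replicate batches are combined by arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Iterable

from pyteomics import mass as _pmass
from pyteomics.auxiliary import PyteomicsError

from .refio import ValidationError, clean_sequence

DEFAULT_TOTAL_PEPTIDE_UG = 10.0


@dataclass(frozen=True)
class QuantInput:
    """One light/heavy area pair for a peptide in one product batch."""

    peptide: str
    H: float  # heavy spike on column, pmol
    light_area: float
    heavy_area: float
    total_peptide_ug: float = DEFAULT_TOTAL_PEPTIDE_UG
    product_id: str = ""
    batch_id: str = ""

    def __post_init__(self) -> None:
        if self.H <= 0:
            raise ValidationError(f"{self.peptide}: heavy spike H must be > 0")
        if self.heavy_area <= 0:
            raise ValidationError(f"{self.peptide}: heavy_area must be > 0")
        if self.light_area < 0:
            raise ValidationError(f"{self.peptide}: negative light_area")
        if self.total_peptide_ug <= 0:
            raise ValidationError(f"{self.peptide}: total_peptide_ug must be > 0")


@dataclass(frozen=True)
class QuantResult:
    peptide: str
    L: float  # endogenous light amount, pmol
    mass: float  # Da
    pg_per_ug: float
    product_id: str = ""
    batch_id: str = ""


def peptide_mass(sequence: str, kind: str = "mono") -> float:
    """Mass in Da of the unlabelled, unmodified peptide (residues + water).

    ``kind`` is ``"mono"`` (monoisotopic, the targeted-proteomics norm) or
    ``"average"``.
    """
    if kind not in ("mono", "average"):
        raise ValueError(f"kind must be 'mono' or 'average', got {kind!r}")
    sequence = clean_sequence(sequence)
    try:
        return _pmass.calculate_mass(sequence=sequence, average=(kind == "average"))
    except PyteomicsError as exc:  # pragma: no cover - clean_sequence guards
        raise ValidationError(str(exc)) from exc


def light_amount(q: QuantInput) -> float:
    """Endogenous amount L = (light/heavy area ratio) x H, in pmol."""
    return (q.light_area / q.heavy_area) * q.H


def pg_per_ug(L: float, mass: float, total_ug: float = DEFAULT_TOTAL_PEPTIDE_UG) -> float:
    """Normalise L pmol of a mass-Da peptide to pg per ug of total peptide."""
    if total_ug <= 0:
        raise ValidationError(f"total_ug must be > 0, got {total_ug}")
    return L * mass / total_ug


def quantify(q: QuantInput, kind: str = "mono") -> QuantResult:
    """Full quantification of one light/heavy observation."""
    L = light_amount(q)
    m = peptide_mass(q.peptide, kind=kind)
    return QuantResult(
        peptide=q.peptide,
        L=L,
        mass=m,
        pg_per_ug=pg_per_ug(L, m, q.total_peptide_ug),
        product_id=q.product_id,
        batch_id=q.batch_id,
    )


def average_over_batches(
    results: Iterable[QuantResult],
) -> dict[tuple[str, str], tuple[float, int]]:
    """Mean pg/ug per (peptide, product) with the number of batches averaged."""
    groups: dict[tuple[str, str], list[float]] = {}
    for r in results:
        groups.setdefault((r.peptide, r.product_id), []).append(r.pg_per_ug)
    return {key: (fmean(vals), len(vals)) for key, vals in groups.items()}
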