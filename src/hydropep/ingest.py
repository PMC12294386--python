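"""Filtering and merging of identification records into per-product peptide sets.

Search-engine exports arrive as one row per observation (product x batch x
fraction).  This module applies the identification acceptance rules — peptide
length between 4 and 65 residues inclusive and a peptide-level FDR pass flag —
and pools the survivors into one unique-peptide set per product, retaining
batch provenance.  A peptide belongs to a product if it was identified in at
least ``min_batches`` of that product's batches (default 1, i.e. pooling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .refio import IdentRecord

DEFAULT_MIN_LEN = 4
DEFAULT_MAX_LEN = 65


class ConfigError(ValueError):
    """Invalid filtering or pooling configuration."""


@dataclass
class PeptideSet:
    """Unique peptides of one product with per-peptide batch provenance."""

    product_id: str
    peptides: set[str] = field(default_factory=set)
    per_peptide_batches: dict[str, set[str]] = field(default_factory=dict)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.peptides

    def __len__(self) -> int:
        return len(self.peptides)


def filter_idents(
    records: list[IdentRecord],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    require_fdr: bool = True,
) -> list[IdentRecord]:
    """Keep records with min_len <= length <= max_len that pass FDR.

    Both length bounds are inclusive. Order is preserved, so the filter is
    idempotent.
    """
    if min_len > max_len:
        raise ConfigError(f"min_len {min_len} > max_len {max_len}")
    return [
        r
        for r in records
        if min_len <= r.length <= max_len and (r.fdr_pass or not require_fdr)
    ]


def build_peptide_sets(
    records: list[IdentRecord], min_batches: int = 1
) -> dict[str, PeptideSet]:
    """Pool filtered records into one :class:`PeptideSet` per product.

    ``min_batches`` raises the membership requirement from "seen in any batch"
    to "seen in at least that many distinct batches of the product".
    """
    if min_batches < 1:
        raise ConfigError(f"min_batches must be >= 1, got {min_batches}")
    provenance: dict[str, dict[str, set[str]]] = {}
    for rec in records:
        provenance.setdefault(rec.product_id, {}).setdefault(
            rec.sequence, set()
        ).add(rec.batch_id)
    out: dict[str, PeptideSet] = {}
    for product, by_pep in provenance.items():
        kept = {p: b for p, b in by_pep.items() if len(b) >= min_batches}
        out[product] = PeptideSet(
            product_id=product,
            peptides=set(kept),
            per_peptide_batches=kept,
        )
    return out


def shared_peptides(set_a: PeptideSet, set_b: PeptideSet) -> set[str]:
    """Exact-string intersection of two products' peptide sets."""
    return set_a.peptides & set_b.peptides
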