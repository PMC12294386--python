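"""Parent-protein mapping and bioactive-database cross-referencing.

A peptide identified in a hydrolysate is annotated two ways: by locating every
occurrence of it inside the parent proteome (proteoform ambiguity is real in
hydrolysates, so all parents and all occurrences are kept), and by relating it
to reference bioactive entries.  Three relations are searched for every
(peptide, entry) pair: the peptide equals the entry, the peptide is a proper
substring of a longer catalogued peptide, or a catalogued fragment sits inside
the peptide.  Containment relations honour a minimum contained-sequence length
(default 4, the identification minimum) to avoid spurious short matches.

Hits carry 0-based, half-open coordinates into the containing sequence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .ingest import PeptideSet
from .refio import BioactiveEntry, ProteinRecord, ValidationError

DEFAULT_MIN_CONTAINED_LEN = 4


class Relation(enum.Enum):
    EXACT = "exact"
    PEPTIDE_IN_ENTRY = "peptide_in_entry"
    ENTRY_IN_PEPTIDE = "entry_in_peptide"
    PEPTIDE_IN_PARENT = "peptide_in_parent"


@dataclass(frozen=True)
class AnnotationHit:
    """One located match between a peptide and a containing sequence."""

    peptide: str
    target_id: str  # entry_id for database relations, accession for parents
    relation: Relation
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValidationError(f"bad hit coordinates [{self.start}, {self.end})")


@dataclass
class BAPRecord:
    """A consolidated bioactive peptide: one row per (peptide, activity)."""

    peptide: str
    activity: str
    parent_accession: str = ""
    parent_name: str = ""
    evidence: list[AnnotationHit] = field(default_factory=list)
    products: set[str] = field(default_factory=set)
    flagged: bool = False  # annotated but absent from every product's peptide set


def find_occurrences(needle: str, haystack: str) -> list[int]:
    """All (possibly overlapping) 0-based start offsets of needle in haystack."""
    starts: list[int] = []
    i = haystack.find(needle)
    while i != -1:
        starts.append(i)
        i = haystack.find(needle, i + 1)
    return starts


def map_to_parents(
    peptide: str, proteins: Iterable[ProteinRecord]
) -> list[AnnotationHit]:
    """Locate every occurrence of ``peptide`` in every parent protein.

    One hit per occurrence; ordered by (accession, start).
    """
    if not peptide:
        raise ValidationError("empty peptide")
    peptide = peptide.upper()
    hits = [
        AnnotationHit(
            peptide=peptide,
            target_id=prot.accession,
            relation=Relation.PEPTIDE_IN_PARENT,
            start=s,
            end=s + len(peptide),
        )
        for prot in sorted(proteins, key=lambda p: p.accession)
        for s in find_occurrences(peptide, prot.sequence)
    ]
    return hits


def cross_reference(
    peptides: Iterable[str],
    entries: Iterable[BioactiveEntry],
    min_contained_len: int = DEFAULT_MIN_CONTAINED_LEN,
) -> list[AnnotationHit]:
    """Relate peptides to reference entries by equality or containment.

    EXACT hits ignore ``min_contained_len``; for the two proper-containment
    relations the contained sequence must reach that length.
    """
    hits: list[AnnotationHit] = []
    entries = list(entries)
    for peptide in sorted({p.upper() for p in peptides}):
        for entry in entries:
            eseq = entry.sequence
            if peptide == eseq:
                hits.append(
                    AnnotationHit(peptide, entry.entry_id, Relation.EXACT,
                                  0, len(peptide))
                )
                continue
            if len(peptide) >= min_contained_len and peptide in eseq:
                for s in find_occurrences(peptide, eseq):
                    hits.append(
                        AnnotationHit(peptide, entry.entry_id,
                                      Relation.PEPTIDE_IN_ENTRY, s,
                                      s + len(peptide))
                    )
            if len(eseq) >= min_contained_len and eseq in peptide:
                for s in find_occurrences(eseq, peptide):
                    hits.append(
                        AnnotationHit(peptide, entry.entry_id,
                                      Relation.ENTRY_IN_PEPTIDE, s,
                                      s + len(eseq))
                    )
    return hits


def consolidate(
    hits: Iterable[AnnotationHit],
    entries: Iterable[BioactiveEntry],
    proteins: Iterable[ProteinRecord],
    peptide_sets: Mapping[str, PeptideSet],
) -> list[BAPRecord]:
    """Collapse annotation hits into one record per (peptide, activity).

    The activity is inherited from the matched entries; a peptide matching
    entries of different activities yields one record per activity
    (multifunctional peptides are real).  The parent accession comes from
    direct parent-mapping hits when present, else from the matched entry's
    catalogued parent.  Products are the peptide sets containing the peptide;
    a peptide with database evidence but no product membership is kept and
    flagged.
    """
    entry_by_id = {e.entry_id: e for e in entries}
    protein_by_acc = {p.accession: p for p in proteins}
    hits = list(hits)
    db_hits: dict[str, list[AnnotationHit]] = {}
    parent_hits: dict[str, list[AnnotationHit]] = {}
    for h in hits:
        if h.relation is Relation.PEPTIDE_IN_PARENT:
            parent_hits.setdefault(h.peptide, []).append(h)
        else:
            db_hits.setdefault(h.peptide, []).append(h)

    records: list[BAPRecord] = []
    for peptide in sorted(db_hits):
        by_activity: dict[str, list[AnnotationHit]] = {}
        for h in db_hits[peptide]:
            activity = entry_by_id[h.target_id].activity
            by_activity.setdefault(activity, []).append(h)
        for activity in sorted(by_activity):
            evidence = by_activity[activity] + parent_hits.get(peptide, [])
            parents = sorted({h.target_id for h in parent_hits.get(peptide, [])})
            if not parents:
                parents = sorted(
                    {
                        entry_by_id[h.target_id].parent_accession
                        for h in by_activity[activity]
                        if entry_by_id[h.target_id].parent_accession
                    }
                )
            products = {
                pid for pid, pset in peptide_sets.items() if peptide in pset
            }
            records.append(
                BAPRecord(
                    peptide=peptide,
                    activity=activity,
                    parent_accession=",".join(parents),
                    parent_name=",".join(
                        protein_by_acc[a].name
                        for a in parents
                        if a in protein_by_acc
                    ),
                    evidence=evidence,
                    products=products,
                    flagged=not products,
                )
            )
    return records
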