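"""Parent mapping, database cross-referencing, consolidation."""

from __future__ import annotations

import random

import pytest

from hydropep.annotate import (
    Relation,
    consolidate,
    cross_reference,
    find_occurrences,
    map_to_parents,
)
from hydropep.ingest import PeptideSet
from hydropep.refio import BioactiveEntry, ProteinRecord, ValidationError
from tests.conftest import SIX_BAPS


def protein(acc, seq):
    return ProteinRecord(accession=acc, name=acc, sequence=seq)


class TestMapToParents:
    def test_single_occurrence_in_mif(self, parent_proteins):
        hits = map_to_parents("VHVVPDQLMAF", parent_proteins)
        assert len(hits) == 1
        hit = hits[0]
        assert hit.target_id == "P14174"
        assert hit.relation is Relation.PEPTIDE_IN_PARENT
        mif = next(p for p in parent_proteins if p.accession == "P14174")
        assert mif.sequence[hit.start:hit.end] == "VHVVPDQLMAF"

    def test_overlapping_occurrences_all_reported(self):
        hits = map_to_parents("AA", [protein("X", "AAAA")])
        assert [h.start for h in hits] == [0, 1, 2]

    def test_absent_peptide_empty(self, parent_proteins):
        assert map_to_parents("WWWWWW", parent_proteins) == []

    def test_empty_peptide_rejected(self, parent_proteins):
        with pytest.raises(ValidationError):
            map_to_parents("", parent_proteins)

    def test_order_by_accession_then_start(self):
        prots = [protein("B", "AACAA"), protein("A", "AA")]
        hits = map_to_parents("AA", prots)
        assert [(h.target_id, h.start) for h in hits] == [("A", 0), ("B", 0), ("B", 3)]


class TestCrossReference:
    def entry(self, eid, seq, activity="antimicrobial"):
        return BioactiveEntry(entry_id=eid, sequence=seq, activity=activity)

    def test_peptide_inside_larger_entry(self, bioactive_entries):
        hits = cross_reference(["DAVEDLESVGK"], bioactive_entries)
        rels = {(h.target_id, h.relation) for h in hits}
        assert ("BP0567", Relation.PEPTIDE_IN_ENTRY) in rels

    def test_exact_match(self):
        hits = cross_reference(["AAAA"], [self.entry("E", "AAAA")])
        assert [h.relation for h in hits] == [Relation.EXACT]
        assert (hits[0].start, hits[0].end) == (0, 4)

    def test_entry_inside_peptide(self):
        hits = cross_reference(["CCAAAACC"], [self.entry("E", "AAAA")])
        assert [h.relation for h in hits] == [Relation.ENTRY_IN_PEPTIDE]
        assert "CCAAAACC"[hits[0].start:hits[0].end] == "AAAA"

    def test_no_relation_no_hit(self):
        assert cross_reference(["DDDD"], [self.entry("E", "AAAA")]) == []

    def test_short_containment_suppressed_by_min_len(self):
        entries = [self.entry("E", "CCAAACC")]
        assert cross_reference(["AAA"], entries, min_contained_len=4) == []
        hits = cross_reference(["AAA"], entries, min_contained_len=3)
        assert [h.relation for h in hits] == [Relation.PEPTIDE_IN_ENTRY]

    def test_containment_symmetric_under_swap(self):
        pep, ent = "AAAACC", "AAAA"
        fwd = cross_reference([pep], [self.entry("E", ent)])
        rev = cross_reference([ent], [self.entry("E", pep)])
        assert [h.relation for h in fwd] == [Relation.ENTRY_IN_PEPTIDE]
        assert [h.relation for h in rev] == [Relation.PEPTIDE_IN_ENTRY]

    def test_slices_check_out_by_construction(self, bioactive_entries):
        entry_by_id = {e.entry_id: e for e in bioactive_entries}
        hits = cross_reference(SIX_BAPS, bioactive_entries)
        assert hits
        for h in hits:
            entry_seq = entry_by_id[h.target_id].sequence
            if h.relation in (Relation.EXACT, Relation.PEPTIDE_IN_ENTRY):
                assert entry_seq[h.start:h.end] == h.peptide
            else:
                assert h.peptide[h.start:h.end] == entry_seq

    def test_matches_quadratic_brute_force_on_random_inputs(self):
        rng = random.Random(202)
        alphabet = "ACDG"
        for _ in range(20):
            peptides = [
                "".join(rng.choices(alphabet, k=rng.randint(4, 10)))
                for _ in range(rng.randint(1, 30))
            ]
            entries = [
                BioactiveEntry(
                    entry_id=f"E{i}",
                    sequence="".join(rng.choices(alphabet, k=rng.randint(4, 12))),
                    activity="x",
                )
                for i in range(rng.randint(1, 30))
            ]
            got = {
                (h.peptide, h.target_id, h.relation, h.start)
                for h in cross_reference(peptides, entries)
            }
            expected = set()
            for pep in {p for p in peptides}:
                for e in entries:
                    if pep == e.sequence:
                        expected.add((pep, e.entry_id, Relation.EXACT, 0))
                        continue
                    for i in range(len(e.sequence) - len(pep) + 1):
                        if e.sequence[i:i + len(pep)] == pep:
                            expected.add(
                                (pep, e.entry_id, Relation.PEPTIDE_IN_ENTRY, i)
                            )
                    for i in range(len(pep) - len(e.sequence) + 1):
                        if pep[i:i + len(e.sequence)] == e.sequence:
                            expected.add(
                                (pep, e.entry_id, Relation.ENTRY_IN_PEPTIDE, i)
                            )
            assert got == expected


class TestConsolidate:
    def build_sets(self, peptides):
        return {
            prod: PeptideSet(
                product_id=prod,
                peptides=set(peptides),
                per_peptide_batches={p: {"b1"} for p in peptides},
            )
            for prod in ("PHP", "P62")
        }

    def test_six_peptides_give_six_records_in_both_products(
        self, bioactive_entries, parent_proteins
    ):
        sets = self.build_sets(SIX_BAPS)
        hits = cross_reference(SIX_BAPS, bioactive_entries)
        for pep in {h.peptide for h in hits}:
            hits.extend(map_to_parents(pep, parent_proteins))
        records = consolidate(hits, bioactive_entries, parent_proteins, sets)
        assert len(records) == 6
        assert {r.peptide for r in records} == set(SIX_BAPS)
        for r in records:
            assert r.products == {"PHP", "P62"}
            assert r.evidence
            assert not r.flagged
        by_pep = {r.peptide: r for r in records}
        assert by_pep["DAVEDLESVGK"].parent_accession == "P81605"
        assert by_pep["TITLEVEPSDTIENVK"].parent_accession == "P0CG47"
        assert by_pep["VHVVPDQLMAF"].parent_accession == "P14174"
        assert by_pep["DAVEDLESVGK"].activity == "antimicrobial"
        assert by_pep["TNVPRASVPDGFLS"].activity == "cytokine/growth factor"

    def test_annotated_but_unobserved_peptide_flagged(
        self, bioactive_entries, parent_proteins
    ):
        hits = cross_reference(["DAVEDLESVGK"], bioactive_entries)
        records = consolidate(hits, bioactive_entries, parent_proteins, {})
        (r,) = records
        assert r.flagged and r.products == set()

    def test_parent_falls_back_to_entry_accession(self, bioactive_entries):
        hits = cross_reference(["DAVEDLESVGK"], bioactive_entries)
        (r,) = consolidate(hits, bioactive_entries, [], {})
        assert r.parent_accession == "P81605"

    def test_multifunctional_peptide_yields_one_record_per_activity(self):
        entries = [
            BioactiveEntry(entry_id="E1", sequence="AAAA", activity="antimicrobial"),
            BioactiveEntry(entry_id="E2", sequence="AAAA", activity="ACE-inhibitor"),
        ]
        hits = cross_reference(["AAAA"], entries)
        records = consolidate(hits, entries, [], {})
        assert sorted(r.activity for r in records) == ["ACE-inhibitor", "antimicrobial"]

    def test_no_hits_empty_output(self, bioactive_entries, parent_proteins):
        assert consolidate([], bioactive_entries, parent_proteins, {}) == []


def test_find_occurrences_overlapping():
    assert find_occurrences("AA", "AAAA") == [0, 1, 2]
    assert find_occurrences("AAAA", "AA") == []
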