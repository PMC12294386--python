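"""Format readers/writers: parsing, validation, round trips."""

from __future__ import annotations

import pytest

from hydropep import refio
from hydropep.refio import (
    BioactiveEntry,
    FormatError,
    Fraction,
    IdentRecord,
    ProteinRecord,
    SourceDB,
    ValidationError,
    clean_sequence,
)


class TestCleanSequence:
    def test_strips_modifications_and_uppercases(self):
        assert clean_sequence("M(+15.99)PMF") == "MPMF"
        assert clean_sequence("pep[+42]tide") == "PEPTIDE"

    @pytest.mark.parametrize("bad", ["", "()", "PEPB", "PEXP", "AB"])
    def test_rejects_non_canonical(self, bad):
        with pytest.raises(ValidationError):
            clean_sequence(bad)

    def test_error_names_position(self):
        with pytest.raises(ValidationError, match="position 2"):
            clean_sequence("PEBTIDE")


class TestFasta:
    def test_uniprot_header_parsed(self, tmp_path):
        f = tmp_path / "one.fasta"
        f.write_text(">sp|P14174|MIF_HUMAN Macrophage migration inhibitory factor\nmpmfivntnv\n")
        recs = refio.read_fasta(f)
        assert len(recs) == 1
        assert recs[0].accession == "P14174"
        assert recs[0].sequence == "MPMFIVNTNV"

    def test_plain_header_first_token(self, tmp_path):
        f = tmp_path / "one.fasta"
        f.write_text(">SYN0001 synthetic background\nACDEFGHIK\n")
        assert refio.read_fasta(f)[0].accession == "SYN0001"

    def test_empty_file_gives_empty_list(self, tmp_path):
        f = tmp_path / "empty.fasta"
        f.write_text("")
        assert refio.read_fasta(f) == []

    def test_non_canonical_residue_rejected(self, tmp_path):
        f = tmp_path / "bad.fasta"
        f.write_text(">x|Q00000|BAD entry\nPEPTIDEB\n")
        with pytest.raises(ValidationError):
            refio.read_fasta(f)

    def test_round_trip_preserves_sequences_and_accessions(self, tmp_path, parent_proteins):
        out = tmp_path / "rt.fasta"
        refio.write_fasta(parent_proteins, out)
        back = refio.read_fasta(out)
        assert [(r.accession, r.sequence) for r in back] == [
            (r.accession, r.sequence) for r in parent_proteins
        ]


class TestIdentTable:
    def test_basic_row(self, tmp_path):
        f = tmp_path / "idents.csv"
        f.write_text(
            "sequence,product,batch,fraction,fdr_pass\n"
            "TNVPRASVPDGFLS,PHP,20/0352,LT3K,true\n"
        )
        recs = refio.read_ident_table(f)
        (rec,) = recs
        assert rec.length == 14
        assert rec.product_id == "PHP"
        assert rec.fraction is Fraction.LT3K
        assert rec.fdr_pass is True

    def test_modification_annotations_stripped(self, tmp_path):
        f = tmp_path / "idents.csv"
        f.write_text("sequence\nM(+15.99)PMF\n")
        assert refio.read_ident_table(f)[0].sequence == "MPMF"

    def test_header_only_gives_empty_list(self, tmp_path):
        f = tmp_path / "idents.csv"
        f.write_text("sequence,product\n")
        assert refio.read_ident_table(f) == []

    def test_dialect_maps_columns(self, tmp_path):
        f = tmp_path / "peaks.csv"
        f.write_text("Peptide,Sample\nVHVVPDQLMAF,PHP\n")
        recs = refio.read_ident_table(
            f, dialect={"sequence": "Peptide", "product_id": "Sample"}
        )
        assert recs[0].sequence == "VHVVPDQLMAF"
        assert recs[0].product_id == "PHP"

    def test_missing_sequence_column_is_config_error(self, tmp_path):
        f = tmp_path / "idents.csv"
        f.write_text("pep,product\nAAAA,PHP\n")
        with pytest.raises(FormatError, match="sequence"):
            refio.read_ident_table(f)

    def test_bad_row_error_names_row(self, tmp_path):
        f = tmp_path / "idents.csv"
        f.write_text("sequence\nAAAA\nAAXB\n")
        with pytest.raises(FormatError, match="row 3"):
            refio.read_ident_table(f)

    def test_permissive_skips_bad_rows(self, tmp_path):
        f = tmp_path / "idents.csv"
        f.write_text("sequence\nAAAA\nAAXB\nPEPTIDE\n")
        recs = refio.read_ident_table(f, permissive=True)
        assert [r.sequence for r in recs] == ["AAAA", "PEPTIDE"]

    def test_semicolon_accessions_and_areas(self, tmp_path):
        f = tmp_path / "idents.tsv"
        f.write_text(
            "sequence\taccessions\tlight_area\theavy_area\n"
            "AAAA\tP14174;P81605\t100.5\t50.25\n"
        )
        rec = refio.read_ident_table(f)[0]
        assert rec.accessions == ("P14174", "P81605")
        assert rec.light_area == pytest.approx(100.5)
        assert rec.heavy_area == pytest.approx(50.25)


class TestBioactiveDb:
    def test_bundled_fixture_loads(self, bioactive_entries):
        by_id = {e.entry_id: e for e in bioactive_entries}
        assert by_id["BP0567"].activity == "antimicrobial"
        assert by_id["BP0567"].source_db is SourceDB.STRAPEP
        assert by_id["BP0567"].parent_accession == "P81605"
        assert by_id["satpdb12186"].source_db is SourceDB.APD2

    def test_duplicate_entry_id_rejected(self, tmp_path):
        f = tmp_path / "db.tsv"
        f.write_text(
            "entry_id\tsequence\tactivity\tsource_db\tparent_accession\n"
            "X1\tAAAA\tantimicrobial\tAPD2\t\n"
            "X1\tCCCC\tantimicrobial\tAPD2\t\n"
        )
        with pytest.raises(FormatError, match="duplicate"):
            refio.read_bioactive_db(f)

    def test_empty_activity_rejected(self):
        with pytest.raises(ValidationError):
            BioactiveEntry(entry_id="X", sequence="AAAA", activity="")


class TestMotifDb:
    def test_duplicate_motifs_collapsed_with_warning(self, tmp_path, caplog):
        f = tmp_path / "motifs.tsv"
        f.write_text("activity\tmotif\nACE-inhibitor\tGP\nACE-inhibitor\tGP\n")
        with caplog.at_level("WARNING"):
            sets = refio.read_motif_db(f)
        assert sets["ACE-inhibitor"].motifs == frozenset({"GP"})
        assert any("duplicate" in m for m in caplog.messages)

    def test_empty_motif_rejected(self, tmp_path):
        f = tmp_path / "motifs.tsv"
        f.write_text("activity\tmotif\nACE-inhibitor\t\n")
        with pytest.raises(FormatError, match="empty motif"):
            refio.read_motif_db(f)

    def test_snapshot_id_read_from_comment(self, motif_sets):
        assert all(
            s.snapshot_id == "hydropep-motifs-synthetic-v1"
            for s in motif_sets.values()
        )


class TestQuantReport:
    def test_round_trips_fields(self, tmp_path):
        f = tmp_path / "report.csv"
        f.write_text(
            "peptide,product,batch,light_area,heavy_area,H_pmol\n"
            "DAVEDLESVGK,PHP,20/0352,1000,2000,0.55\n"
        )
        (q,) = refio.read_quant_report(f)
        assert q.peptide == "DAVEDLESVGK"
        assert q.H == pytest.approx(0.55)
        assert q.heavy_area == pytest.approx(2000)

    def test_missing_columns_rejected(self, tmp_path):
        f = tmp_path / "report.csv"
        f.write_text("peptide,light_area\nAAAA,1\n")
        with pytest.raises(FormatError, match="missing columns"):
            refio.read_quant_report(f)


def test_protein_record_validates_on_construction():
    with pytest.raises(ValidationError):
        ProteinRecord(accession="X", name="bad", sequence="AAZB")
    rec = ProteinRecord(accession="X", name="ok", sequence="aaaa")
    assert rec.sequence == "AAAA"


def test_ident_record_length_matches_sequence():
    rec = IdentRecord(sequence="PEPTIDE")
    assert rec.length == len(rec.sequence) == 7
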