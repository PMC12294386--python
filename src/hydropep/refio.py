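"""Readers and writers for the external formats the pipeline touches.

All downstream stages operate on the plain-text record types defined here:
parent proteins (FASTA), peptide identification exports (CSV/TSV), bioactive
reference entries (TSV), activity-motif tables (TSV) and light/heavy
quantification reports (CSV).  Sequences are uppercased on load, search-engine
modification annotations are stripped, and every record is validated against
the 20-letter canonical amino-acid alphabet; a loader either returns valid
records or raises.

Coordinates anywhere in this package are 0-based, half-open.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

_MOD_RE = re.compile(r"\([^)]*\)|\[[^\]]*\]")


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class ValidationError(ValueError):
    """A parsed record violates a type invariant."""


def clean_sequence(raw: str, *, context: str = "") -> str:
    """Uppercase ``raw``, strip modification annotations in ()/[], validate.

    Raises :class:`ValidationError` naming the offending position if a
    non-canonical residue remains.
    """
    seq = _MOD_RE.sub("", raw).replace(" ", "").replace(".", "").upper()
    if not seq:
        raise ValidationError(f"empty sequence{' in ' + context if context else ''}")
    for i, ch in enumerate(seq):
        if ch not in CANONICAL_AA:
            raise ValidationError(
                f"non-canonical residue {ch!r} at position {i}"
                f"{' in ' + context if context else ''}"
            )
    return seq


class Fraction(enum.Enum):
    """Molecular-weight fraction a peptide observation came from."""

    LT3K = "lt3k"
    K3TO10 = "3to10k"
    GT10K = "gt10k"

    @classmethod
    def parse(cls, label: str) -> "Fraction":
        norm = label.strip().lower().replace("-", "").replace("_", "")
        for f in cls:
            if norm in (f.value, f.name.lower()):
                return f
        raise ValidationError(f"unknown fraction label {label!r}")


class SourceDB(enum.Enum):
    APD2 = "APD2"
    STRAPEP = "StraPep"
    AHTPDB = "AHTPDB"
    BIOPEP = "BIOPEP"
    OTHER = "OTHER"

    @classmethod
    def parse(cls, label: str) -> "SourceDB":
        norm = label.strip().lower()
        for s in cls:
            if norm == s.value.lower():
                return s
        return cls.OTHER


@dataclass(frozen=True)
class ProteinRecord:
    """A parent protein: UniProt-style accession, name, canonical sequence."""

    accession: str
    name: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", clean_sequence(self.sequence, context=self.accession)
        )


@dataclass
class IdentRecord:
    """One identified-peptide observation from a search-engine export."""

    sequence: str
    product_id: str = ""
    batch_id: str = ""
    fraction: Fraction | None = None
    fdr_pass: bool = True
    accessions: tuple[str, ...] = ()
    light_area: float | None = None
    heavy_area: float | None = None

    def __post_init__(self) -> None:
        self.sequence = clean_sequence(self.sequence, context="identification record")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BioactiveEntry:
    """A reference bioactive peptide from a public database snapshot."""

    entry_id: str
    sequence: str
    activity: str
    source_db: SourceDB = SourceDB.OTHER
    parent_accession: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", clean_sequence(self.sequence, context=self.entry_id)
        )
        if not self.activity:
            raise ValidationError(f"entry {self.entry_id}: empty activity")


@dataclass(frozen=True)
class MotifSet:
    """Activity-specific short bioactive fragments (a BIOPEP-style list)."""

    activity: str
    motifs: frozenset[str]
    snapshot_id: str = ""

    def __post_init__(self) -> None:
        if any(not m for m in self.motifs):
            raise ValidationError(f"{self.activity}: empty motif")


# ---------------------------------------------------------------------------
# FASTA

def _parse_fasta_header(rec: SeqRecord) -> tuple[str, str]:
    """Accession from a UniProt ``db|ACC|ID`` header, else the first token."""
    token = rec.id
    if "|" in token:
        parts = token.split("|")
        acc = parts[1] if len(parts) >= 2 and parts[1] else parts[0]
    else:
        acc = token
    name = rec.description.partition(" ")[2].strip() or rec.id
    return acc, name


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Load parent proteins from FASTA; sequences validated and uppercased."""
    path = Path(path)
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for rec in parsed:
        acc, name = _parse_fasta_header(rec)
        records.append(ProteinRecord(accession=acc, name=name,
                                     sequence=str(rec.seq), source=str(path)))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.name)
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Identification tables

#: canonical column -> default column name in the export
DEFAULT_DIALECT: Mapping[str, str] = {
    "sequence": "sequence",
    "product_id": "product",
    "batch_id": "batch",
    "fraction": "fraction",
    "fdr_pass": "fdr_pass",
    "accessions": "accessions",
    "light_area": "light_area",
    "heavy_area": "heavy_area",
}

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"unparseable boolean {value!r}")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_ident_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    permissive: bool = False,
) -> list[IdentRecord]:
    """Load a peptide identification export (CSV or TSV).

    ``dialect`` maps canonical field names (keys of :data:`DEFAULT_DIALECT`)
    to the column names actually present in the export; search engines do not
    share a common export schema, so the mapping is explicit configuration.
    Only ``sequence`` is required.  With ``permissive=True`` rows that fail
    validation are logged and skipped instead of aborting the load.
    """
    path = Path(path)
    cols = dict(DEFAULT_DIALECT)
    cols.update(dialect or {})
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, comment="#")
    if cols["sequence"] not in df.columns:
        raise FormatError(
            f"{path}: no sequence column {cols['sequence']!r}; "
            f"columns present: {list(df.columns)}"
        )
    records: list[IdentRecord] = []
    for idx, row in df.iterrows():
        def get(key: str) -> str | None:
            col = cols[key]
            if col not in df.columns:
                return None
            val = row[col]
            return None if pd.isna(val) else str(val)

        try:
            rec = IdentRecord(
                sequence=get("sequence") or "",
                product_id=get("product_id") or "",
                batch_id=get("batch_id") or "",
                fraction=Fraction.parse(get("fraction")) if get("fraction") else None,
                fdr_pass=_parse_bool(get("fdr_pass")) if get("fdr_pass") is not None else True,
                accessions=tuple(
                    a for a in (get("accessions") or "").split(";") if a
                ),
                light_area=float(get("light_area")) if get("light_area") else None,
                heavy_area=float(get("heavy_area")) if get("heavy_area") else None,
            )
        except (ValidationError, ValueError) as exc:
            if permissive:
                logger.warning("%s row %d skipped: %s", path, idx + 2, exc)
                continue
            raise FormatError(f"{path} row {idx + 2}: {exc}") from exc
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Bioactive entries and motif tables

def read_bioactive_db(path: str | Path) -> list[BioactiveEntry]:
    """Load a bioactive-peptide reference TSV; duplicate entry_ids rejected."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"entry_id", "sequence", "activity"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    entries: list[BioactiveEntry] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        eid = str(row["entry_id"]).strip()
        if eid in seen:
            raise FormatError(f"{path} row {idx + 2}: duplicate entry_id {eid!r}")
        seen.add(eid)
        parent = row.get("parent_accession")
        entries.append(
            BioactiveEntry(
                entry_id=eid,
                sequence=str(row["sequence"]),
                activity=str(row["activity"]).strip(),
                source_db=SourceDB.parse(str(row.get("source_db", "OTHER"))),
                parent_accession=None if pd.isna(parent) else str(parent).strip(),
            )
        )
    return entries


def read_motif_db(path: str | Path) -> dict[str, MotifSet]:
    """Load an activity-motif TSV (columns ``activity`` and ``motif``).

    Returns one :class:`MotifSet` per activity.  Duplicate motifs within an
    activity are collapsed with a warning; an empty motif cell is an error.
    A ``# snapshot_id: <tag>`` comment line, if present, is carried onto the
    returned sets for provenance.
    """
    path = Path(path)
    snapshot_id = path.stem
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                m = re.match(r"#\s*snapshot_id\s*:\s*(\S+)", line)
                if m:
                    snapshot_id = m.group(1)
            else:
                break
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if not {"activity", "motif"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns 'activity' and 'motif'")
    by_activity: dict[str, list[str]] = {}
    for idx, row in df.iterrows():
        if pd.isna(row["motif"]) or not str(row["motif"]).strip():
            raise FormatError(f"{path} row {idx + 2}: empty motif")
        motif = clean_sequence(str(row["motif"]), context=f"{path} row {idx + 2}")
        by_activity.setdefault(str(row["activity"]).strip(), []).append(motif)
    sets: dict[str, MotifSet] = {}
    for activity, motifs in by_activity.items():
        unique = frozenset(motifs)
        if len(unique) < len(motifs):
            logger.warning(
                "%s: %d duplicate motif rows collapsed for activity %r",
                path, len(motifs) - len(unique), activity,
            )
        sets[activity] = MotifSet(activity=activity, motifs=unique,
                                  snapshot_id=snapshot_id)
    return sets


# ---------------------------------------------------------------------------
# Quantification reports (imported lazily to avoid a refio<->quant cycle)

def read_quant_report(path: str | Path) -> "list":
    """Load a Skyline-style light/heavy report CSV into QuantInput records.

    Expected columns: ``peptide, product, batch, light_area, heavy_area,
    H_pmol`` and optional ``total_peptide_ug``.
    """
    from .quant import QuantInput

    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    required = {"peptide", "light_area", "heavy_area", "H_pmol"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                QuantInput(
                    peptide=clean_sequence(str(row["peptide"])),
                    H=float(row["H_pmol"]),
                    light_area=float(row["light_area"]),
                    heavy_area=float(row["heavy_area"]),
                    total_peptide_ug=float(row.get("total_peptide_ug", 10.0)),
                    product_id=str(row.get("product", "")),
                    batch_id=str(row.get("batch", "")),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise FormatError(f"{path} row {idx + 2}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Bundled reference fixtures

def _data_path(name: str) -> Path:
    return Path(resources.files("hydropep").joinpath("data", name))  # type: ignore[arg-type]


def bundled_motifs() -> dict[str, MotifSet]:
    """The pinned ACE-/DPP-IV-inhibitor motif snapshot shipped with the package."""
    return read_motif_db(_data_path("motifs_synthetic.tsv"))


def bundled_bioactive_entries() -> list[BioactiveEntry]:
    """Synthetic reference entries emulating StraPep/APD2 records."""
    return read_bioactive_db(_data_path("bioactive_entries_synthetic.tsv"))


def bundled_parent_proteins() -> list[ProteinRecord]:
    """Synthetic fixture sequences for the MIF, dermcidin and ubiquitin parents."""
    return read_fasta(_data_path("parents_synthetic.fasta"))
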