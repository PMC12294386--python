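"""End-to-end orchestration: ingest -> annotate -> BF -> quant -> predict.

The pipeline mirrors a hydrolysate peptidomics workflow: identification
exports are filtered and pooled per product, peptides are mapped to parent
proteins and cross-referenced against bioactive reference entries, the
consolidated bioactive peptides are scored for motif frequency and absolutely
quantified from light/heavy reports, and (optionally) all identified peptides
are scored by the activity classifiers.  Every report is tab-separated UTF-8
with a ``#``-comment provenance header naming the inputs, seeds and the motif
snapshot used, so runs are diff-able and auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from . import activity_ml, annotate, bfscore, ingest, quant, refio

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """Paths, toggles and parameters for one pipeline run."""

    out_dir: Path
    ident_tables: Sequence[Path] = ()
    dialect: Mapping[str, str] | None = None
    parents_fasta: Path | None = None  # bundled fixture when None
    bioactive_db: Path | None = None
    motif_db: Path | None = None
    quant_report: Path | None = None
    labeled_peptides: Path | None = None
    activities: Sequence[str] = ("ACE-inhibitor", "DPP-IV-inhibitor")
    min_len: int = ingest.DEFAULT_MIN_LEN
    max_len: int = ingest.DEFAULT_MAX_LEN
    min_batches: int = 1
    total_peptide_ug: float = quant.DEFAULT_TOTAL_PEPTIDE_UG
    seed: int = 0
    run_ingest: bool = True
    run_annotate: bool = True
    run_bf: bool = True
    run_quant: bool = True
    run_ml: bool = False

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        base = Path(path).parent

        def _p(key):
            return (base / raw[key]) if raw.get(key) else None

        cfg = cls(
            out_dir=base / raw.get("out_dir", "hydropep_out"),
            ident_tables=tuple(base / p for p in raw.get("ident_tables", [])),
            dialect=raw.get("dialect"),
            parents_fasta=_p("parents_fasta"),
            bioactive_db=_p("bioactive_db"),
            motif_db=_p("motif_db"),
            quant_report=_p("quant_report"),
            labeled_peptides=_p("labeled_peptides"),
            activities=tuple(raw.get("activities",
                                     ("ACE-inhibitor", "DPP-IV-inhibitor"))),
            min_len=int(raw.get("min_len", ingest.DEFAULT_MIN_LEN)),
            max_len=int(raw.get("max_len", ingest.DEFAULT_MAX_LEN)),
            min_batches=int(raw.get("min_batches", 1)),
            total_peptide_ug=float(
                raw.get("total_peptide_ug", quant.DEFAULT_TOTAL_PEPTIDE_UG)
            ),
            seed=int(raw.get("seed", 0)),
            run_ingest=bool(raw.get("run_ingest", True)),
            run_annotate=bool(raw.get("run_annotate", True)),
            run_bf=bool(raw.get("run_bf", True)),
            run_quant=bool(raw.get("run_quant", True)),
            run_ml=bool(raw.get("run_ml", False)),
        )
        return cfg

    def validate(self) -> None:
        if not (self.run_ingest or self.run_annotate or self.run_bf
                or self.run_quant or self.run_ml):
            raise ingest.ConfigError("all pipeline stages are disabled")
        for p in [*self.ident_tables, self.parents_fasta, self.bioactive_db,
                  self.motif_db, self.quant_report, self.labeled_peptides]:
            if p is not None and not Path(p).exists():
                raise ingest.ConfigError(f"input file not found: {p}")


def _header(cfg: RunConfig, extra: Mapping[str, str] | None = None) -> str:
    lines = [f"# hydropep {__version__}", f"# seed: {cfg.seed}"]
    for key, val in (extra or {}).items():
        lines.append(f"# {key}: {val}")
    return "\n".join(lines) + "\n"


def _write_tsv(path: Path, header: str, columns: Sequence[str],
               rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the toggled stages; returns the in-memory result bundle."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    log_lines = [f"hydropep {__version__}", f"seed={cfg.seed}"]

    def stage(name):
        def deco(fn):
            try:
                fn()
                log_lines.append(f"stage {name}: ok")
            except Exception as exc:
                log_lines.append(f"stage {name}: FAILED: {exc}")
                (out / "run.log").write_text("\n".join(log_lines) + "\n")
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return deco

    proteins = (refio.read_fasta(cfg.parents_fasta) if cfg.parents_fasta
                else refio.bundled_parent_proteins())
    entries = (refio.read_bioactive_db(cfg.bioactive_db) if cfg.bioactive_db
               else refio.bundled_bioactive_entries())
    motif_sets = (refio.read_motif_db(cfg.motif_db) if cfg.motif_db
                  else refio.bundled_motifs())
    snapshot_id = next(iter(motif_sets.values())).snapshot_id if motif_sets else "none"

    if cfg.run_ingest:
        @stage("ingest")
        def _ingest():
            records: list[refio.IdentRecord] = []
            for path in cfg.ident_tables:
                records.extend(refio.read_ident_table(path, cfg.dialect))
            kept = ingest.filter_idents(records, cfg.min_len, cfg.max_len)
            bundle["peptide_sets"] = ingest.build_peptide_sets(
                kept, cfg.min_batches
            )
            rows = [
                (pid, pep, ";".join(sorted(pset.per_peptide_batches[pep])))
                for pid, pset in sorted(bundle["peptide_sets"].items())
                for pep in sorted(pset.peptides)
            ]
            _write_tsv(out / "peptides.tsv",
                       _header(cfg, {"inputs": ",".join(map(str, cfg.ident_tables))}),
                       ("product", "peptide", "batches"), rows)

    peptide_sets = bundle.get("peptide_sets", {})
    all_peptides = sorted({p for s in peptide_sets.values() for p in s.peptides})

    if cfg.run_annotate:
        @stage("annotate")
        def _annotate():
            hits = annotate.cross_reference(all_peptides, entries)
            for pep in {h.peptide for h in hits}:
                hits.extend(annotate.map_to_parents(pep, proteins))
            bundle["bap_records"] = annotate.consolidate(
                hits, entries, proteins, peptide_sets
            )

    if cfg.run_quant and cfg.quant_report:
        @stage("quant")
        def _quant():
            inputs = refio.read_quant_report(cfg.quant_report)
            results = [quant.quantify(q) for q in inputs]
            bundle["amounts"] = quant.average_over_batches(results)
            rows = [
                (pep, prod, f"{mean:.4f}", n)
                for (pep, prod), (mean, n) in sorted(bundle["amounts"].items())
            ]
            _write_tsv(out / "amounts.tsv",
                       _header(cfg, {"quant_report": str(cfg.quant_report),
                                     "total_peptide_ug": cfg.total_peptide_ug}),
                       ("peptide", "product", "mean_pg_per_ug", "n_batches"),
                       rows)

    if cfg.run_annotate:
        @stage("bap_table")
        def _bap_table():
            amounts = bundle.get("amounts", {})
            products = sorted(peptide_sets)
            columns = ["peptide", "activity", "parent", "products"] + [
                f"amount_{p}_pg_per_ug" for p in products
            ]
            rows = []
            for rec in sorted(bundle["bap_records"],
                              key=lambda r: (r.peptide, r.activity)):
                row = [rec.peptide, rec.activity, rec.parent_accession,
                       ";".join(sorted(rec.products))]
                for prod in products:
                    mean = amounts.get((rec.peptide, prod))
                    row.append(f"{mean[0]:.4f}" if mean else "NA")
                rows.append(row)
            _write_tsv(out / "bap_table.tsv",
                       _header(cfg, {"bioactive_db": cfg.bioactive_db or "bundled",
                                     "parents": cfg.parents_fasta or "bundled"}),
                       columns, rows)

    if cfg.run_bf:
        @stage("bf")
        def _bf():
            targets = ([r.peptide for r in bundle.get("bap_records", [])]
                       or all_peptides)
            targets = sorted(set(targets))
            chosen = {a: motif_sets[a] for a in cfg.activities if a in motif_sets}
            missing = [a for a in cfg.activities if a not in motif_sets]
            if missing:
                raise ingest.ConfigError(
                    f"activities absent from motif snapshot: {missing}"
                )
            results = bfscore.score_peptides(targets, chosen)
            bundle["bf_results"] = results
            rows = [
                (r.peptide, r.activity, r.a, r.N,
                 f"{r.bf_rounded:.4f}", r.band.value)
                for r in results
            ]
            _write_tsv(out / "bf.tsv",
                       _header(cfg, {"snapshot_id": snapshot_id}),
                       ("peptide", "activity", "a", "N", "bf", "band"), rows)

    if cfg.run_ml:
        @stage("ml")
        def _ml():
            if not cfg.labeled_peptides:
                raise ingest.ConfigError("run_ml requires labeled_peptides")
            import pandas as pd

            df = pd.read_csv(cfg.labeled_peptides, sep="\t")
            data = [
                activity_ml.LabeledPeptide(
                    str(r["sequence"]),
                    activity_ml.ActivityClass.parse(str(r["activity_class"])),
                    str(r["label"]).strip().lower() in ("true", "1", "yes"),
                )
                for _, r in df.iterrows()
            ]
            rows = []
            for cls in activity_ml.ActivityClass:
                model, metrics = activity_ml.train(data, cls, seed=cfg.seed)
                preds, errors = activity_ml.predict(model, all_peptides)
                for pep, prob, call in preds:
                    rows.append((pep, cls.value, f"{prob:.4f}", call))
                for pep, reason in errors:
                    logger.warning("predict %s on %r failed: %s",
                                   cls.value, pep, reason)
                log_lines.append(
                    f"ml {cls.value}: accuracy={metrics.accuracy:.3f} "
                    f"sensitivity={metrics.sensitivity:.3f} "
                    f"specificity={metrics.specificity:.3f}"
                )
            bundle["predictions"] = rows
            _write_tsv(out / "predictions.tsv",
                       _header(cfg, {"labeled_peptides": cfg.labeled_peptides}),
                       ("peptide", "activity_class", "probability", "call"),
                       rows)

    log_lines.append(f"snapshot_id={snapshot_id}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    bundle["out_dir"] = out
    return bundle
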