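"""Synthetic peptidomics data with a ground-truth ledger.

Every input the pipeline consumes can be generated here: a background
proteome, per-product/per-batch identification tables from simulated
enzymatic hydrolysis, light/heavy quantification reports with known true
amounts, and labelled peptide sets for the activity classifiers.  The
defaults emulate the hydrolysate study design this package was built around:
two products ("PHP", "P62") of three batches each, peptides of 4-65 residues
from unspecific cleavage, six planted bioactive peptides present in both
products with their published per-product amounts and heavy-spike levels
(0.34-1.2 pmol), and multiplicative lognormal area noise.

All generators are pure functions of the configuration (every random draw
derives from ``cfg.seed``), and each returns or records its ground truth so
round-trip tests can compare recovered values against planted ones.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .activity_ml import ActivityClass, LabeledPeptide
from .quant import QuantInput, peptide_mass
from .refio import ProteinRecord, bundled_parent_proteins
from .ingest import ConfigError
from .refio import Fraction, IdentRecord

#: Swiss-Prot-wide amino-acid background frequencies (release-level averages,
#: renormalised to sum exactly to 1).
_AA_BACKGROUND_RAW: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}
_RAW_TOTAL = sum(_AA_BACKGROUND_RAW.values())
AA_BACKGROUND: dict[str, float] = {
    aa: f / _RAW_TOTAL for aa, f in _AA_BACKGROUND_RAW.items()
}

KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: the six planted bioactive peptides: (sequence, activity, parent accession)
PLANTED_BAPS: tuple[tuple[str, str, str], ...] = (
    ("TNVPRASVPDGFLS", "cytokine/growth factor", "P14174"),
    ("TNVPRASVPDGFLSEL", "cytokine/growth factor", "P14174"),
    ("VHVVPDQLMAF", "cytokine/growth factor", "P14174"),
    ("DAVEDLESVGK", "antimicrobial", "P81605"),
    ("EGIPPDQQRLIFAGK", "antimicrobial", "P0CG47"),
    ("TITLEVEPSDTIENVK", "antimicrobial", "P0CG47"),
)

#: true planted amounts, pg peptide per ug total peptide, per product
TRUE_AMOUNTS_PG_PER_UG: dict[tuple[str, str], float] = {
    ("TNVPRASVPDGFLS", "PHP"): 1.4596, ("TNVPRASVPDGFLS", "P62"): 0.1898,
    ("TNVPRASVPDGFLSEL", "PHP"): 8.0500, ("TNVPRASVPDGFLSEL", "P62"): 0.9224,
    ("VHVVPDQLMAF", "PHP"): 0.0310, ("VHVVPDQLMAF", "P62"): 0.0054,
    ("DAVEDLESVGK", "PHP"): 0.1626, ("DAVEDLESVGK", "P62"): 0.1939,
    ("EGIPPDQQRLIFAGK", "PHP"): 0.2637, ("EGIPPDQQRLIFAGK", "P62"): 0.1852,
    ("TITLEVEPSDTIENVK", "PHP"): 0.3594, ("TITLEVEPSDTIENVK", "P62"): 0.4327,
}

#: heavy spike per target peptide, pmol on column
HEAVY_SPIKE_PMOL: dict[str, float] = {
    "TNVPRASVPDGFLS": 0.73,
    "TNVPRASVPDGFLSEL": 1.20,
    "DAVEDLESVGK": 0.55,
    "EGIPPDQQRLIFAGK": 0.34,
    "TITLEVEPSDTIENVK": 0.47,
    "VHVVPDQLMAF": 0.50,
}

DEFAULT_BATCHES: dict[str, tuple[str, ...]] = {
    "PHP": ("20/0352", "20/0360", "20/0361"),
    "P62": ("19/0044", "20/0006", "20/0010"),
}


class CleavageMode(enum.Enum):
    UNSPECIFIC = "unspecific"
    LYSC = "lysc"
    TRYPSIN = "trypsin"


@dataclass
class SynthConfig:
    """Study-design parameters for every generator; ``seed`` is mandatory."""

    seed: int
    n_proteins: int = 20
    protein_length_range: tuple[int, int] = (80, 300)
    cleavage_mode: CleavageMode = CleavageMode.UNSPECIFIC
    peptide_length_range: tuple[int, int] = (4, 65)
    n_batches: int = 3
    batch_ids: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BATCHES)
    )
    planted_baps: tuple[tuple[str, str, str], ...] = PLANTED_BAPS
    true_amounts_pg_per_ug: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(TRUE_AMOUNTS_PG_PER_UG)
    )
    heavy_pmol: Mapping[str, float] = field(
        default_factory=lambda: dict(HEAVY_SPIKE_PMOL)
    )
    noise_cv: float = 0.1
    total_peptide_ug: float = 10.0
    peptides_per_protein: int = 25
    batch_presence_prob: float = 0.7
    missed_cleavages: int = 0
    ml_effect: float = 3.0
    n_labeled_per_class: int = 400

    def __post_init__(self) -> None:
        lo, hi = self.peptide_length_range
        if lo < 1 or lo > hi:
            raise ConfigError(f"bad peptide_length_range {self.peptide_length_range}")
        lo, hi = self.protein_length_range
        if lo < 1 or lo > hi:
            raise ConfigError(f"bad protein_length_range {self.protein_length_range}")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        total = sum(AA_BACKGROUND.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"background frequencies sum to {total}, not 1")

    @property
    def products(self) -> tuple[str, ...]:
        return tuple(self.batch_ids)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream per generator."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class SynthTruth:
    """Ground-truth ledger for one generated dataset."""

    per_batch_peptides: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    planted: dict[str, dict] = field(default_factory=dict)
    quant: dict[str, dict] = field(default_factory=dict)  # "pep|prod|batch" -> truth
    labels: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, set):
                return sorted(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=default, indent=1)


_AAS = tuple(AA_BACKGROUND)
_BG_P = np.array([AA_BACKGROUND[a] for a in _AAS])
_BG_P = _BG_P / _BG_P.sum()


def _random_sequence(rng: np.random.Generator, length: int,
                     p: np.ndarray = _BG_P) -> str:
    return "".join(rng.choice(_AAS, size=length, p=p))


def gen_proteome(cfg: SynthConfig, include_planted_parents: bool = True
                 ) -> list[ProteinRecord]:
    """Random background proteins, plus the fixture parent proteins verbatim.

    The appended parents guarantee that planted peptides map somewhere.
    """
    rng = cfg.rng(1)
    lo, hi = cfg.protein_length_range
    records = [
        ProteinRecord(
            accession=f"SYN{i:04d}",
            name=f"synthetic background protein {i}",
            sequence=_random_sequence(rng, int(rng.integers(lo, hi + 1))),
            source="synthdata",
        )
        for i in range(cfg.n_proteins)
    ]
    if include_planted_parents:
        records.extend(bundled_parent_proteins())
    return records


def cleavage_fragments(sequence: str, mode: CleavageMode,
                       missed_cleavages: int = 0) -> list[str]:
    """Enzymatic fragments before any length filtering.

    LYSC cuts after K; TRYPSIN after K or R except before P.
    """
    if mode is CleavageMode.UNSPECIFIC:
        raise ConfigError("unspecific digestion has no deterministic fragment list")
    cuts = []
    for i, aa in enumerate(sequence[:-1]):
        if mode is CleavageMode.LYSC and aa == "K":
            cuts.append(i + 1)
        elif mode is CleavageMode.TRYPSIN and aa in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    bounds = [0] + cuts + [len(sequence)]
    frags = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(bounds))):
            frags.append(sequence[bounds[i]:bounds[j]])
    return frags


def simulate_hydrolysis(
    protein: "ProteinRecord | str",
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Peptides released from one protein under the configured cleavage mode.

    Unspecific digestion draws ``cfg.peptides_per_protein`` random substrings
    with lengths uniform over the configured range; enzymatic modes apply
    their cleavage rule.  All emitted peptides respect the length bounds.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    lo, hi = cfg.peptide_length_range
    if lo > len(seq):
        raise ConfigError(
            f"minimum peptide length {lo} exceeds protein length {len(seq)}"
        )
    if cfg.cleavage_mode is CleavageMode.UNSPECIFIC:
        if rng is None:
            rng = cfg.rng(2)
        out = []
        for _ in range(cfg.peptides_per_protein):
            length = int(rng.integers(lo, min(hi, len(seq)) + 1))
            start = int(rng.integers(0, len(seq) - length + 1))
            out.append(seq[start:start + length])
        return out
    frags = cleavage_fragments(seq, cfg.cleavage_mode, cfg.missed_cleavages)
    return [f for f in frags if lo <= len(f) <= hi]


def _fraction_for_mass(mass_da: float) -> Fraction:
    if mass_da < 3000:
        return Fraction.LT3K
    if mass_da <= 10000:
        return Fraction.K3TO10
    return Fraction.GT10K


def gen_ident_records(
    cfg: SynthConfig, proteome: list[ProteinRecord] | None = None
) -> tuple[list[IdentRecord], SynthTruth]:
    """Per-product, per-batch identification tables with planted bioactives.

    Background peptides come from simulated hydrolysis of the proteome and are
    present in each batch with probability ``cfg.batch_presence_prob``; each
    planted peptide is guaranteed present in every batch of every product.  A
    small number of deliberately failing rows (too short, too long, FDR fail)
    is included so acceptance filtering has something to reject.
    """
    if proteome is None:
        proteome = gen_proteome(cfg)
    rng = cfg.rng(3)
    # background peptides come from background proteins only: the planted
    # parents stay in the proteome for mapping, but their peptide content is
    # controlled exclusively by cfg.planted_baps so the truth ledger is exact
    planted_parents = {parent for _, _, parent in cfg.planted_baps}
    pool: list[str] = []
    for prot in proteome:
        if prot.accession in planted_parents:
            continue
        pool.extend(simulate_hydrolysis(prot, cfg, rng=rng))
    pool = sorted(set(pool))
    truth = SynthTruth()
    for seq, activity, parent in cfg.planted_baps:
        truth.planted[seq] = {"activity": activity, "parent": parent,
                              "products": sorted(cfg.products)}
    records: list[IdentRecord] = []
    for product in cfg.products:
        batches = cfg.batch_ids[product][: cfg.n_batches]
        truth.per_batch_peptides[product] = {}
        # each product sees its own random subset of the shared pool
        product_pool = [p for p in pool if rng.random() < 0.75]
        for batch in batches:
            present = {p for p in product_pool
                       if rng.random() < cfg.batch_presence_prob}
            present.update(seq for seq, _, _ in cfg.planted_baps)
            truth.per_batch_peptides[product][batch] = set(present)
            for pep in sorted(present):
                records.append(
                    IdentRecord(
                        sequence=pep,
                        product_id=product,
                        batch_id=batch,
                        fraction=_fraction_for_mass(peptide_mass(pep)),
                        fdr_pass=True,
                    )
                )
            # rejects: an FDR failure and a too-short fragment per batch
            records.append(
                IdentRecord(
                    sequence=_random_sequence(rng, int(rng.integers(6, 20))),
                    product_id=product, batch_id=batch,
                    fraction=Fraction.LT3K, fdr_pass=False,
                )
            )
            records.append(
                IdentRecord(
                    sequence=_random_sequence(rng, 3),
                    product_id=product, batch_id=batch,
                    fraction=Fraction.LT3K, fdr_pass=True,
                )
            )
    return records, truth


def gen_quant_report(
    cfg: SynthConfig, truth: SynthTruth | None = None
) -> tuple[list[QuantInput], SynthTruth]:
    """Light/heavy area pairs for the planted peptides with known amounts.

    The true endogenous amount L (pmol) is back-computed from the planted
    pg/ug amount; the light area is the heavy area scaled by L/H times a
    mean-one lognormal noise factor with coefficient of variation
    ``cfg.noise_cv`` (zero noise gives exact ratios).
    """
    if truth is None:
        truth = SynthTruth()
    rng = cfg.rng(4)
    sigma = float(np.sqrt(np.log1p(cfg.noise_cv ** 2)))
    inputs: list[QuantInput] = []
    for seq, _activity, _parent in cfg.planted_baps:
        H = cfg.heavy_pmol[seq]
        mass = peptide_mass(seq)
        for product in cfg.products:
            amount = cfg.true_amounts_pg_per_ug[(seq, product)]
            L_true = amount * cfg.total_peptide_ug / mass
            for batch in cfg.batch_ids[product][: cfg.n_batches]:
                heavy_area = float(rng.lognormal(np.log(1e6), 0.3))
                noise = (
                    float(rng.lognormal(-0.5 * sigma ** 2, sigma))
                    if cfg.noise_cv > 0 else 1.0
                )
                light_area = heavy_area * (L_true / H) * noise
                inputs.append(
                    QuantInput(
                        peptide=seq, H=H,
                        light_area=light_area, heavy_area=heavy_area,
                        total_peptide_ug=cfg.total_peptide_ug,
                        product_id=product, batch_id=batch,
                    )
                )
                truth.quant[f"{seq}|{product}|{batch}"] = {
                    "L_true_pmol": L_true,
                    "amount_pg_per_ug": amount,
                    "noise": noise,
                }
    return inputs, truth


#: per-class log-weight tilts applied to positive sequences, scaled by ml_effect
_CLASS_TILTS: dict[ActivityClass, dict[str, float]] = {
    ActivityClass.ANTIMICROBIAL: {"K": 1.0, "R": 1.0},
    ActivityClass.ANTIVIRAL: {"R": 0.8, "W": 0.8, "F": 0.6},
    ActivityClass.ANTIOXIDANT: {"W": 1.0, "Y": 1.0, "C": 0.8, "H": 0.8, "M": 0.8},
}
#: hydropathy share of the tilt (normalised Kyte-Doolittle), per class
_KD_TILT: dict[ActivityClass, float] = {
    ActivityClass.ANTIMICROBIAL: 0.3,
    ActivityClass.ANTIVIRAL: 0.2,
    ActivityClass.ANTIOXIDANT: 0.0,
}


def _positive_freqs(cls: ActivityClass, ml_effect: float) -> np.ndarray:
    kd = np.array([KYTE_DOOLITTLE[a] / 4.5 for a in _AAS])
    tilt = np.array([_CLASS_TILTS[cls].get(a, 0.0) for a in _AAS])
    w = _BG_P * np.exp(ml_effect * (tilt + _KD_TILT[cls] * kd))
    return w / w.sum()


def gen_labeled_sets(cfg: SynthConfig) -> tuple[list[LabeledPeptide], SynthTruth]:
    """Class-balanced labelled peptides for the three activity classifiers.

    Positives are drawn from a composition tilted towards class-typical
    residues (cationic for antimicrobial, aromatic/cationic for antiviral,
    radical-scavenging for antioxidant) with strength ``cfg.ml_effect``;
    negatives come from the plain background.  ``ml_effect=0`` removes the
    signal entirely, making classifier performance collapse to chance.
    """
    rng = cfg.rng(5)
    out: list[LabeledPeptide] = []
    truth = SynthTruth()
    n_per_label = cfg.n_labeled_per_class // 2
    for cls in ActivityClass:
        pos_p = _positive_freqs(cls, cfg.ml_effect)
        for label, p in ((True, pos_p), (False, _BG_P)):
            for _ in range(n_per_label):
                length = int(rng.integers(10, 41))
                seq = _random_sequence(rng, length, p)
                out.append(LabeledPeptide(seq, cls, label))
                truth.labels.append(
                    {"sequence": seq, "class": cls.value, "label": label}
                )
    return out, truth


def write_dataset(cfg: SynthConfig, out_dir: "str | Path") -> Path:
    """Generate and write a full dataset (FASTA, ident TSVs, quant CSV,
    labelled TSV) plus the ``truth.json`` ledger; returns the directory."""
    import pandas as pd

    from .refio import write_fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    proteome = gen_proteome(cfg)
    write_fasta(proteome, out_dir / "proteome.fasta")
    idents, truth = gen_ident_records(cfg, proteome)
    rows = [
        {
            "sequence": r.sequence,
            "product": r.product_id,
            "batch": r.batch_id,
            "fraction": r.fraction.value if r.fraction else "",
            "fdr_pass": str(r.fdr_pass).lower(),
        }
        for r in idents
    ]
    pd.DataFrame(rows).to_csv(out_dir / "idents.tsv", sep="\t", index=False)
    quant_inputs, truth = gen_quant_report(cfg, truth)
    pd.DataFrame(
        [
            {
                "peptide": q.peptide, "product": q.product_id,
                "batch": q.batch_id, "light_area": q.light_area,
                "heavy_area": q.heavy_area, "H_pmol": q.H,
                "total_peptide_ug": q.total_peptide_ug,
            }
            for q in quant_inputs
        ]
    ).to_csv(out_dir / "quant_report.csv", index=False)
    labeled, ltruth = gen_labeled_sets(cfg)
    truth.labels = ltruth.labels
    pd.DataFrame(
        [
            {
                "sequence": d.sequence,
                "activity_class": d.activity_class.value,
                "label": str(d.label).lower(),
            }
            for d in labeled
        ]
    ).to_csv(out_dir / "labeled_peptides.tsv", sep="\t", index=False)
    (out_dir / "truth.json").write_text(truth.to_json())
    return out_dir
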