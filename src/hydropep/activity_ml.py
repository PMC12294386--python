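"""Random-Forest activity classifiers over sequence-derived features.

Three independent binary classifiers predict antimicrobial, antiviral and
antioxidant activity of short peptides.  Each peptide is represented by
community-standard physicochemical features: amino-acid composition (20
fractions), length, monoisotopic mass, net charge at pH 7 (Henderson-
Hasselbalch over the standard sidechain and terminal pKa values), mean
Kyte-Doolittle hydropathy (GRAVY), aromaticity (fraction of F/W/Y) and
cysteine fraction; 400 dipeptide-composition fractions can be switched on.

Training uses a stratified 80/20 train/validation split and reports accuracy,
sensitivity and specificity on the held-out 20%.  With a fixed seed and input
order the whole procedure is bit-reproducible.  Predicted probability is the
forest vote fraction; the call threshold is 0.5 with ties called positive.
"""

from __future__ import annotations

import enum
import hashlib
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import joblib
import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .quant import peptide_mass
from .refio import ValidationError, clean_sequence

AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")
DIPEPTIDES = tuple(a + b for a, b in itertools.product(AA_ORDER, AA_ORDER))

DEFAULT_HYPERPARAMS = {
    "n_estimators": 500,
    "max_features": "sqrt",
    "max_depth": None,
}


class ActivityClass(enum.Enum):
    ANTIMICROBIAL = "antimicrobial"
    ANTIVIRAL = "antiviral"
    ANTIOXIDANT = "antioxidant"

    @classmethod
    def parse(cls, label: "str | ActivityClass") -> "ActivityClass":
        if isinstance(label, cls):
            return label
        return cls(label.strip().lower())


@dataclass(frozen=True)
class LabeledPeptide:
    sequence: str
    activity_class: ActivityClass
    label: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", clean_sequence(self.sequence))


@dataclass(frozen=True)
class ClassifierMetrics:
    accuracy: float
    sensitivity: float
    specificity: float


def feature_names(dipeptides: bool = False) -> list[str]:
    names = [f"comp_{aa}" for aa in AA_ORDER]
    names += ["length", "mass", "net_charge_pH7", "mean_hydropathy",
              "aromaticity", "cys_fraction"]
    if dipeptides:
        names += [f"dipep_{d}" for d in DIPEPTIDES]
    return names


def featurize(sequence: str, dipeptides: bool = False) -> np.ndarray:
    """Deterministic physicochemical feature vector of one peptide."""
    seq = clean_sequence(sequence)
    n = len(seq)
    pa = ProteinAnalysis(seq)
    comp = np.array([seq.count(aa) / n for aa in AA_ORDER])
    features = [
        *comp,
        float(n),
        peptide_mass(seq),
        pa.charge_at_pH(7.0),
        pa.gravy(),
        pa.aromaticity(),
        seq.count("C") / n,
    ]
    if dipeptides:
        pairs = max(n - 1, 1)
        counts = {d: 0 for d in DIPEPTIDES}
        for i in range(n - 1):
            counts[seq[i:i + 2]] += 1
        features += [counts[d] / pairs for d in DIPEPTIDES]
    vec = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(vec)):
        raise ValidationError(f"non-finite feature for {seq!r}")
    return vec


@dataclass
class ModelHandle:
    """A trained forest plus the feature schema it expects."""

    activity_class: ActivityClass
    forest: RandomForestClassifier
    dipeptides: bool
    schema_hash: str
    seed: int
    metrics: "ClassifierMetrics | None" = None

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelHandle":
        handle = joblib.load(path)
        expected = _schema_hash(handle.dipeptides)
        if handle.schema_hash != expected:
            raise ValidationError("model feature schema does not match this version")
        return handle


def _schema_hash(dipeptides: bool) -> str:
    return hashlib.sha256("|".join(feature_names(dipeptides)).encode()).hexdigest()[:16]


def evaluate(predictions: Sequence[bool], truth: Sequence[bool]) -> ClassifierMetrics:
    """Accuracy, sensitivity and specificity from paired boolean vectors."""
    if len(predictions) != len(truth):
        raise ValidationError(
            f"length mismatch: {len(predictions)} predictions vs {len(truth)} truths"
        )
    pred = np.asarray(predictions, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if not (true.any() and (~true).any()):
        raise ValidationError("truth must contain at least one positive and one negative")
    tp = int(np.sum(pred & true))
    tn = int(np.sum(~pred & ~true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    return ClassifierMetrics(
        accuracy=(tp + tn) / (tp + tn + fp + fn),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
    )


def train(
    data: Iterable[LabeledPeptide],
    activity_class: "str | ActivityClass",
    seed: int = 0,
    hyperparams: dict | None = None,
    dipeptides: bool = False,
) -> tuple[ModelHandle, ClassifierMetrics]:
    """Fit one activity's forest on an 80/20 stratified split.

    Only records of ``activity_class`` are used; both labels must be present
    and the class subset must hold at least 20 peptides.
    """
    activity_class = ActivityClass.parse(activity_class)
    subset = [d for d in data if d.activity_class is activity_class]
    if len(subset) < 20:
        raise ValidationError(
            f"{activity_class.value}: need >= 20 labelled peptides, got {len(subset)}"
        )
    y = np.array([d.label for d in subset], dtype=bool)
    if y.all() or not y.any():
        raise ValidationError(f"{activity_class.value}: both labels required")
    X = np.vstack([featurize(d.sequence, dipeptides=dipeptides) for d in subset])
    X_tr, X_va, y_tr, y_va = train_test_split(
        X, y, test_size=0.2, random_state=seed, stratify=y
    )
    params = dict(DEFAULT_HYPERPARAMS)
    params.update(hyperparams or {})
    forest = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    forest.fit(X_tr, y_tr)
    prob_va = forest.predict_proba(X_va)[:, list(forest.classes_).index(True)]
    metrics = evaluate(prob_va >= 0.5, y_va)
    handle = ModelHandle(
        activity_class=activity_class,
        forest=forest,
        dipeptides=dipeptides,
        schema_hash=_schema_hash(dipeptides),
        seed=seed,
        metrics=metrics,
    )
    return handle, metrics


def predict(
    model: ModelHandle, peptides: Iterable[str]
) -> tuple[list[tuple[str, float, bool]], list[tuple[str, str]]]:
    """Score peptides with a trained model.

    Returns ``(results, errors)`` where results are ``(peptide, probability,
    call)`` tuples and errors hold ``(peptide, reason)`` for records that
    could not be featurised; one bad record never aborts the run.
    """
    results: list[tuple[str, float, bool]] = []
    errors: list[tuple[str, str]] = []
    true_col = list(model.forest.classes_).index(True)
    for pep in peptides:
        try:
            vec = featurize(pep, dipeptides=model.dipeptides).reshape(1, -1)
        except (ValidationError, ValueError) as exc:
            errors.append((pep, str(exc)))
            continue
        prob = float(model.forest.predict_proba(vec)[0, true_col])
        results.append((pep.upper(), prob, prob >= 0.5))
    return results, errors
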