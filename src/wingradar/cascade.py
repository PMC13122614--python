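"""Hierarchical family -> genus -> species classification.

Stage 1 separates Vespidae from Apidae with a gradient-boosted tree
ensemble; Vespidae finalizes directly to *Vespula vulgaris*.  Stage 2
separates *Apis* from *Bombus* within Apidae (gradient boosting); *Apis*
finalizes to *A. mellifera*.  Stage 3 discriminates the three *Bombus*
species with an extremely-randomized-trees ensemble, whose randomized
splits generalize better when class separability is subtle.  Splits are
grouped by subject so no individual contributes to both train and test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, GradientBoostingClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .detection import HarmonicRatioParams, MicroDopplerSegment, resegment_durations
from .features import FeatureRegistry, default_registry, extract_features
from .preprocess import FilterSpec, highpass, normalize

SPECIES_TAXONOMY: dict[str, tuple[str, str]] = {
    "Vespula vulgaris": ("Vespidae", "Vespula"),
    "Apis mellifera": ("Apidae", "Apis"),
    "Bombus lapidarius": ("Apidae", "Bombus"),
    "Bombus muscorum": ("Apidae", "Bombus"),
    "Bombus terrestris": ("Apidae", "Bombus"),
}


@dataclass(frozen=True)
class TaxonomyTable:
    """Fixed two-family, three-genus, five-species tree."""

    table: tuple[tuple[str, str, str], ...] = tuple(
        (fam, gen, sp) for sp, (fam, gen) in sorted(SPECIES_TAXONOMY.items())
    )

    def __post_init__(self) -> None:
        species = [sp for _, _, sp in self.table]
        if len(set(species)) != len(species):
            raise ValueError("duplicate species")
        if len(species) != 5 or len(self.genera) != 3 or len(self.families) != 2:
            raise ValueError("expected 5 species, 3 genera, 2 families")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(sp for _, _, sp in self.table))

    @property
    def genera(self) -> tuple[str, ...]:
        return tuple(sorted({g for _, g, _ in self.table}))

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(sorted({f for f, _, _ in self.table}))

    def family_of(self, species: str) -> str:
        return self._lookup(species)[0]

    def genus_of(self, species: str) -> str:
        return self._lookup(species)[1]

    def _lookup(self, species: str) -> tuple[str, str]:
        for fam, gen, sp in self.table:
            if sp == species:
                return fam, gen
        raise KeyError(f"species {species!r} not in taxonomy")


TAXONOMY = TaxonomyTable()


@dataclass
class LabeledDataset:
    """Feature matrix plus species / subject / duration metadata."""

    frame: pd.DataFrame
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.frame["species"]) - set(SPECIES_TAXONOMY)
        if bad:
            raise ValueError(f"species outside taxonomy: {sorted(bad)}")
        if (self.frame["subject_id"] == "").any():
            raise ValueError("empty subject_id")

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.feature_names)].to_numpy(dtype=float)

    @property
    def species(self) -> np.ndarray:
        return self.frame["species"].to_numpy()

    @property
    def subjects(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.frame.loc[mask].reset_index(drop=True), self.feature_names)


def build_dataset(
    segments: list[MicroDopplerSegment], registry: FeatureRegistry | None = None
) -> LabeledDataset:
    """Extract features for every segment into one labeled table."""
    registry = registry or default_registry()
    rows = []
    for seg in segments:
        fv = extract_features(seg, registry)
        row = dict(fv.values)
        row.update(
            species=seg.species_name,
            subject_id=seg.subject_id,
            recording_id=seg.recording_id,
            duration_s=seg.duration_s,
            start_s=seg.start_s,
            eta_hr=seg.eta_hr,
        )
        rows.append(row)
    return LabeledDataset(pd.DataFrame(rows), registry.names)


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must lie in (0, 1)")


def subject_grouped_split(
    dataset: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset]:
    """Partition by subject, per species, greedily approaching the target.

    Within each species, shuffled subjects are moved to the test side while
    doing so brings that species' realized test sample fraction closer to
    the target.  A species with a single subject goes entirely to train
    (with a warning) since grouping admits no other assignment.
    """
    rng = np.random.default_rng(spec.seed)
    test_subjects: set[str] = set()
    df = dataset.frame
    for sp in sorted(df["species"].unique()):
        sub_counts = df.loc[df["species"] == sp].groupby("subject_id").size()
        subjects = list(sub_counts.index)
        if len(subjects) < 2:
            warnings.warn(
                f"species {sp!r} has a single subject; assigned to train",
                stacklevel=2,
            )
            continue
        rng.shuffle(subjects)
        total = sub_counts.sum()
        picked: list[str] = []
        n_test = 0
        for s in subjects:
            if len(picked) == len(subjects) - 1:
                break  # keep at least one subject in train
            new_frac = (n_test + sub_counts[s]) / total
            if abs(new_frac - spec.test_fraction) <= abs(n_test / total - spec.test_fraction):
                picked.append(s)
                n_test += sub_counts[s]
        test_subjects.update(picked)
    mask = df["subject_id"].isin(test_subjects).to_numpy()
    return dataset.subset(~mask), dataset.subset(mask)


def compute_class_weights(labels: np.ndarray) -> dict[str, float]:
    """w_c = total / (n_classes * count_c); sample-weighted mean is 1."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    total = counts.sum()
    return {
        str(c): float(total / (len(classes) * n)) for c, n in zip(classes, counts)
    }


@dataclass(frozen=True)
class CascadeConfig:
    n_estimators: int = 300
    max_depth: int = 6
    learning_rate: float = 0.1
    extratrees_estimators: int = 300
    use_class_weights: bool = True
    resample: str | None = None  # None | "oversample" | "undersample"
    seed: int = 0


@dataclass
class CascadeModel:
    stage1: GradientBoostingClassifier
    stage2: GradientBoostingClassifier
    stage3: ExtraTreesClassifier
    feature_names: tuple[str, ...]
    class_weights: dict[str, dict[str, float]]
    config: CascadeConfig
    taxonomy: TaxonomyTable = field(default_factory=TaxonomyTable)


def _sample_weights(labels: np.ndarray, weights: dict[str, float]) -> np.ndarray:
    return np.array([weights[str(c)] for c in labels])


def _resample(
    X: np.ndarray, y: np.ndarray, how: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max() if how == "oversample" else counts.min()
    idx_all = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        idx_all.append(rng.choice(idx, size=target, replace=how == "oversample"))
    keep = np.concatenate(idx_all)
    return X[keep], y[keep]


def fit_cascade(train: LabeledDataset, config: CascadeConfig | None = None) -> CascadeModel:
    """Train the three stages on true labels (each stage on its stratum)."""
    config = config or CascadeConfig()
    tax = TAXONOMY
    X = train.X
    species = train.species
    families = np.array([tax.family_of(s) for s in species])
    genera = np.array([tax.genus_of(s) for s in species])

    if len(np.unique(families)) < 2:
        raise ValueError("training data missing a family stratum")
    apidae = families == "Apidae"
    if len(np.unique(genera[apidae])) < 2:
        raise ValueError("Apidae rows missing a genus stratum")
    bombus = genera == "Bombus"
    if len(np.unique(species[bombus])) < 2:
        raise ValueError("Bombus rows missing a species stratum")

    rng = np.random.default_rng(config.seed)
    weights: dict[str, dict[str, float]] = {}

    def _fit(model, Xs, ys, key):
        if config.resample:
            Xs, ys = _resample(Xs, ys, config.resample, rng)
        weights[key] = compute_class_weights(ys)
        sw = _sample_weights(ys, weights[key]) if config.use_class_weights else None
        model.fit(Xs, ys, sample_weight=sw)
        return model

    stage1 = _fit(
        GradientBoostingClassifier(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
            learning_rate=config.learning_rate,
            random_state=config.seed,
        ),
        X,
        families,
        "family",
    )
    stage2 = _fit(
        GradientBoostingClassifier(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
            learning_rate=config.learning_rate,
            random_state=config.seed + 1,
        ),
        X[apidae],
        genera[apidae],
        "genus",
    )
    stage3 = _fit(
        ExtraTreesClassifier(
            n_estimators=config.extratrees_estimators,
            random_state=config.seed + 2,
        ),
        X[bombus],
        species[bombus],
        "species",
    )
    return CascadeModel(stage1, stage2, stage3, train.feature_names, weights, config)


def predict_cascade(model: CascadeModel, X: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Route every row through the hierarchy; returns (family, genus, species).

    Vespidae finalizes to Vespula vulgaris without invoking later stages;
    Apis finalizes to Apis mellifera; only Bombus rows reach stage 3.  Every
    returned triple is a valid taxonomy path by construction.
    """
    if isinstance(X, pd.DataFrame):
        X = X[list(model.feature_names)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(X)
    family = model.stage1.predict(X)
    genus = np.empty(n, dtype=object)
    species = np.empty(n, dtype=object)
    vesp = family == "Vespidae"
    genus[vesp] = "Vespula"
    species[vesp] = "Vespula vulgaris"
    apid = ~vesp
    if apid.any():
        g = model.stage2.predict(X[apid])
        genus[apid] = g
        apis_rows = np.flatnonzero(apid)[g == "Apis"]
        species[apis_rows] = "Apis mellifera"
        bombus_rows = np.flatnonzero(apid)[g == "Bombus"]
        if bombus_rows.size:
            species[bombus_rows] = model.stage3.predict(X[bombus_rows])
    return pd.DataFrame({"family": family, "genus": genus, "species": species})


@dataclass
class EvaluationReport:
    """Cumulative confusion matrices and per-class metrics at each level."""

    confusion: dict[str, pd.DataFrame]
    per_class: pd.DataFrame
    accuracy: dict[str, float]
    micro_f1: float
    n_test: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "micro_f1": self.micro_f1,
            "n_test": self.n_test,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": {k: v.to_dict() for k, v in self.confusion.items()},
        }


def f1_score_from_counts(tp: int, fp: int, fn: int) -> float:
    """F1 = 2 * precision * recall / (precision + recall)."""
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate(pred_species: np.ndarray, true_species: np.ndarray) -> EvaluationReport:
    """Species / genus / family confusion matrices and per-class P/R/F1.

    Genus- and family-level matrices are cumulative: species finalized at
    an earlier stage are carried forward by mapping both prediction and
    truth up the taxonomy.  Accuracy is trace / total at each level; for
    single-label evaluation the species accuracy equals micro-averaged F1.
    """
    tax = TAXONOMY
    pred_species = np.asarray(pred_species, dtype=object)
    true_species = np.asarray(true_species, dtype=object)
    for lab in np.unique(np.concatenate([pred_species, true_species])):
        tax._lookup(str(lab))  # raises on labels outside the taxonomy
    levels = {
        "species": (lambda s: s, tax.species),
        "genus": (tax.genus_of, tax.genera),
        "family": (tax.family_of, tax.families),
    }
    confusion: dict[str, pd.DataFrame] = {}
    accuracy: dict[str, float] = {}
    for name, (mapper, labels) in levels.items():
        t = np.array([mapper(str(s)) for s in true_species])
        p = np.array([mapper(str(s)) for s in pred_species])
        cm = confusion_matrix(t, p, labels=list(labels))
        confusion[name] = pd.DataFrame(cm, index=list(labels), columns=list(labels))
        accuracy[name] = float(np.trace(cm) / cm.sum())
    prec, rec, f1, support = precision_recall_fscore_support(
        true_species, pred_species, labels=list(tax.species), zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=list(tax.species),
    )
    micro = precision_recall_fscore_support(
        true_species, pred_species, average="micro", zero_division=0
    )[2]
    return EvaluationReport(
        confusion=confusion,
        per_class=per_class,
        accuracy=accuracy,
        micro_f1=float(micro),
        n_test=len(true_species),
    )


def duration_sweep(
    recordings,
    durations: tuple[float, ...],
    config: CascadeConfig | None = None,
    registry: FeatureRegistry | None = None,
    filter_spec: FilterSpec | None = None,
    hr_params: HarmonicRatioParams | None = None,
    split: SplitSpec | None = None,
    max_segments_per_recording: int | None = 50,
) -> pd.DataFrame:
    """detect -> extract -> split -> fit -> evaluate at each duration.

    Every duration is scanned independently over each preprocessed
    recording (50% overlap); the subject partition is computed once from
    the longest-duration dataset and reused so accuracies are paired across
    durations.
    """
    config = config or CascadeConfig()
    registry = registry or default_registry()
    filter_spec = filter_spec or FilterSpec()
    hr_params = hr_params or HarmonicRatioParams()
    split = split or SplitSpec(seed=config.seed)
    durations = tuple(sorted(durations, reverse=True))

    per_duration: dict[float, list[MicroDopplerSegment]] = {d: [] for d in durations}
    for rec in recordings:
        clean = highpass(normalize(rec.iq), filter_spec, rec.fs)
        segs = resegment_durations(
            rec,
            durations,
            hr_params,
            mode="independent",
            preprocessed_iq=clean,
            max_segments_per_duration=max_segments_per_recording,
        )
        for d, s in segs.items():
            per_duration[d].extend(s)

    datasets = {d: build_dataset(per_duration[d], registry) for d in durations}
    # one subject partition, from the longest duration, reused throughout
    ref_train, ref_test = subject_grouped_split(datasets[durations[0]], split)
    test_subjects = set(ref_test.subjects)

    rows = []
    for d in durations:
        ds = datasets[d]
        mask = ds.frame["subject_id"].isin(test_subjects).to_numpy()
        train, test = ds.subset(~mask), ds.subset(mask)
        model = fit_cascade(train, config)
        pred = predict_cascade(model, test.X)
        report = evaluate(pred["species"].to_numpy(), test.species)
        row = {
            "duration_s": d,
            "n_segments": len(ds),
            "n_train": len(train),
            "n_test": len(test),
            "accuracy": report.accuracy["species"],
        }
        for sp in TAXONOMY.species:
            row[f"f1_{sp.replace(' ', '_')}"] = report.per_class.loc[sp, "f1"]
        rows.append(row)
    return pd.DataFrame(rows)
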