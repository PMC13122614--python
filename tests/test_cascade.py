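import numpy as np
import pandas as pd
import pytest

import wingradar as wr
from wingradar.cascade import SPECIES_TAXONOMY


def synthetic_feature_dataset(
    n_per_species=40, n_subjects=5, seed=0, separation=6.0
) -> wr.LabeledDataset:
    """Linearly separable 10-feature table with subject structure."""
    rng = np.random.default_rng(seed)
    names = tuple(f"f{i}" for i in range(10))
    rows = []
    for si, sp in enumerate(sorted(SPECIES_TAXONOMY)):
        center = np.zeros(10)
        center[si % 10] = separation
        center[(si + 3) % 10] = -separation
        for j in range(n_per_species):
            row = dict(zip(names, center + rng.normal(size=10)))
            row["species"] = sp
            row["subject_id"] = f"{sp}-{j % n_subjects}"
            row["duration_s"] = 2.0
            rows.append(row)
    return wr.LabeledDataset(pd.DataFrame(rows), names)


class TestTaxonomy:
    def test_structure(self):
        tax = wr.TAXONOMY
        assert len(tax.species) == 5
        assert tax.genera == ("Apis", "Bombus", "Vespula")
        assert tax.families == ("Apidae", "Vespidae")
        assert tax.family_of("Vespula vulgaris") == "Vespidae"
        assert tax.genus_of("Bombus muscorum") == "Bombus"

    def test_unknown_species_rejected(self):
        with pytest.raises(KeyError):
            wr.TAXONOMY.family_of("Musca domestica")


class TestSubjectGroupedSplit:
    def test_no_subject_leakage(self):
        ds = synthetic_feature_dataset()
        tr, te = wr.subject_grouped_split(ds, wr.SplitSpec(seed=0))
        assert set(tr.subjects).isdisjoint(te.subjects)

    def test_five_subjects_per_species_puts_one_in_test(self):
        ds = synthetic_feature_dataset(n_per_species=50, n_subjects=5, seed=1)
        _, te = wr.subject_grouped_split(ds, wr.SplitSpec(test_fraction=0.2, seed=3))
        per_species = te.frame.groupby("species")["subject_id"].nunique()
        assert (per_species == 1).all()
        assert len(te) / len(ds) == pytest.approx(0.2, abs=1e-9)

    def test_deterministic_under_seed(self):
        ds = synthetic_feature_dataset()
        a = wr.subject_grouped_split(ds, wr.SplitSpec(seed=5))
        b = wr.subject_grouped_split(ds, wr.SplitSpec(seed=5))
        assert np.array_equal(a[1].subjects, b[1].subjects)

    def test_single_subject_species_warns_and_goes_to_train(self):
        ds = synthetic_feature_dataset(n_subjects=1)
        with pytest.warns(UserWarning, match="single subject"):
            tr, te = wr.subject_grouped_split(ds, wr.SplitSpec(seed=0))
        assert len(te) == 0 and len(tr) == len(ds)


class TestClassWeights:
    def test_balanced_labels_give_unit_weights(self):
        w = wr.compute_class_weights(np.array(["a"] * 10 + ["b"] * 10))
        assert w == {"a": 1.0, "b": 1.0}

    def test_stated_formula_on_100_50(self):
        w = wr.compute_class_weights(np.array(["a"] * 100 + ["b"] * 50))
        assert w["a"] == pytest.approx(0.75)
        assert w["b"] == pytest.approx(1.5)

    def test_weights_decrease_with_class_count(self):
        labels = np.array(["a"] * 60 + ["b"] * 30 + ["c"] * 10)
        w = wr.compute_class_weights(labels)
        assert w["a"] < w["b"] < w["c"]


SMALL_CONFIG = wr.CascadeConfig(
    n_estimators=40, max_depth=3, extratrees_estimators=60, seed=0
)


@pytest.fixture(scope="module")
def fitted():
    ds = synthetic_feature_dataset(seed=2)
    tr, te = wr.subject_grouped_split(ds, wr.SplitSpec(seed=2))
    return wr.fit_cascade(tr, SMALL_CONFIG), tr, te


class TestCascadeFitPredict:
    CONFIG = SMALL_CONFIG

    def test_training_accuracy_on_separable_features(self, fitted):
        model, tr, _ = fitted
        pred = wr.predict_cascade(model, tr.X)
        assert np.mean(pred["species"].to_numpy() == tr.species) >= 0.99

    def test_stage_strata(self, fitted):
        model, _, _ = fitted
        assert set(model.stage1.classes_) == {"Apidae", "Vespidae"}
        assert set(model.stage2.classes_) == {"Apis", "Bombus"}
        assert set(model.stage3.classes_) == {
            "Bombus lapidarius",
            "Bombus muscorum",
            "Bombus terrestris",
        }

    def test_predictions_are_valid_taxonomy_paths(self, fitted):
        model, _, te = fitted
        pred = wr.predict_cascade(model, te.X)
        for _, row in pred.iterrows():
            fam, gen = SPECIES_TAXONOMY[row["species"]]
            assert row["family"] == fam and row["genus"] == gen

    def test_vespidae_routing_shortcuts_to_vulgaris(self, fitted):
        model, _, te = fitted
        pred = wr.predict_cascade(model, te.X)
        vesp = pred[pred["family"] == "Vespidae"]
        assert (vesp["species"] == "Vespula vulgaris").all()
        assert (vesp["genus"] == "Vespula").all()

    def test_refit_is_deterministic(self, fitted):
        _, tr, te = fitted
        m1 = wr.fit_cascade(tr, self.CONFIG)
        m2 = wr.fit_cascade(tr, self.CONFIG)
        p1 = wr.predict_cascade(m1, te.X)["species"]
        p2 = wr.predict_cascade(m2, te.X)["species"]
        assert p1.equals(p2)

    def test_missing_stratum_raises(self):
        ds = synthetic_feature_dataset(seed=3)
        only_apidae = ds.subset(ds.frame["species"] != "Vespula vulgaris")
        with pytest.raises(ValueError, match="family"):
            wr.fit_cascade(only_apidae, self.CONFIG)


class TestEvaluate:
    def test_f1_from_printed_style_confusion(self):
        # TP=8, FP=2, FN=1 -> precision 0.8, recall 8/9, F1 ~= 0.842
        assert wr.f1_score_from_counts(8, 2, 1) == pytest.approx(0.8421052631578948)

    def test_per_class_metrics_match_hand_counts(self):
        a, b = "Apis mellifera", "Vespula vulgaris"
        truth = np.array([a] * 9 + [b] * 7)
        pred = np.array([a] * 8 + [b] * 1 + [a] * 2 + [b] * 5)
        rep = wr.evaluate(pred, truth)
        assert rep.per_class.loc[a, "precision"] == pytest.approx(0.8)
        assert rep.per_class.loc[a, "recall"] == pytest.approx(8 / 9)
        assert rep.per_class.loc[a, "f1"] == pytest.approx(0.8421052631578948)

    def test_perfect_predictions(self):
        truth = np.array(sorted(SPECIES_TAXONOMY) * 3)
        rep = wr.evaluate(truth.copy(), truth)
        assert rep.accuracy == {"species": 1.0, "genus": 1.0, "family": 1.0}
        assert (rep.per_class["f1"] == 1.0).all()

    def test_micro_f1_equals_accuracy(self):
        rng = np.random.default_rng(4)
        species = np.array(sorted(SPECIES_TAXONOMY))
        truth = rng.choice(species, size=200)
        pred = rng.choice(species, size=200)
        rep = wr.evaluate(pred, truth)
        assert rep.micro_f1 == pytest.approx(rep.accuracy["species"], abs=1e-12)

    def test_confusion_matrices_are_cumulative_and_consistent(self):
        rng = np.random.default_rng(5)
        species = np.array(sorted(SPECIES_TAXONOMY))
        truth = rng.choice(species, size=120)
        pred = rng.choice(species, size=120)
        rep = wr.evaluate(pred, truth)
        for level in ("species", "genus", "family"):
            cm = rep.confusion[level]
            assert cm.to_numpy().sum() == 120
        # genus-level accuracy can never be below species-level accuracy
        assert rep.accuracy["genus"] >= rep.accuracy["species"]
        assert rep.accuracy["family"] >= rep.accuracy["genus"]

    def test_label_outside_taxonomy_rejected(self):
        with pytest.raises(KeyError):
            wr.evaluate(np.array(["Musca domestica"]), np.array(["Apis mellifera"]))
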