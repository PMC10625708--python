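"""Ensemble contract: voting algebra, degeneracies, persistence."""

import numpy as np
import pytest

from cellstate import (
    default_specs,
    fit_ensemble,
    load_model,
    predict,
    predict_proba,
    save_model,
    stratified_split,
)
from cellstate.models import FAMILIES, BaseLearnerSpec, ModelFormatError


@pytest.fixture(scope="module")
def fitted(small_sim_module):
    dataset, genes = small_sim_module
    model = fit_ensemble(dataset, genes, default_specs(0))
    return dataset, model


@pytest.fixture(scope="module")
def small_sim_module():
    from cellstate import SyntheticSpec, generate, normalize_dataset

    spec = SyntheticSpec(
        class_sizes=(40, 60, 50),
        class_names=("alpha", "beta", "gamma"),
        n_genes=80,
        n_markers_per_class=5,
        marker_fold_change=16.0,
        seed=11,
    )
    raw, truth = generate(spec)
    dataset = normalize_dataset(raw)
    genes = tuple(g for ms in truth.markers.values() for g in ms)
    return dataset, genes


class TestVotingAlgebra:
    def test_single_nonzero_weight_equals_that_member(self, small_sim_module):
        dataset, genes = small_sim_module
        model = fit_ensemble(dataset, genes, default_specs(0), weights=(1, 0, 0, 0))
        ens_labels = predict(model, dataset.matrix)
        member = model.members[0]
        X = dataset.matrix.values[:, dataset.matrix.gene_index(genes)]
        member_labels = tuple(dataset.class_names[c] for c in member.predict(X))
        assert ens_labels == member_labels

    def test_weight_scaling_leaves_probabilities_unchanged(self, fitted):
        dataset, model = fitted
        base = predict_proba(model, dataset.matrix)
        scaled = fit_ensemble(dataset, model.gene_subset, default_specs(0), (3, 3, 3, 3))
        np.testing.assert_allclose(predict_proba(scaled, dataset.matrix), base, atol=1e-12)

    def test_rows_sum_to_one(self, fitted):
        dataset, model = fitted
        proba = predict_proba(model, dataset.matrix)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_two_member_weighted_mean(self, fitted):
        # analytic check of the voting arithmetic on stubbed probabilities
        dataset, model = fitted

        class Stub:
            def __init__(self, row):
                self.row = np.asarray(row)
                self.classes_ = np.arange(3)

            def predict_proba(self, X):
                return np.tile(self.row, (len(X), 1))

        model2 = type(model)(
            members=(Stub([0.8, 0.2, 0.0]), Stub([0.4, 0.6, 0.0]), Stub([1, 0, 0]), Stub([1, 0, 0])),
            specs=model.specs,
            weights=np.array([1.0, 1.0, 0.0, 0.0]),
            gene_subset=model.gene_subset,
            class_names=model.class_names,
        )
        proba = predict_proba(model2, dataset.matrix)
        np.testing.assert_allclose(proba[0], [0.6, 0.4, 0.0], atol=1e-12)

    def test_all_zero_weights_rejected(self, small_sim_module):
        dataset, genes = small_sim_module
        with pytest.raises(ValueError, match="at least one weight"):
            fit_ensemble(dataset, genes, default_specs(0), weights=(0, 0, 0, 0))

    def test_unknown_gene_named_in_error(self, small_sim_module):
        dataset, genes = small_sim_module
        with pytest.raises(KeyError, match="NOT_A_GENE"):
            fit_ensemble(dataset, genes[:3] + ("NOT_A_GENE",), default_specs(0))

    def test_argmax_ties_take_earliest_class(self, fitted):
        dataset, model = fitted

        class Tied:
            classes_ = np.arange(3)

            def predict_proba(self, X):
                return np.tile([0.5, 0.5, 0.0], (len(X), 1))

        tied = type(model)(
            members=(Tied(), Tied(), Tied(), Tied()),
            specs=model.specs,
            weights=np.ones(4),
            gene_subset=model.gene_subset,
            class_names=model.class_names,
        )
        assert set(predict(tied, dataset.matrix)) == {dataset.class_names[0]}


class TestEnsembleOutperformsMembers:
    def test_ensemble_tracks_best_member_across_seeds(self):
        """Soft voting should never fall meaningfully below its best member."""
        from cellstate import SyntheticSpec, generate, normalize_dataset

        failures = []
        for seed in range(10):
            spec = SyntheticSpec(
                class_sizes=(40, 90, 70),
                class_names=("a", "b", "c"),
                n_genes=120,
                n_markers_per_class=6,
                marker_fold_change=16.0,
                seed=100 + seed,
            )
            raw, truth = generate(spec)
            dataset = normalize_dataset(raw)
            train, test = stratified_split(dataset, 0.3, seed)
            genes = tuple(g for ms in truth.markers.values() for g in ms)
            model = fit_ensemble(train, genes, default_specs(seed))
            X = test.matrix.values[:, test.matrix.gene_index(genes)]
            y = test.label_codes()
            member_acc = [float(np.mean(m.predict(X) == y)) for m in model.members]
            ens_acc = float(np.mean(np.asarray(predict(model, test.matrix)) == np.asarray(test.labels)))
            if ens_acc < max(member_acc) - 0.02:
                failures.append((seed, ens_acc, max(member_acc)))
        assert not failures, failures


class TestPersistence:
    def test_save_load_roundtrip_preserves_predictions(self, fitted, tmp_path):
        dataset, model = fitted
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(
            predict_proba(loaded, dataset.matrix), predict_proba(model, dataset.matrix)
        )
        assert predict(loaded, dataset.matrix) == predict(model, dataset.matrix)
        assert loaded.gene_subset == model.gene_subset
        assert loaded.class_names == model.class_names

    def test_corrupt_file_rejected(self, tmp_path):
        p = tmp_path / "junk.joblib"
        p.write_bytes(b"this is not a model")
        with pytest.raises(ModelFormatError):
            load_model(p)

    def test_wrong_payload_rejected(self, tmp_path):
        import joblib

        p = tmp_path / "other.joblib"
        joblib.dump({"something": 1}, p)
        with pytest.raises(ModelFormatError, match="not a saved ensemble"):
            load_model(p)
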