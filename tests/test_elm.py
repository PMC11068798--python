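"""ROI splitting and the closed-form classifier."""

import numpy as np
import pytest

from spatannot import (
    ELMConfig,
    NormalizedMatrix,
    ValidationError,
    annotate,
    elm_predict,
    elm_train,
    generate_dataset,
    load_model,
    save_model,
    split_rois,
    train_annotator,
)
from spatannot.elm import ACTIVATIONS, elm_hidden
from spatannot.io import IntensityTable
from conftest import small_config


def _roi_table(n_rois, cells_per_roi=3, statuses=None):
    n = n_rois * cells_per_roi
    roi_ids = np.repeat([f"r{i}" for i in range(n_rois)], cells_per_roi)
    status = None
    if statuses is not None:
        status = np.repeat([statuses[i % len(statuses)] for i in range(n_rois)],
                           cells_per_roi)
    return IntensityTable(
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        roi_ids=roi_ids.astype(object),
        x=np.zeros(n), y=np.zeros(n),
        intensities=np.ones((n, 2)),
        protein_names=["P1", "P2"],
        status=None if status is None else status.astype(object),
    )


class TestSplitRois:
    def test_ten_rois_split_five_five(self):
        plan = split_rois(_roi_table(10), frac=0.5, seed=1)
        assert len(plan.train_rois) == 5 and len(plan.test_rois) == 5

    def test_stratified_two_by_four(self):
        table = _roi_table(8, statuses=["Control", "T1D"])
        plan = split_rois(table, frac=0.5, stratify=True, seed=2)
        status_of = {f"r{i}": ("Control" if i % 2 == 0 else "T1D") for i in range(8)}
        for group in (plan.train_rois, plan.test_rois):
            counts = {"Control": 0, "T1D": 0}
            for roi in group:
                counts[status_of[roi]] += 1
            assert counts == {"Control": 2, "T1D": 2}

    def test_cells_never_straddle_the_split(self):
        table = _roi_table(7, cells_per_roi=5)
        for seed in range(10):
            plan = split_rois(table, frac=0.4, seed=seed)
            mask = plan.train_mask(table.roi_ids)
            for roi in set(table.roi_ids):
                roi_mask = table.roi_ids == roi
                assert mask[roi_mask].all() or (~mask[roi_mask]).all()
            assert set(plan.train_rois) | set(plan.test_rois) == set(map(str, table.roi_ids))

    def test_deterministic_given_seed(self):
        table = _roi_table(9)
        assert split_rois(table, seed=5).train_rois == split_rois(table, seed=5).train_rois

    def test_singleton_status_goes_to_train_with_warning(self):
        table = _roi_table(3, statuses=["A", "B", "B"])
        # roi r0 is the only "A"
        status = np.repeat(["A", "B", "B"], 3).astype(object)
        table = IntensityTable(
            cell_ids=table.cell_ids, roi_ids=table.roi_ids, x=table.x, y=table.y,
            intensities=table.intensities, protein_names=table.protein_names,
            status=status,
        )
        with pytest.warns(UserWarning, match="single ROI"):
            plan = split_rois(table, stratify=True, seed=0)
        assert "r0" in plan.train_rois

    def test_fewer_than_two_rois_rejected(self):
        with pytest.raises(ValidationError, match="2 ROIs"):
            split_rois(_roi_table(1))


def _unit_rows(values, proteins):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(values, proteins, "unit")


class TestElmTrain:
    def test_identity_hidden_layer_recovers_onehot(self, monkeypatch):
        # with phi = identity, W_in = I, b_in = 0 and X = I, H is the identity
        # so the closed-form solution is exactly the one-hot label matrix
        import spatannot.elm as elm_mod

        X = _unit_rows(np.eye(3), ["P1", "P2", "P3"])
        labels = np.array(["a", "b", "a"], dtype=object)
        monkeypatch.setitem(ACTIVATIONS, "identity", lambda z: z)

        class FixedRng:
            def standard_normal(self, shape):
                return np.eye(3) if shape == (3, 3) else np.zeros(shape)

        monkeypatch.setattr(elm_mod.np.random, "default_rng", lambda seed: FixedRng())
        model = elm_train(X, labels, ["a", "b"], ELMConfig(n_hidden=3, activation="identity"))
        expected = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(model.W_out, expected, atol=1e-10)

    @pytest.mark.parametrize("trial", range(5))
    def test_training_residual_is_least_squares_optimal(self, trial):
        rng = np.random.default_rng(100 + trial)
        n, p, h = 30, 4, 10
        X = _unit_rows(rng.uniform(0, 1, size=(n, p)), [f"P{j}" for j in range(p)])
        labels = rng.choice(["a", "b", "c"], size=n).astype(object)
        model = elm_train(X, labels, ["a", "b", "c"], ELMConfig(n_hidden=h, seed=trial))
        H = elm_hidden(model, X.values)
        Y = np.zeros((n, 3))
        for i, lab in enumerate(labels):
            Y[i, ["a", "b", "c"].index(lab)] = 1.0
        res_model = np.linalg.norm(H @ model.W_out - Y)
        W_ls, *_ = np.linalg.lstsq(H, Y, rcond=None)  # independent solver
        res_ls = np.linalg.norm(H @ W_ls - Y)
        assert res_model == pytest.approx(res_ls, rel=1e-8, abs=1e-10)

    def test_same_seed_identical_weights(self, rng):
        X = _unit_rows(rng.uniform(0, 1, size=(20, 3)), ["A", "B", "C"])
        labels = rng.choice(["a", "b"], size=20).astype(object)
        m1 = elm_train(X, labels, ["a", "b"], ELMConfig(seed=9))
        m2 = elm_train(X, labels, ["a", "b"], ELMConfig(seed=9))
        np.testing.assert_array_equal(m1.W_in, m2.W_in)
        np.testing.assert_array_equal(m1.b_in, m2.b_in)
        np.testing.assert_array_equal(m1.W_out, m2.W_out)

    def test_underdetermined_system_warns(self, rng):
        X = _unit_rows(rng.uniform(0, 1, size=(5, 2)), ["A", "B"])
        labels = np.array(["a"] * 5, dtype=object)
        with pytest.warns(UserWarning, match="underdetermined"):
            elm_train(X, labels, ["a"], ELMConfig(n_hidden=50))

    def test_unknown_training_label_rejected(self, rng):
        X = _unit_rows(rng.uniform(0, 1, size=(4, 2)), ["A", "B"])
        with pytest.raises(ValidationError, match="label order"):
            elm_train(X, np.array(["zzz"] * 4, dtype=object), ["a", "b"])


class TestElmPredict:
    def test_single_class_training_predicts_that_class(self, rng):
        X = _unit_rows(rng.uniform(0, 1, size=(25, 3)), ["A", "B", "C"])
        labels = np.array(["only"] * 25, dtype=object)
        model = elm_train(X, labels, ["only", "other"], ELMConfig(seed=0))
        pred = elm_predict(model, X)
        assert (pred.labels == "only").all()

    def test_panel_mismatch_lists_proteins(self, rng):
        X = _unit_rows(rng.uniform(0, 1, size=(10, 2)), ["A", "B"])
        model = elm_train(X, np.array(["a"] * 10, dtype=object), ["a"], ELMConfig(seed=0))
        X_bad = _unit_rows(rng.uniform(0, 1, size=(4, 2)), ["A", "ZZ"])
        with pytest.raises(ValidationError, match="ZZ"):
            elm_predict(model, X_bad)

    def test_round_tripped_model_predicts_identically(self, rng, tmp_path):
        X = _unit_rows(rng.uniform(0, 1, size=(30, 3)), ["A", "B", "C"])
        labels = rng.choice(["a", "b"], size=30).astype(object)
        model = elm_train(X, labels, ["a", "b"], ELMConfig(seed=4))
        path = tmp_path / "m.zip"
        save_model(model, path)
        pred1 = elm_predict(model, X)
        pred2 = elm_predict(load_model(path), X)
        np.testing.assert_array_equal(pred1.labels, pred2.labels)
        np.testing.assert_array_equal(pred1.scores, pred2.scores)


class TestAnnotationTransfer:
    """A model trained on one cohort annotates an independent cohort."""

    def test_transfer_to_new_rois(self):
        cfg_a = small_config(seed=21, n_rois=6, cells_per_roi=600)
        table_a, spec, truth_a = generate_dataset(cfg_a)
        result = train_annotator(table_a, spec, seed=1)

        cfg_b = small_config(seed=22, n_rois=3, cells_per_roi=600)
        table_b, _, truth_b = generate_dataset(cfg_b)
        pred = annotate(result.model, table_b)
        truth_map = dict(zip(truth_b.cell_ids, truth_b.labels))
        y = np.array([truth_map[c] for c in pred.cell_ids], dtype=object)
        assert np.mean(pred.labels == y) >= 0.95

    def test_elm_at_least_matches_nearest_centroid_minus_two_points(self):
        cfg = small_config(seed=31, n_rois=6, cells_per_roi=600)
        table, spec, truth = generate_dataset(cfg)
        result = train_annotator(table, spec, seed=2)
        truth_map = dict(zip(truth.cell_ids, truth.labels))
        test_mask = ~result.split.train_mask(table.roi_ids)
        held = table.subset(test_mask)
        y = np.array([truth_map[c] for c in held.cell_ids], dtype=object)

        pred = annotate(result.model, held)
        acc_elm = np.mean(pred.labels == y)

        # nearest-centroid baseline from the clustering stage's centroids
        from spatannot.preprocessing import log_pseudocount, unit_normalize
        from spatannot.annotator import (
            GateConfig, abundance_order, constrained_kmeans, marker_score,
            seed_centroids, select_representatives,
        )

        X_tr = unit_normalize(log_pseudocount(table.subset(~test_mask)))
        order = abundance_order(X_tr, spec)
        scores = {ct: marker_score(X_tr, spec, ct) for ct in spec.cell_types}
        reps = select_representatives(scores, GateConfig(), order, include_unknown=False)
        sets = [reps.rep_indices[ct] for ct in spec.cell_types]
        state = constrained_kmeans(X_tr.values, sets, seed_centroids(X_tr.values, sets),
                                   label_names=spec.cell_types)
        X_ts = unit_normalize(log_pseudocount(held))
        d2 = ((X_ts.values[:, None, :] - state.centroids[None]) ** 2).sum(axis=2)
        ssc_labels = np.asarray(spec.cell_types, dtype=object)[d2.argmin(axis=1)]
        acc_ssc = np.mean(ssc_labels == y)
        assert acc_elm >= acc_ssc - 0.02
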