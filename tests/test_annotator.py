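"""Marker scoring, percentile gating and the constrained K-means contract."""

import numpy as np
import pytest

from spatannot import (
    GateConfig,
    GatingError,
    MarkerSpec,
    NormalizedMatrix,
    ValidationError,
    abundance_order,
    constrained_kmeans,
    generate_dataset,
    log_pseudocount,
    marker_score,
    seed_centroids,
    select_representatives,
    unit_normalize,
)
from conftest import small_config


def _unit(values, proteins):
    return NormalizedMatrix(np.asarray(values, float), proteins, "unit")


class TestMarkerScore:
    def test_single_positive_marker_is_that_column(self):
        X = _unit([[0.1, 0.9], [0.8, 0.2]], ["A", "B"])
        spec = MarkerSpec(["t"], {"t": ["A"]}, {"t": []})
        np.testing.assert_array_equal(marker_score(X, spec, "t"), X.values[:, 0])

    def test_cell_at_negative_marker_max_scores_zero(self):
        X = _unit([[0.5, 0.9], [0.5, 0.2]], ["A", "B"])
        spec = MarkerSpec(["t"], {"t": ["A"]}, {"t": ["B"]})
        scores = marker_score(X, spec, "t")
        assert scores[0] == 0.0
        assert scores[1] > 0.0

    def test_matches_scalar_brute_force(self, rng):
        values = rng.uniform(0, 1, size=(5, 3))
        values /= np.linalg.norm(values, axis=1, keepdims=True)
        X = _unit(values, ["A", "B", "C"])
        spec = MarkerSpec(["t"], {"t": ["A", "C"]}, {"t": ["B"]})
        scores = marker_score(X, spec, "t")
        col_max_b = values[:, 1].max()
        for i in range(5):
            expected = values[i, 0] * values[i, 2] * (col_max_b - values[i, 1])
            assert scores[i] == pytest.approx(expected, rel=1e-12)
        assert (scores >= 0).all()

    def test_unknown_marker_error_names_protein_and_type(self):
        X = _unit([[0.5]], ["A"])
        spec = MarkerSpec(["t"], {"t": ["MISSING"]}, {"t": []})
        with pytest.raises(ValidationError, match="MISSING.*'t'"):
            marker_score(X, spec, "t")

    def test_requires_unit_provenance(self, tiny_table, tiny_spec):
        with pytest.raises(ValidationError, match="unit"):
            marker_score(log_pseudocount(tiny_table), tiny_spec, "alpha")


class TestAbundanceOrder:
    def test_dominant_type_ranked_first(self, tiny_table, tiny_spec):
        X = unit_normalize(log_pseudocount(tiny_table))
        assert abundance_order(X, tiny_spec)[0] == "alpha"  # 3 of 5 cells

    def test_exact_ties_keep_file_order(self):
        X = _unit([[0.5, 0.5], [0.5, 0.5]], ["A", "B"])
        spec = MarkerSpec(["z_last", "a_first"], {"z_last": ["A"], "a_first": ["B"]}, {})
        assert abundance_order(X, spec) == ["z_last", "a_first"]

    def test_recovers_known_proportions(self):
        cfg = small_config(seed=3, n_rois=2, cells_per_roi=2000)
        table, spec, _ = generate_dataset(cfg)
        X = unit_normalize(log_pseudocount(table))
        assert abundance_order(X, spec) == ["t1", "t2", "t3", "t4"]  # 0.5/0.3/0.15/0.05


class TestSelectRepresentatives:
    def test_q95_with_distinct_scores_selects_about_five_percent(self, rng):
        scores = {"t": rng.permutation(100).astype(float)}
        cfg = GateConfig(q_high=95.0, q_max=100.0, q_low=50.0)
        reps = select_representatives(scores, cfg, ["t"], include_unknown=False)
        assert len(reps.rep_indices["t"]) == 5

    def test_qmax_100_admits_the_maximum(self, rng):
        scores = {"t": np.arange(100, dtype=float)}
        reps = select_representatives(
            scores, GateConfig(q_high=95.0, q_max=100.0), ["t"], include_unknown=False
        )
        assert 99 in reps.rep_indices["t"]
        reps_trim = select_representatives(
            scores, GateConfig(q_high=90.0, q_max=99.0), ["t"], include_unknown=False
        )
        assert 99 not in reps_trim.rep_indices["t"]

    def test_two_type_gating_matches_sorting_oracle(self, rng):
        n = 400
        a = rng.uniform(0, 1, n)
        b = 1.0 - a + rng.normal(0, 0.01, n)  # anti-correlated
        scores = {"ta": a, "tb": b}
        cfg = GateConfig(q_high=95.0, q_max=100.0)
        reps = select_representatives(scores, cfg, ["ta", "tb"], include_unknown=False)
        # oracle: strict > on the interpolated percentile
        expect_a = set(np.flatnonzero(a > np.percentile(a, 95)))
        assert set(reps.rep_indices["ta"]) == expect_a
        expect_b = set(np.flatnonzero(b > np.percentile(b, 95))) - expect_a
        assert set(reps.rep_indices["tb"]) == expect_b
        assert not set(reps.rep_indices["ta"]) & set(reps.rep_indices["tb"])

    def test_claiming_removes_cells_from_later_types(self):
        s = np.arange(10, dtype=float)
        second = s.copy()
        second[5] = 9.5  # second's gate overlaps first's top cells at index 9
        scores = {"first": s, "second": second}
        cfg = GateConfig(q_high=80.0, q_max=100.0)
        reps = select_representatives(scores, cfg, ["first", "second"],
                                      include_unknown=False)
        assert set(reps.rep_indices["first"]) == {8, 9}
        assert set(reps.rep_indices["second"]) == {5}  # index 9 already claimed

    def test_unknown_is_intersection_of_low_sets(self, rng):
        a = np.concatenate([np.zeros(50), np.linspace(1, 2, 50)])
        b = np.concatenate([np.linspace(1, 2, 50), np.zeros(50)])
        scores = {"ta": a, "tb": b}
        cfg = GateConfig(q_high=90.0, q_max=100.0, q_low=60.0)
        reps = select_representatives(scores, cfg, ["ta", "tb"])
        low_a = set(np.flatnonzero(a < np.percentile(a, 60)))
        low_b = set(np.flatnonzero(b < np.percentile(b, 60)))
        assert set(reps.unknown) <= (low_a & low_b)
        assert len(reps.unknown) > 0

    def test_empty_gate_suggests_lowering_q_high(self):
        scores = {"t": np.zeros(10)}  # all ties: nothing strictly above the percentile
        with pytest.raises(GatingError, match="q_high"):
            select_representatives(scores, GateConfig(), ["t"], include_unknown=False)

    def test_gate_ordering_validated(self):
        with pytest.raises(ValueError, match="q_low < q_high"):
            GateConfig(q_high=40.0, q_low=50.0).validate(["t"])


class TestSeedCentroids:
    def test_singleton_and_mean_oracle(self, rng):
        values = rng.normal(size=(10, 3))
        cents = seed_centroids(values, [np.array([4]), np.array([1, 3, 7])])
        np.testing.assert_array_equal(cents[0], values[4])
        np.testing.assert_allclose(cents[1], values[[1, 3, 7]].mean(axis=0))

    def test_empty_set_errors(self, rng):
        with pytest.raises(GatingError):
            seed_centroids(rng.normal(size=(5, 2)), [np.array([], dtype=int)])


def _lloyd_oracle(values, centroids, max_iter):
    """Textbook Lloyd iteration (independent of the implementation)."""
    cents = centroids.copy()
    labels = None
    for _ in range(max_iter):
        d2 = ((values[:, None, :] - cents[None]) ** 2).sum(axis=2)
        new = d2.argmin(axis=1)
        if labels is not None and (new == labels).all():
            break
        labels = new
        for k in range(len(cents)):
            if (labels == k).any():
                cents[k] = values[labels == k].mean(axis=0)
    return labels, cents


class TestConstrainedKmeans:
    def test_fully_constrained_returns_seeds(self, rng):
        values = rng.normal(size=(12, 2))
        sets = [np.arange(0, 6), np.arange(6, 12)]
        cents = seed_centroids(values, sets)
        state = constrained_kmeans(values, sets, cents)
        assert (state.labels[:6] == 0).all() and (state.labels[6:] == 1).all()
        assert state.n_iter <= 2

    def test_no_representatives_reproduces_lloyd(self, rng):
        values = np.vstack(
            [rng.normal(loc, 0.5, size=(25, 2)) for loc in ([0, 0], [4, 0], [0, 4])]
        )
        init = values[[0, 25, 50]].copy()
        empty = [np.array([], dtype=int)] * 3
        state = constrained_kmeans(values, empty, init.copy(), max_iter=50)
        oracle_labels, oracle_cents = _lloyd_oracle(values, init.copy(), 50)
        np.testing.assert_array_equal(state.labels, oracle_labels)
        np.testing.assert_allclose(state.centroids, oracle_cents, atol=1e-12)

    def test_adversarial_representative_keeps_its_seed_label(self):
        # one pinned point sitting right on the foreign centroid
        values = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 0.0], [5.1, 0.0]])
        sets = [np.array([0, 2]), np.array([3])]  # point 2 pinned to cluster 0
        cents = np.array([[0.0, 0.0], [5.0, 0.0]])
        state = constrained_kmeans(values, sets, cents, max_iter=20)
        assert state.labels[2] == 0  # nearer to cluster 1's centroid, still pinned

    def test_constraint_holds_at_every_iteration(self, rng):
        values = rng.normal(size=(60, 2))
        sets = [np.arange(0, 5), np.arange(30, 35)]
        cents = seed_centroids(values, sets)
        for n_iter in range(1, 8):
            state = constrained_kmeans(values, sets, cents, max_iter=n_iter)
            for k, idx in enumerate(sets):
                assert (state.labels[idx] == k).all()

    def test_objective_non_increasing(self, small_dataset):
        table, spec, _ = small_dataset
        X = unit_normalize(log_pseudocount(table))
        order = abundance_order(X, spec)
        scores = {ct: marker_score(X, spec, ct) for ct in spec.cell_types}
        reps = select_representatives(scores, GateConfig(q_high=97.0), order,
                                      include_unknown=False)
        sets = [reps.rep_indices[ct] for ct in spec.cell_types]
        cents = seed_centroids(X.values, sets)
        state = constrained_kmeans(X.values, sets, cents)
        diffs = np.diff(state.objective_history)
        assert (diffs <= 1e-8).all()

    def test_well_separated_mixture_recovers_types(self):
        cfg = small_config(seed=11, n_rois=2, cells_per_roi=1500)
        table, spec, truth = generate_dataset(cfg)
        X = unit_normalize(log_pseudocount(table))
        order = abundance_order(X, spec)
        scores = {ct: marker_score(X, spec, ct) for ct in spec.cell_types}
        reps = select_representatives(scores, GateConfig(q_high=97.0), order,
                                      include_unknown=False)
        sets = [reps.rep_indices[ct] for ct in spec.cell_types]
        state = constrained_kmeans(X.values, sets, seed_centroids(X.values, sets),
                                   label_names=spec.cell_types)
        labels = state.label_strings()
        pinned = np.zeros(len(labels), dtype=bool)
        for idx in sets:
            pinned[idx] = True
        free = ~pinned
        acc = np.mean(labels[free] == truth.labels[free])
        assert acc >= 0.99

    def test_deterministic(self, rng):
        values = rng.normal(size=(40, 3))
        sets = [np.arange(3), np.arange(20, 23)]
        cents = seed_centroids(values, sets)
        s1 = constrained_kmeans(values, sets, cents)
        s2 = constrained_kmeans(values, sets, cents)
        np.testing.assert_array_equal(s1.labels, s2.labels)
        np.testing.assert_array_equal(s1.centroids, s2.centroids)
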