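import itertools

import numpy as np
import pytest

from conftest import feature_matrix
from ethoproto import (
    cluster_quality,
    leave_out_plan,
    match_distance,
    mean_set,
    restarted_kmeans,
    select_k,
    validation_scan,
)
from ethoproto.io import CentroidSet
from ethoproto.validate import (
    ConditionResult,
    QualityReport,
    StabilityReport,
    ValidationReport,
)


def cs_from(centroids, k=None):
    c = np.atleast_2d(np.asarray(centroids, float))
    k = c.shape[0]
    return CentroidSet(c, np.full(k, 1.0 / k), np.zeros(k), np.zeros_like(c))


class TestLeaveOutPlan:
    def test_fifty_masks_each_keep_ninety_percent(self):
        plan = leave_out_plan(1000, 0.1, 50)
        assert len(plan.masks) == 50
        assert all(len(m) == 900 for m in plan.masks)

    def test_hand_enumeration(self):
        plan = leave_out_plan(10, 0.5, 2)
        np.testing.assert_array_equal(plan.masks[0], [5, 6, 7, 8, 9])
        np.testing.assert_array_equal(plan.masks[1], [0, 1, 2, 3, 4])

    @pytest.mark.parametrize("N", [100, 257, 1000])
    @pytest.mark.parametrize("fraction", [0.1, 0.2, 0.5])
    def test_union_of_kept_indices_is_everything(self, N, fraction):
        plan = leave_out_plan(N, fraction, 50)
        kept = set()
        for m in plan.masks:
            kept.update(m.tolist())
        assert kept == set(range(N))

    def test_wrapping_keeps_mask_size_constant(self):
        plan = leave_out_plan(100, 0.2, 50)
        assert {len(m) for m in plan.masks} == {80}

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            leave_out_plan(100, 1.5)


class TestMatchDistance:
    def test_permutation_gives_zero(self, rng):
        A = cs_from(rng.normal(size=(4, 3)))
        B = cs_from(A.centroids[[2, 0, 3, 1]])
        _, d = match_distance(A, B)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_hand_computation(self):
        A = cs_from([[0.0, 0.0], [1.0, 1.0]])
        B = cs_from([[1.0, 1.0], [0.0, 0.5]])
        matching, d = match_distance(A, B)
        np.testing.assert_array_equal(matching, [1, 0])
        assert d == pytest.approx(0.25 / 4.0, abs=1e-12)  # 0.0625

    def test_matches_exhaustive_permutation_minimum(self, rng):
        for _ in range(5):
            A = cs_from(rng.normal(size=(6, 6)))
            B = cs_from(rng.normal(size=(6, 6)))
            _, d = match_distance(A, B)
            brute = min(
                sum(((A.centroids[i] - B.centroids[p[i]]) ** 2).sum() for i in range(6))
                for p in itertools.permutations(range(6))
            )
            assert d == pytest.approx(brute / 36.0, abs=1e-9)

    def test_pseudometric_properties(self, rng):
        for _ in range(100):
            A, B, C = (cs_from(rng.normal(size=(3, 2))) for _ in range(3))
            _, dab = match_distance(A, B)
            _, dba = match_distance(B, A)
            _, dbc = match_distance(B, C)
            _, dac = match_distance(A, C)
            assert dab == pytest.approx(dba, abs=1e-12)
            assert dab >= 0
            # triangle inequality holds for the matched sqrt-distances; in
            # squared units the standard relaxed form applies
            assert np.sqrt(dac) <= np.sqrt(dab) + np.sqrt(dbc) + 1e-9

    def test_cardinality_mismatch(self, rng):
        with pytest.raises(ValueError, match="cardinality"):
            match_distance(cs_from(rng.normal(size=(2, 2))), cs_from(rng.normal(size=(3, 2))))


class TestMeanSet:
    def test_identical_sets_zero_instability(self, rng):
        A = cs_from(rng.normal(size=(3, 2)))
        rep = mean_set([A, A, A])
        assert rep.instability == pytest.approx(0.0, abs=1e-12)

    def test_hand_example_one_dimensional(self):
        sets = [cs_from([[0.0]]), cs_from([[1.0]]), cs_from([[5.0]])]
        rep = mean_set(sets)
        # squared distances: d(0,1)=1, d(0,5)=25, d(1,5)=16 (k=F=1)
        # mean distances to others: 13, 8.5, 20.5 -> mean set is {1}
        assert rep.mean_set_index == 1
        assert rep.instability == pytest.approx(8.5, abs=1e-12)

    def test_instability_invariant_under_list_permutation(self, rng):
        sets = [cs_from(rng.normal(size=(3, 2))) for _ in range(5)]
        i1 = mean_set(sets).instability
        i2 = mean_set(sets[::-1]).instability
        assert i1 == pytest.approx(i2, abs=1e-12)

    def test_mean_error_definition(self):
        sets = [cs_from([[0.0]]), cs_from([[1.0]]), cs_from([[5.0]])]
        rep = mean_set(sets)
        # sd (ddof=1) of the mean set's distances {1, 16} divided by 3 sets
        expected = np.std([1.0, 16.0], ddof=1) / 3.0
        assert rep.mean_error == pytest.approx(expected, abs=1e-12)

    def test_needs_two_sets(self, rng):
        with pytest.raises(ValueError):
            mean_set([cs_from(rng.normal(size=(2, 2)))])


class TestClusterQuality:
    def test_hand_computation(self):
        fm = feature_matrix([[-1.1], [-0.9], [0.9], [1.1]])
        cs = cs_from([[-1.0], [1.0]])
        q = cluster_quality(fm, cs)
        np.testing.assert_allclose(q.inner, 0.01, atol=1e-12)
        np.testing.assert_allclose(q.outer, 4.0, atol=1e-12)
        np.testing.assert_allclose(q.per_cluster_q, 400.0, atol=1e-9)
        assert q.mean_q == pytest.approx(400.0, abs=1e-9)

    def test_duplicating_data_leaves_quality(self, rng):
        X = rng.normal(size=(40, 2)) + np.repeat([[0, 0], [6, 6]], 20, axis=0)
        cs = cs_from([[0.0, 0.0], [6.0, 6.0]])
        q1 = cluster_quality(feature_matrix(X), cs)
        q2 = cluster_quality(feature_matrix(np.vstack([X, X])), cs)
        np.testing.assert_allclose(q1.per_cluster_q, q2.per_cluster_q, atol=1e-9)

    def test_brute_force_equivalence_on_benchmark(self, artificial):
        fmz, _, _ = artificial
        run = restarted_kmeans(fmz, k=5, n_restarts=5, base_seed=0)
        q = cluster_quality(fmz, run.centroids, run.labels)
        # independent brute force, straight from the definitions
        X, C = fmz.values, run.centroids.centroids
        for j in range(5):
            members = X[run.labels == j]
            inner = np.mean([(p - C[j]) @ (p - C[j]) for p in members])
            outer = min((C[j] - C[i]) @ (C[j] - C[i]) for i in range(5) if i != j)
            assert q.per_cluster_q[j] == pytest.approx(outer / inner, abs=1e-9)

    def test_contracting_a_cluster_raises_its_quality(self, rng):
        X = rng.normal(size=(60, 2)) + np.repeat([[0, 0], [8, 8]], 30, axis=0)
        cs = cs_from([[0.0, 0.0], [8.0, 8.0]])
        labels = np.repeat([0, 1], 30)
        q1 = cluster_quality(feature_matrix(X), cs, labels)
        X2 = X.copy()
        X2[:30] = cs.centroids[0] + 0.5 * (X2[:30] - cs.centroids[0])
        q2 = cluster_quality(feature_matrix(X2), cs, labels)
        assert q2.per_cluster_q[0] > q1.per_cluster_q[0]

    def test_zero_inner_reported_infinite_excluded(self):
        fm = feature_matrix([[0.0], [0.0], [3.0], [5.0]])
        cs = cs_from([[0.0], [4.0]])
        with pytest.warns(UserWarning, match="zero within-cluster"):
            q = cluster_quality(fm, cs, np.array([0, 0, 1, 1]))
        assert np.isinf(q.per_cluster_q[0])
        assert q.mean_q == pytest.approx(q.per_cluster_q[1], abs=1e-12)

    def test_empty_cluster_is_error(self):
        fm = feature_matrix([[0.0], [1.0]])
        cs = cs_from([[0.0], [50.0]])
        with pytest.raises(ValueError, match="empty"):
            cluster_quality(fm, cs, np.array([0, 0]))


def constructed_report(k_values, between_inst, qualities):
    """Minimal ValidationReport for exercising select_k."""
    cells = {}
    between = {}
    for k, bi, q in zip(k_values, between_inst, qualities):
        stab = StabilityReport(np.zeros((2, 2)), 0, bi, 0.0)
        qual = QualityReport(np.full(k, q), np.ones(k), np.full(k, q))
        cs = cs_from(np.zeros((k, 2)))
        cells[(k, "full")] = ConditionResult(stab, cs, qual)
        between[k] = stab
    return ValidationReport(tuple(k_values), ("full",), cells, between)


class TestSelectK:
    def test_single_k(self):
        rep = constructed_report([4], [0.001], [3.0])
        assert select_k(rep) == 4

    def test_unstable_k4_stable_k5_with_top_quality(self):
        # four clusters unstable on reduced data; five stable and best
        rep = constructed_report([3, 4, 5, 6], [0.002, 0.35, 0.003, 0.004], [5.0, 9.0, 7.0, 6.0])
        assert select_k(rep) == 5

    def test_monotone_quality_with_exploding_instability(self):
        rep = constructed_report(
            [2, 4, 6, 8, 10], [0.001, 0.002, 0.4, 0.9, 1.5], [1.0, 2.0, 3.0, 4.0, 5.0]
        )
        assert select_k(rep) == 4

    def test_tie_goes_to_smaller_k(self):
        rep = constructed_report([3, 5], [0.001, 0.001], [2.0, 2.0])
        assert select_k(rep) == 3

    def test_no_admissible_k_is_error(self):
        rep = constructed_report([2, 3], [0.5, 0.9], [1.0, 2.0])
        with pytest.raises(ValueError, match="instabilit"):
            select_k(rep, stability_factor=1.0, stability_floor=0.0, instability_cap=0.1)


@pytest.fixture(scope="module")
def two_blob_scan():
    rng = np.random.default_rng(0)
    pts = np.vstack(
        [rng.normal([0, 0], 0.2, size=(150, 2)), rng.normal([9, 9], 0.2, size=(150, 2))]
    )
    fm = feature_matrix(pts)
    return validation_scan(
        fm, [2], fractions=(0.2,), n_positions=10, n_full_runs=4, restarts=4, seed=3
    )


class TestValidationScan:
    def test_clean_two_cluster_data_is_stable(self, two_blob_scan):
        rep = two_blob_scan
        assert rep.selected_k == 2
        assert rep.instability("full")[0] == pytest.approx(0.0, abs=1e-9)
        assert rep.between_instability()[0] < 1e-3

    def test_report_round_trips_through_json(self, two_blob_scan, tmp_path):
        p = tmp_path / "report.json"
        two_blob_scan.to_json(p)
        back = ValidationReport.from_json(p)
        assert back.k_values == two_blob_scan.k_values
        assert back.selected_k == two_blob_scan.selected_k
        np.testing.assert_allclose(
            back.between_instability(), two_blob_scan.between_instability(), atol=1e-12
        )
        np.testing.assert_allclose(back.mean_quality(), two_blob_scan.mean_quality(), atol=1e-12)

    def test_scan_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        fm = feature_matrix(rng.normal(size=(120, 2)))
        kw = dict(fractions=(0.2,), n_positions=5, n_full_runs=3, restarts=3, seed=11)
        r1 = validation_scan(fm, [2, 3], **kw)
        r2 = validation_scan(fm, [2, 3], **kw)
        np.testing.assert_array_equal(r1.between_instability(), r2.between_instability())
        for key in r1.cells:
            np.testing.assert_array_equal(
                r1.cells[key].mean_centroids.centroids, r2.cells[key].mean_centroids.centroids
            )
        assert r1.selected_k == r2.selected_k
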