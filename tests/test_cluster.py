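"""Logistic boundary, cluster split, and DTN geometry/statistics."""

import math

import numpy as np
import pytest

from fetopulm.cluster import (
    DisplacementRecord,
    ReactivityBoundary,
    assign_clusters,
    compare_dtn,
    compute_dtn,
    displacement_records,
    fit_boundary,
)


def _toy_boundary():
    x = np.array([[2.0, 0.3], [3.0, -0.2], [1.5, 0.1], [2.5, 0.0],
                  [-2.0, 0.2], [-3.0, -0.1], [-1.5, 0.0], [-2.5, 0.3]])
    y = np.array(["control"] * 4 + ["FGR"] * 4)
    return fit_boundary(x, y), x, y


class TestBoundary:
    def test_separable_toy_has_perfect_accuracy(self):
        model, x, y = _toy_boundary()
        assert model.accuracy_ == 1.0
        assert np.all(model.predict(x[:4]) == "A")
        assert np.all(model.predict(x[4:]) == "B")

    def test_symmetric_classes_give_axis_boundary_through_origin(self):
        """Classes at +-(1, 0): the likelihood is symmetric, so the boundary
        passes through the origin with its normal along the first axis."""
        rng = np.random.default_rng(0)
        base = rng.normal(0, 0.2, (40, 2))
        x = np.vstack([base + [1.0, 0.0], -base - [1.0, 0.0]])
        y = np.array(["control"] * 40 + ["FGR"] * 40)
        model = fit_boundary(x, y)
        assert abs(model.intercept_) < 1e-6
        assert abs(model.normal_[0]) > 0.999
        assert model.normal_[0] > 0  # controls-positive orientation

    def test_label_swap_restores_orientation(self):
        model, x, y = _toy_boundary()
        y_swapped = np.where(y == "control", "FGR", "control")
        # now FGR sits on the positive x side; orientation convention must
        # still put the *controls'* mean score positive
        swapped = fit_boundary(x, y_swapped)
        assert np.mean(x[y_swapped == "control"] @ swapped.coef_
                       + swapped.intercept_) > 0
        assert np.dot(swapped.normal_, model.normal_) < 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            fit_boundary(np.random.default_rng(0).normal(size=(10, 2)),
                         np.array(["control"] * 10))

    def test_tie_scores_assigned_to_cluster_a(self):
        # a model whose boundary passes exactly through x1 = 0: a point with
        # score exactly zero falls in cluster A by the documented convention
        model, _, _ = _toy_boundary()
        model.coef_ = np.array([1.0, 0.0])
        model.intercept_ = 0.0
        model.normal_ = model.coef_
        tie_point = np.array([[0.0, 3.7]])
        assert model.decision_function(tie_point)[0] == 0.0
        assert assign_clusters(tie_point, model)[0] == "A"

    def test_dimension_mismatch_rejected(self):
        model, _, _ = _toy_boundary()
        with pytest.raises(ValueError, match="dimension"):
            model.decision_function(np.ones((3, 5)))
        with pytest.raises(ValueError, match="dimension"):
            model.dtn(np.zeros(3), np.ones(3))


class TestDTNGeometry:
    def test_zero_displacement_zero_dtn(self):
        model, x, _ = _toy_boundary()
        assert compute_dtn(x[0], x[0], model) == 0.0

    def test_unit_normal_displacement_gives_one(self):
        model, x, _ = _toy_boundary()
        assert compute_dtn(x[4], x[4] + model.normal_, model) == pytest.approx(1.0)

    def test_orthogonal_displacement_gives_zero(self):
        model, x, _ = _toy_boundary()
        tangent = np.array([-model.normal_[1], model.normal_[0]])
        assert compute_dtn(x[4], x[4] + 3.0 * tangent, model) == pytest.approx(
            0.0, abs=1e-12)

    def test_invariant_under_weight_rescaling(self):
        model, x, _ = _toy_boundary()
        d0 = compute_dtn(x[4], x[0], model)
        model.coef_ = 7.3 * model.coef_
        model.normal_ = model.coef_ / np.linalg.norm(model.coef_)
        assert compute_dtn(x[4], x[0], model) == pytest.approx(d0, rel=1e-12)

    def test_pythagorean_decomposition(self, rng):
        model, x, _ = _toy_boundary()
        base = rng.normal(size=(20, 2))
        mhox = rng.normal(size=(20, 2))
        recs = displacement_records([f"s{i}" for i in range(20)], base, mhox, model)
        for r in recs:
            total = float(r.displacement @ r.displacement)
            assert r.dtn ** 2 + r.tangential_norm() ** 2 == pytest.approx(
                total, rel=1e-9)
            assert abs(r.dtn) <= math.sqrt(total) + 1e-12


class TestCompareDTN:
    def _records(self, dtn_a, dtn_b):
        recs = [DisplacementRecord(f"a{i}", np.zeros(2), v, "A")
                for i, v in enumerate(dtn_a)]
        recs += [DisplacementRecord(f"b{i}", np.zeros(2), v, "B")
                 for i, v in enumerate(dtn_b)]
        return recs

    def test_reports_medians_and_iqr(self, rng):
        recs = self._records(rng.normal(size=30), rng.normal(1.0, 1.0, 30))
        out = compare_dtn(recs)
        assert out["clusters"]["A"]["n"] == 30
        q1, q3 = out["clusters"]["B"]["iqr"]
        assert q1 <= out["clusters"]["B"]["median"] <= q3

    def test_null_calibration(self):
        """Same-distribution clusters (n=30 each): p > 0.05 in >= 90% of
        100 seeded replicates."""
        rng = np.random.default_rng(123)
        not_significant = 0
        for _ in range(100):
            recs = self._records(rng.normal(size=30), rng.normal(size=30))
            if compare_dtn(recs)["p_value"] > 0.05:
                not_significant += 1
        assert not_significant >= 90

    def test_power_for_one_sd_shift(self):
        """Cluster B shifted by +1 SD (n=30/arm): the comparison is almost
        always significant at the 1% level.  The asymptotic power of the
        rank-sum test at this design is ~0.89, so the bound reflects that."""
        rng = np.random.default_rng(321)
        significant = 0
        for _ in range(100):
            recs = self._records(rng.normal(size=30), rng.normal(1.0, 1.0, 30))
            if compare_dtn(recs)["p_value"] < 0.01:
                significant += 1
        assert significant >= 85

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compare_dtn(self._records([0.1, 0.2], []))

    def test_unknown_cluster_label_rejected(self):
        recs = [DisplacementRecord("x", np.zeros(2), 0.0, "C")]
        with pytest.raises(ValueError, match="unknown cluster"):
            compare_dtn(recs)
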