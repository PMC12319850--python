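"""Tests for AIRM/LEM geometry and the rMDM/rSVM proxy classifiers."""

import numpy as np
import pytest

from eegspd.core_spd import expm_spd, logeig_map, vect
from eegspd.metrics import (
    FrechetMeanError,
    RMDMClassifier,
    distance,
    frechet_mean,
    rmdm_fit_predict,
    rsvm_fit_predict,
    tangent_project,
)
from sklearn.svm import SVC


def _spd(rng, n, scale=1.0):
    A = rng.normal(size=(n, n))
    return scale * (A @ A.T + n * np.eye(n))


class TestDistance:
    @pytest.mark.parametrize("metric", ["AIRM", "LEM"])
    def test_identity_of_indiscernibles(self, rng, metric):
        S = _spd(rng, 4)
        assert distance(S, S, metric) == pytest.approx(0.0, abs=1e-9)

    def test_lem_diagonal_closed_form(self):
        assert distance(np.eye(2), np.e * np.eye(2), "LEM") == pytest.approx(np.sqrt(2.0))

    def test_airm_affine_invariance(self, rng):
        S1, S2 = _spd(rng, 4), _spd(rng, 4)
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)  # invertible
        d0 = distance(S1, S2, "AIRM")
        d1 = distance(A @ S1 @ A.T, A @ S2 @ A.T, "AIRM")
        assert d1 == pytest.approx(d0, rel=1e-8)

    @pytest.mark.parametrize("metric", ["AIRM", "LEM"])
    def test_symmetry_and_triangle_inequality(self, rng, metric):
        mats = [_spd(rng, 3) for _ in range(3)]
        d01 = distance(mats[0], mats[1], metric)
        d10 = distance(mats[1], mats[0], metric)
        assert d01 == pytest.approx(d10, rel=1e-8)
        d02 = distance(mats[0], mats[2], metric)
        d12 = distance(mats[1], mats[2], metric)
        assert d02 <= d01 + d12 + 1e-8

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            distance(_spd(rng, 3), _spd(rng, 4))


class TestFrechetMean:
    @pytest.mark.parametrize("metric", ["AIRM", "LEM"])
    def test_mean_of_repeated_matrix_is_itself(self, rng, metric):
        S = _spd(rng, 3)
        M = frechet_mean([S, S], metric)
        assert np.allclose(M, S, rtol=1e-7)

    @pytest.mark.parametrize("metric", ["AIRM", "LEM"])
    def test_commuting_pair_geodesic_midpoint(self, metric):
        M = frechet_mean([np.eye(2), np.e**2 * np.eye(2)], metric)
        assert np.allclose(M, np.e * np.eye(2), rtol=1e-7)

    def test_airm_karcher_stationarity(self, rng):
        mats = [_spd(rng, 4) for _ in range(6)]
        M = frechet_mean(mats, "AIRM")
        w, U = np.linalg.eigh(M)
        isq = (U * w**-0.5) @ U.T
        residual = np.mean([logeig_map(isq @ S @ isq) for S in mats], axis=0)
        assert np.linalg.norm(residual) < 1e-6

    def test_airm_equals_lem_for_commuting_family(self, rng):
        d = rng.uniform(0.5, 2.0, size=(5, 3))
        mats = [np.diag(x) for x in d]
        assert np.allclose(
            frechet_mean(mats, "AIRM"), frechet_mean(mats, "LEM"), rtol=1e-8
        )

    def test_nonconvergence_carries_last_iterate(self, rng):
        mats = [_spd(rng, 3) for _ in range(4)]
        with pytest.raises(FrechetMeanError) as exc:
            frechet_mean(mats, "AIRM", tol=1e-30, max_iter=2)
        assert exc.value.last_iterate.shape == (3, 3)
        assert np.isfinite(exc.value.residual)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            frechet_mean([], "LEM")


class TestTangentProject:
    def test_airm_at_identity_is_plain_log(self, rng):
        S = _spd(rng, 3)
        ts = tangent_project([S], "AIRM", reference=np.eye(3))
        assert np.allclose(ts.vectors[0], vect(logeig_map(S)))

    def test_lem_projection_of_identity_is_zero(self):
        ts = tangent_project([np.eye(4)], "LEM")
        assert np.allclose(ts.vectors, 0.0)

    def test_airm_isometry_at_reference(self, rng):
        R = _spd(rng, 4)
        S = _spd(rng, 4)
        ts = tangent_project([S], "AIRM", reference=R)
        assert np.linalg.norm(ts.vectors[0]) == pytest.approx(
            distance(S, R, "AIRM"), rel=1e-8
        )


class TestRMDM:
    def test_perfect_self_assignment(self, rng):
        mats = [_spd(rng, 3, scale=s) for s in (1.0, 10.0)]
        y = np.array([0, 1])
        pred = rmdm_fit_predict(mats, y, mats, metric="LEM")
        assert np.array_equal(pred, y)

    def test_lem_equals_euclidean_mdm_in_log_domain(self, rng):
        mats = [_spd(rng, 3) for _ in range(8)]
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        test = [_spd(rng, 3) for _ in range(6)]
        pred = rmdm_fit_predict(mats, y, test, metric="LEM")
        # independent oracle: Euclidean nearest-mean on matrix logarithms
        logs = np.stack([logeig_map(S) for S in mats])
        means = [logs[y == c].mean(axis=0) for c in (0, 1)]
        expected = [
            int(np.argmin([np.linalg.norm(logeig_map(S) - m) for m in means]))
            for S in test
        ]
        assert np.array_equal(pred, expected)

    def test_tie_breaks_to_lowest_class_index(self):
        clf = RMDMClassifier(metric="LEM")
        clf.fit([np.eye(2), np.eye(2)], np.array([0, 1]))  # identical class means
        assert np.array_equal(clf.predict([2.0 * np.eye(2)]), [0])

    def test_congruence_invariance_of_airm_decision(self, rng):
        mats = [_spd(rng, 3, s) for s in (0.5, 0.6, 3.0, 3.5)]
        y = np.array([0, 0, 1, 1])
        test = [_spd(rng, 3) for _ in range(4)]
        pred = rmdm_fit_predict(mats, y, test, metric="AIRM")
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        cong = lambda S: A @ S @ A.T
        pred_t = rmdm_fit_predict(
            [cong(S) for S in mats], y, [cong(S) for S in test], metric="AIRM"
        )
        assert np.array_equal(pred, pred_t)

    def test_empty_training_set_rejected(self):
        clf = RMDMClassifier()
        with pytest.raises(ValueError):
            clf.fit([], np.array([]))


class TestRSVM:
    def _two_class_set(self, rng, n_per=10):
        a = [_spd(rng, 3, scale=1.0) for _ in range(n_per)]
        b = [_spd(rng, 3, scale=8.0) for _ in range(n_per)]
        y = np.array([0] * n_per + [1] * n_per)
        return a + b, y

    def test_separable_classes_fit_perfectly(self, rng):
        mats, y = self._two_class_set(rng)
        pred = rsvm_fit_predict(mats, y, mats, metric="LEM")
        assert np.mean(pred == y) == 1.0

    def test_lem_equals_plain_svm_on_log_vectors(self, rng):
        mats, y = self._two_class_set(rng, n_per=6)
        test = [_spd(rng, 3, 2.0) for _ in range(5)]
        pred = rsvm_fit_predict(mats, y, test, metric="LEM")
        X = np.stack([vect(logeig_map(S)) for S in mats])
        Xt = np.stack([vect(logeig_map(S)) for S in test])
        ref = SVC(kernel="linear", C=1.0).fit(X, y).predict(Xt)
        assert np.array_equal(pred, ref)

    def test_deterministic_across_runs(self, rng):
        mats, y = self._two_class_set(rng, n_per=6)
        p1 = rsvm_fit_predict(mats, y, mats, metric="AIRM")
        p2 = rsvm_fit_predict(mats, y, mats, metric="AIRM")
        assert np.array_equal(p1, p2)

    def test_single_class_training_rejected(self, rng):
        mats = [_spd(rng, 2) for _ in range(4)]
        with pytest.raises(ValueError):
            rsvm_fit_predict(mats, np.zeros(4, dtype=int), mats)


def test_predictions_csv_round_trip(tmp_path):
    import pandas as pd

    from eegspd.metrics import write_predictions_csv

    path = tmp_path / "pred.csv"
    write_predictions_csv(path, [0, 1, 1], [0, 1, 0])
    table = pd.read_csv(path)
    assert list(table.columns) == ["sample", "true", "predicted"]
    assert table["predicted"].tolist() == [0, 1, 0]
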