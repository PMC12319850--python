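"""Riemannian geometry on the SPD manifold and the two proxy classifiers.

Implements the affine-invariant (AIRM) and log-Euclidean (LEM) metrics:
geodesic distances, Fréchet means, tangent-space projection, and on top of
them the minimum-distance-to-Riemannian-mean classifier (rMDM) and the
tangent-space SVM (rSVM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .core_spd import check_symmetric, expm_spd, logeig_map, sym, vect

__all__ = [
    "METRICS",
    "FrechetMeanError",
    "distance",
    "frechet_mean",
    "tangent_project",
    "TangentVectorSet",
    "RMDMClassifier",
    "RSVMClassifier",
    "rmdm_fit_predict",
    "rsvm_fit_predict",
]

METRICS = ("AIRM", "LEM")


class FrechetMeanError(RuntimeError):
    """AIRM mean iteration failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: np.ndarray, residual: float):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.residual = residual


def _check_metric(metric: str) -> str:
    m = metric.upper()
    if m not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    return m


def _eigh_pd(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    S = check_symmetric(S)
    w, U = np.linalg.eigh(S)
    if np.any(w <= 0):
        raise ValueError(f"matrix not strictly PD (min eigenvalue {w.min():.3e})")
    return w, U

def _invsqrtm(S: np.ndarray) -> np.ndarray:
    w, U = _eigh_pd(S)
    return sym((U * (w ** -0.5)) @ U.T)

def _sqrtm(S: np.ndarray) -> np.ndarray:
    w, U = _eigh_pd(S)
    return sym((U * (w ** 0.5)) @ U.T)


def distance(S1: np.ndarray, S2: np.ndarray, metric: str = "AIRM") -> float:
    """Geodesic distance between two SPD matrices.

    AIRM: ``||logm(S1^{-1/2} S2 S1^{-1/2})||_F`` — invariant under any joint
    congruence ``S -> A S A^T``.  LEM: ``||logm S1 - logm S2||_F``.
    """
    metric = _check_metric(metric)
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    if S1.shape != S2.shape:
        raise ValueError(f"dimension mismatch: {S1.shape} vs {S2.shape}")
    if metric == "LEM":
        return float(np.linalg.norm(logeig_map(S1) - logeig_map(S2)))
    isq = _invsqrtm(S1)
    return float(np.linalg.norm(logeig_map(sym(isq @ S2 @ isq))))


def frechet_mean(
    mats: list[np.ndarray] | np.ndarray,
    metric: str = "AIRM",
    tol: float = 1e-9,
    max_iter: int = 200,
) -> np.ndarray:
    """Fréchet (geometric) mean of a set of SPD matrices.

    LEM has the closed form ``expm(mean(logm Si))``.  The AIRM (Karcher)
    mean is found by manifold gradient descent with step halving on
    divergence, iterated until the mean tangent displacement drops below
    ``tol`` (Frobenius norm) or ``max_iter`` is hit.
    """
    metric = _check_metric(metric)
    mats = [np.asarray(S, dtype=float) for S in mats]
    if len(mats) == 0:
        raise ValueError("cannot average an empty set")
    if metric == "LEM":
        return expm_spd(np.mean([logeig_map(S) for S in mats], axis=0))

    M = sym(np.mean(mats, axis=0))  # arithmetic init
    step = 1.0
    prev_res = np.inf
    for _ in range(max_iter):
        isq, sq = _invsqrtm(M), _sqrtm(M)
        T = np.mean([logeig_map(sym(isq @ S @ isq)) for S in mats], axis=0)
        res = float(np.linalg.norm(T))
        if res < tol:
            return M
        if res > prev_res:
            step = max(step * 0.5, 1e-4)
        prev_res = res
        M = sym(sq @ expm_spd(step * T) @ sq)
    raise FrechetMeanError(
        f"AIRM mean did not converge in {max_iter} iterations (residual {prev_res:.3e})",
        last_iterate=M,
        residual=prev_res,
    )


@dataclass
class TangentVectorSet:
    """Tangent-space coordinates of a set of SPD matrices.

    ``vectors`` is (n_samples, n(n+1)/2); ``reference`` the base point the
    projection was taken at (identity for LEM, typically the training
    Fréchet mean for AIRM).
    """

    vectors: np.ndarray
    reference: np.ndarray
    metric: str


def tangent_project(
    mats: list[np.ndarray] | np.ndarray,
    metric: str = "LEM",
    reference: np.ndarray | str = "auto",
) -> TangentVectorSet:
    """Project SPD matrices to tangent-space vectors.

    LEM is reference-free: ``vect(logm S)``.  AIRM whitens by the reference
    first: ``vect(logm(R^{-1/2} S R^{-1/2}))``, with ``R`` the AIRM Fréchet
    mean of the set when ``reference="auto"``.  At the reference point the
    vector norm equals the geodesic distance to the reference.
    """
    metric = _check_metric(metric)
    mats = [np.asarray(S, dtype=float) for S in mats]
    n = mats[0].shape[0]
    if metric == "LEM":
        ref = np.eye(n)
        vecs = np.stack([vect(logeig_map(S)) for S in mats])
        return TangentVectorSet(vecs, ref, metric)
    if isinstance(reference, str):
        if reference != "auto":
            raise ValueError(f"unknown reference {reference!r}")
        ref = frechet_mean(mats, metric="AIRM")
    else:
        ref = np.asarray(reference, dtype=float)
    isq = _invsqrtm(ref)
    vecs = np.stack([vect(logeig_map(sym(isq @ S @ isq))) for S in mats])
    return TangentVectorSet(vecs, ref, metric)


class RMDMClassifier:
    """Minimum distance to Riemannian mean.

    Fits one Fréchet mean per class and assigns each test matrix to the
    class of the nearest mean under the chosen metric.  Ties break toward
    the lowest class index.  Deterministic.
    """

    def __init__(self, metric: str = "LEM"):
        self.metric = _check_metric(metric)
        self.classes_: np.ndarray | None = None
        self.means_: list[np.ndarray] = []

    def fit(self, mats: list[np.ndarray] | np.ndarray, y: np.ndarray) -> "RMDMClassifier":
        mats = [np.asarray(S, dtype=float) for S in mats]
        y = np.asarray(y)
        if len(mats) != len(y):
            raise ValueError("label count does not match matrix count")
        if len(mats) == 0:
            raise ValueError("training set is empty")
        self.classes_ = np.unique(y)
        self.means_ = []
        for c in self.classes_:
            members = [S for S, lab in zip(mats, y) if lab == c]
            if not members:
                raise ValueError(f"class {c} has no training samples")
            self.means_.append(frechet_mean(members, metric=self.metric))
        return self

    def predict(self, mats: list[np.ndarray] | np.ndarray) -> np.ndarray:
        if self.classes_ is None:
            raise RuntimeError("classifier is not fitted")
        d = np.array(
            [[distance(S, M, self.metric) for M in self.means_] for S in mats]
        )
        # argmin returns the first (lowest-index) class on exact ties
        return self.classes_[np.argmin(d, axis=1)]


class RSVMClassifier:
    """Tangent-space SVM: Riemannian projection followed by a linear SVM.

    The AIRM reference is estimated from the training set only, so test
    data never leaks into the projection.  Feature standardisation is off
    by default (flag provided).
    """

    def __init__(self, metric: str = "LEM", C: float = 1.0, standardize: bool = False):
        self.metric = _check_metric(metric)
        self.C = float(C)
        self.standardize = bool(standardize)
        self._svm: SVC | None = None
        self._ref: np.ndarray | None = None
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    def fit(self, mats, y) -> "RSVMClassifier":
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("rSVM needs at least two classes in training data")
        ts = tangent_project(mats, metric=self.metric, reference="auto")
        self._ref = ts.reference
        X = ts.vectors
        if self.standardize:
            self._mu = X.mean(axis=0)
            self._sd = X.std(axis=0) + 1e-12
            X = (X - self._mu) / self._sd
        self._svm = SVC(kernel="linear", C=self.C)
        self._svm.fit(X, y)
        return self

    def predict(self, mats) -> np.ndarray:
        if self._svm is None:
            raise RuntimeError("classifier is not fitted")
        ts = tangent_project(mats, metric=self.metric, reference=self._ref)
        X = ts.vectors
        if self.standardize:
            X = (X - self._mu) / self._sd
        return self._svm.predict(X)


def rmdm_fit_predict(train_mats, train_y, test_mats, metric: str = "LEM") -> np.ndarray:
    """One-shot rMDM: fit per-class means on train, label the test set."""
    return RMDMClassifier(metric=metric).fit(train_mats, train_y).predict(test_mats)


def rsvm_fit_predict(
    train_mats, train_y, test_mats, metric: str = "LEM", C: float = 1.0,
    standardize: bool = False,
) -> np.ndarray:
    """One-shot rSVM: tangent projection (train-derived reference) + linear SVM."""
    clf = RSVMClassifier(metric=metric, C=C, standardize=standardize)
    return clf.fit(train_mats, train_y).predict(test_mats)


def write_predictions_csv(path, y_true, y_pred) -> None:
    """Write classifier results as a CSV table (sample id, true, predicted)."""
    import pandas as pd

    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label vectors differ in length")
    pd.DataFrame(
        {"sample": np.arange(len(y_true)), "true": y_true, "predicted": y_pred}
    ).to_csv(path, index=False)
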