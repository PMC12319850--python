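"""Black-box filterbank optimisation (the FB-Opt stage).

Searches the space of sinc bandpass cutoff pairs for the filterbank that
maximises cross-validated accuracy of a lightweight proxy classifier
(rMDM or rSVM) on the pooled covariance matrices of the *training* set
only.  The optimisation engine is a small sequential model-based sampler
behind a propose/observe interface, so any black-box engine can be swapped
in: after a random start-up phase, candidates are drawn from a kernel
density fit to the better-scoring half-space and ranked by a
good-to-rest density ratio (a TPE-style acquisition).

The search space is parameterised per filter as (low cutoff, bandwidth)
with bandwidth >= 1 Hz, so no proposal can violate ``low < high``.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.model_selection import StratifiedKFold

from .data import TrialSet
from .filterbank import FilterbankSpec, default_kernel_len, filterbank_forward, scm_pool
from .metrics import rmdm_fit_predict, rsvm_fit_predict

__all__ = ["SearchConfig", "SearchResult", "objective", "search", "coverage_spectrum"]


@dataclass
class SearchConfig:
    """Budget and scoring configuration of a filterbank search."""

    Nf: int = 1
    specificity: Literal["ChInd", "ChSpec"] = "ChInd"
    metric: str = "LEM"
    proxy: Literal["rMDM", "rSVM"] = "rMDM"
    max_trials: int = 100
    max_walltime: float = float("inf")  # seconds
    cv_folds: int = 5
    keep_interband: bool = False  # ChInd pools per-band covariances block-diagonally
    kernel_len: int | None = None
    min_bandwidth: float = 1.0  # Hz
    n_startup: int = 10
    n_candidates: int = 24
    gamma: float = 0.25  # fraction of trials treated as "good" by the sampler
    explore_prob: float = 0.25  # chance of a uniform proposal after start-up
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.proxy not in ("rMDM", "rSVM"):
            raise ValueError(f"proxy must be rMDM or rSVM, got {self.proxy!r}")


@dataclass
class SearchResult:
    """Best filterbank found plus the full (spec, score) trial log."""

    best_spec: FilterbankSpec
    best_cv_accuracy: float
    trial_log: list[tuple[FilterbankSpec, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "best_spec": self.best_spec.to_json(),
            "best_cv_accuracy": self.best_cv_accuracy,
            "trial_log": [
                {"spec": s.to_json(), "score": sc} for s, sc in self.trial_log
            ],
        }


def _n_units(config: SearchConfig, Ne: int) -> int:
    return config.Nf if config.specificity == "ChInd" else config.Nf * Ne


def objective(spec: FilterbankSpec, train: TrialSet, config: SearchConfig) -> float:
    """Cross-validated proxy-classifier accuracy (percent) of one filterbank.

    Filters every trial with the static sinc kernels, pools the covariance
    (block-diagonal concatenation across bands for ChInd without
    interband), and scores a stratified k-fold CV with the configured
    proxy.  Deterministic given the seed; invariant to trial order because
    the folds shuffle internally with that seed.
    """
    if spec.kind != "sinc":
        raise ValueError("FB-Opt searches sinc filterbanks only")
    keep = config.keep_interband or config.specificity == "ChSpec"
    mats = np.stack(
        [scm_pool(filterbank_forward(x, spec), keep_interband=keep) for x in train.X]
    )
    y = train.y
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    accs = []
    for tr_idx, te_idx in skf.split(np.zeros(len(y)), y):
        if np.unique(y[tr_idx]).size < np.unique(y).size:
            raise ValueError("a CV fold is missing a class; reduce cv_folds")
        if config.proxy == "rMDM":
            pred = rmdm_fit_predict(mats[tr_idx], y[tr_idx], mats[te_idx], metric=config.metric)
        else:
            pred = rsvm_fit_predict(mats[tr_idx], y[tr_idx], mats[te_idx], metric=config.metric)
        accs.append(np.mean(pred == y[te_idx]))
    return 100.0 * float(np.mean(accs))


def _params_to_spec(theta: np.ndarray, config: SearchConfig, fs: float) -> FilterbankSpec:
    """(n_units, 2) array of (low, bandwidth) -> a sinc FilterbankSpec."""
    nyq = fs / 2.0
    cutoffs = []
    for low, band in theta:
        lo = float(np.clip(low, 0.0, nyq - config.min_bandwidth - 0.1))
        hi = float(np.clip(lo + max(band, config.min_bandwidth), lo + config.min_bandwidth, nyq - 1e-6))
        cutoffs.append((lo, hi))
    klen = config.kernel_len or default_kernel_len(fs)
    return FilterbankSpec(
        kind="sinc", Nf=config.Nf, specificity=config.specificity, fs=fs,
        kernel_len=klen, cutoffs=cutoffs,
    )


class _TPESampler:
    """Minimal independent-dimension TPE-style propose/observe engine."""

    def __init__(self, bounds: np.ndarray, config: SearchConfig, rng: np.random.Generator):
        self.bounds = bounds  # (d, 2)
        self.cfg = config
        self.rng = rng
        self.X: list[np.ndarray] = []
        self.y: list[float] = []

    def _uniform(self) -> np.ndarray:
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return self.rng.uniform(lo, hi)

    def propose(self) -> np.ndarray:
        if len(self.y) < self.cfg.n_startup:
            return self._uniform()
        # keep a floor of pure exploration so the sampler cannot lock onto
        # an early local optimum (the density model is per-dimension only)
        if self.rng.uniform() < self.cfg.explore_prob:
            return self._uniform()
        X = np.asarray(self.X)
        y = np.asarray(self.y)
        n_good = max(2, int(np.ceil(self.cfg.gamma * len(y))))
        order = np.argsort(-y)  # maximise
        good, rest = X[order[:n_good]], X[order[n_good:]]
        if len(rest) < 2:
            return self._uniform()
        cands = np.empty((self.cfg.n_candidates, X.shape[1]))
        score = np.zeros(self.cfg.n_candidates)
        for j in range(X.shape[1]):
            g = good[:, j] + self.rng.normal(0, 1e-6, len(good))  # avoid singular KDE
            r = rest[:, j] + self.rng.normal(0, 1e-6, len(rest))
            try:
                kg, kr = gaussian_kde(g), gaussian_kde(r)
            except np.linalg.LinAlgError:
                cands[:, j] = self.rng.uniform(self.bounds[j, 0], self.bounds[j, 1], len(cands))
                continue
            c = kg.resample(len(cands), seed=self.rng).ravel()
            c = np.clip(c, self.bounds[j, 0], self.bounds[j, 1])
            cands[:, j] = c
            score += np.log(kg(c) + 1e-300) - np.log(kr(c) + 1e-300)
        return cands[int(np.argmax(score))]

    def observe(self, theta: np.ndarray, value: float) -> None:
        self.X.append(np.asarray(theta, dtype=float))
        self.y.append(float(value))


def search(train: TrialSet, config: SearchConfig) -> SearchResult:
    """Budgeted filterbank search on the training set only.

    Stops at ``max_trials`` evaluations or when ``max_walltime`` seconds
    have elapsed (a started evaluation always completes and is logged).
    """
    if config.specificity == "ChSpec" and config.Nf * train.n_electrodes > 16:
        warnings.warn(
            "ChSpec at high Nf creates a large search space; sequential "
            "model-based optimisers degrade toward random search here",
            stacklevel=2,
        )
    fs = train.fs
    nyq = fs / 2.0
    d = _n_units(config, train.n_electrodes)
    bounds = np.tile(
        np.array([[0.5, nyq - config.min_bandwidth - 1.0],
                  [config.min_bandwidth, nyq / 2.0]]),
        (d, 1),
    )
    rng = np.random.default_rng(config.seed)
    sampler = _TPESampler(bounds, config, rng)
    log: list[tuple[FilterbankSpec, float]] = []
    t0 = time.monotonic()
    for _ in range(config.max_trials):
        if time.monotonic() - t0 > config.max_walltime and log:
            break
        theta = sampler.propose()
        spec = _params_to_spec(theta.reshape(d, 2), config, fs)
        score = objective(spec, train, config)
        sampler.observe(theta, score)
        log.append((spec, score))
    if not log:
        raise RuntimeError("walltime budget expired before any trial completed")
    scores = [s for _, s in log]
    best = int(np.argmax(scores))
    return SearchResult(best_spec=log[best][0], best_cv_accuracy=scores[best], trial_log=log)


def coverage_spectrum(
    specs: list[FilterbankSpec], grid: np.ndarray
) -> np.ndarray:
    """Percent of all bandpass filters whose [low, high] interval covers each frequency.

    Pools every cutoff pair across all given specs (all models,
    participants, and — for ChSpec — electrodes), so 75% at 30 Hz means
    three out of four filters pass 30 Hz.
    """
    if not specs:
        raise ValueError("coverage_spectrum needs at least one spec")
    pairs = []
    for s in specs:
        if s.kind != "sinc" or not s.cutoffs:
            raise ValueError("coverage is defined for sinc specs with cutoffs")
        pairs.extend(s.cutoffs)
    grid = np.asarray(grid, dtype=float)
    pairs_arr = np.asarray(pairs)
    inside = (grid[None, :] >= pairs_arr[:, 0:1]) & (grid[None, :] <= pairs_arr[:, 1:2])
    return 100.0 * inside.mean(axis=0)
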