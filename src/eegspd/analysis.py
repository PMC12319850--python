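"""Post-hoc analyses of trained networks.

Covers the six analyses used to interpret the models: frequency gain of
the learned filterbank, peak counting for multiband detection,
layer-by-layer probe classification, the eigenvalue/ReEig-threshold audit,
first-BiMap gain aggregation, and gradient-based electrode-frequency
relevance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, welch

from .core_spd import regularize, vect
from .metrics import RSVMClassifier
from .model import EEGSPDNet
from sklearn.svm import SVC

__all__ = [
    "GainSpectrum",
    "frequency_gain",
    "count_peaks",
    "layer_by_layer",
    "eig_below_threshold",
    "bimap_gain",
    "electrode_frequency_relevance",
]


@dataclass
class GainSpectrum:
    """Frequency gain of one filter unit, in dB relative to the input.

    Positive values are amplification, negative attenuation.  Bins whose
    post-filter amplitude vanished (gain -inf) are linearly interpolated
    over log-gain and flagged; a spectrum with more than half its bins at
    -inf is discarded outright and carries no gain values.
    """

    freqs: np.ndarray
    gain_db: np.ndarray | None
    interpolated: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    discarded: bool = False
    band: int = 0
    electrode: int | None = None  # None for ChInd (unit shared across electrodes)


def _interp_neg_inf(gain: np.ndarray) -> tuple[np.ndarray | None, np.ndarray]:
    """Linearly interpolate -inf bins; None if more than 50% are -inf."""
    bad = ~np.isfinite(gain)
    if bad.mean() > 0.5:
        return None, bad
    if bad.any():
        x = np.arange(gain.size)
        gain = gain.copy()
        gain[bad] = np.interp(x[bad], x[~bad], gain[~bad])
    return gain, bad


def frequency_gain(
    model: EEGSPDNet, X: np.ndarray, nperseg: int | None = None
) -> list[GainSpectrum]:
    """Gain spectra of every filter unit of a (trained) network.

    Welch averaged-periodogram amplitude spectra (half-overlapping
    segments) are computed before and after the filterbank, averaged over
    trials (and over electrodes for channel-independent filters), and the
    gain is ``20*log10(post/pre)`` per frequency bin.  An all-zero input
    yields all-discarded spectra rather than an exception.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    cfg = model.config
    fs = cfg.fs
    Y = model.filterbank.forward(X)  # (B, Nf*Ne, Nt')
    nps = nperseg or min(256, Y.shape[-1])
    f, p_pre = welch(X, fs=fs, nperseg=nps, noverlap=nps // 2, axis=-1)
    _, p_post = welch(Y, fs=fs, nperseg=nps, noverlap=nps // 2, axis=-1)
    amp_pre = np.sqrt(p_pre).mean(axis=0)  # (Ne, n_freqs)
    amp_post = np.sqrt(p_post).mean(axis=0)  # (Nf*Ne, n_freqs)

    out: list[GainSpectrum] = []
    with np.errstate(divide="ignore", invalid="ignore"):
        for u in range(cfg.Nf * cfg.Ne if cfg.specificity == "ChSpec" else cfg.Nf):
            if cfg.specificity == "ChSpec":
                band, elec = divmod(u, cfg.Ne)
                post = amp_post[band * cfg.Ne + elec]
                pre = amp_pre[elec]
            else:
                band, elec = u, None
                post = amp_post[band * cfg.Ne : (band + 1) * cfg.Ne].mean(axis=0)
                pre = amp_pre.mean(axis=0)
            gain = 20.0 * np.log10(post / pre)
            gain = np.where(np.isnan(gain), -np.inf, gain)
            interp, bad = _interp_neg_inf(gain)
            out.append(
                GainSpectrum(
                    freqs=f, gain_db=interp, interpolated=bad,
                    discarded=interp is None, band=band, electrode=elec,
                )
            )
    return out


def count_peaks(
    spectrum: GainSpectrum,
    smooth_bins: int = 5,
    height_frac: float = 0.25,
    min_width_hz: float = 2.0,
    min_prominence_db: float = 6.0,
) -> int:
    """Number of distinct pass regions in a gain spectrum.

    The spectrum is smoothed with a moving average, zeroed around its
    median, and peaks are counted with a height threshold (fraction of the
    smoothed maximum), a minimum width in Hz, and a minimum prominence in
    dB.  The prominence floor keeps sub-dB passband ripple of a single wide
    band from registering as several peaks, so a flat-top bandpass counts
    as one region while genuinely disjoint pass regions count separately.
    A count above one labels the filter multiband.  Invariant to adding a
    constant to the spectrum (median-zeroing).
    """
    if spectrum.discarded or spectrum.gain_db is None:
        raise ValueError("cannot count peaks of a discarded spectrum")
    g = np.asarray(spectrum.gain_db, dtype=float)
    k = max(1, int(smooth_bins))
    sm = np.convolve(g, np.ones(k) / k, mode="same")
    sm = sm - np.median(sm)
    if sm.max() <= 0:
        return 0
    df = float(spectrum.freqs[1] - spectrum.freqs[0])
    width_bins = max(1.0, min_width_hz / df)
    peaks, _ = find_peaks(
        sm,
        height=height_frac * sm.max(),
        width=width_bins,
        prominence=min_prominence_db,
    )
    return int(len(peaks))


def _spd_stage_names(model: EEGSPDNet) -> list[str]:
    names = ["pool"]
    for i in range(1, model.config.NBiRe + 1):
        names.extend([f"bimap{i}", f"reeig{i}"])
    return names


def layer_by_layer(
    model: EEGSPDNet,
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xte: np.ndarray,
    yte: np.ndarray,
    svm_C: float = 1.0,
) -> pd.DataFrame:
    """Probe classification at every SPD stage of a trained network.

    At each stage a Euclidean probe (linear SVM on the norm-preserving
    vectorisation) and a Riemannian probe (LEM rSVM) are fitted on the
    training-set feature maps and scored on the test-set maps; the returned
    table reports probe accuracy and its difference to the network's own
    test accuracy.  Degenerate (non-PD) maps are eigenvalue-floored first.
    """
    ytr = np.asarray(ytr)
    yte = np.asarray(yte)
    maps_tr = model.intermediate_maps(Xtr)
    maps_te = model.intermediate_maps(Xte)
    net_acc = 100.0 * float(np.mean(model.predict(Xte) == yte))
    eps = model.config.reeig_eps
    rows = []
    for stage in _spd_stage_names(model):
        Str = np.stack([regularize(S, eps) for S in maps_tr[stage]])
        Ste = np.stack([regularize(S, eps) for S in maps_te[stage]])
        for probe in ("SVM", "rSVM"):
            if probe == "SVM":
                clf = SVC(kernel="linear", C=svm_C)
                clf.fit(np.stack([vect(S) for S in Str]), ytr)
                pred = clf.predict(np.stack([vect(S) for S in Ste]))
            else:
                rclf = RSVMClassifier(metric="LEM", C=svm_C)
                rclf.fit(Str, ytr)
                pred = rclf.predict(Ste)
            acc = 100.0 * float(np.mean(pred == yte))
            rows.append(
                {
                    "stage": stage,
                    "probe": probe,
                    "accuracy": acc,
                    "network_accuracy": net_acc,
                    "probe_minus_network": acc - net_acc,
                }
            )
    return pd.DataFrame(rows)


def eig_below_threshold(model: EEGSPDNet, X: np.ndarray) -> pd.DataFrame:
    """Percentage of feature-map eigenvalues below the ReEig threshold, per layer.

    Aggregated over the batch as the mean of per-trial percentages (equal
    to the pooled percentage, since every map at a stage has the same
    size).  Stages immediately after a ReEig report exactly 0% by
    construction.
    """
    eps = model.config.reeig_eps
    maps = model.intermediate_maps(X)
    rows = []
    for stage in _spd_stage_names(model):
        w = np.linalg.eigvalsh(maps[stage])
        pct = 100.0 * float((w < eps).mean())
        rows.append({"stage": stage, "pct_below_eps": pct})
    return pd.DataFrame(rows)


def bimap_gain(W: np.ndarray, Nf: int = 1, Ne: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Covariance-entry gain of a first-layer BiMap weight.

    ``G[p, q]`` sums, over all output entries, the coefficient applied to
    covariance entry ``C[p, q]``; expanding the double sum collapses it to
    the rank-1 form ``s s^T`` with ``s`` the vector of row sums of ``W``.
    The per-electrode aggregate sums each row of ``G`` and folds the
    band-major row index back onto electrodes, giving each electrode the
    total gain on its variance plus all its covariance pairs.
    """
    W = np.asarray(W, dtype=float)
    s = W.sum(axis=1)
    G = np.outer(s, s)
    n = W.shape[0]
    Ne = Ne or n // Nf
    if Nf * Ne != n:
        raise ValueError(f"Nf*Ne = {Nf * Ne} inconsistent with weight rows {n}")
    row_totals = G.sum(axis=1)
    per_electrode = row_totals.reshape(Nf, Ne).sum(axis=0)
    return G, per_electrode


def electrode_frequency_relevance(
    model: EEGSPDNet, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Signed electrode x frequency relevance per class.

    For each class the gradient of the class score with respect to the
    pooled covariance is computed per trial, summed across matrix rows to a
    per-(band, electrode) scalar and averaged over trials; each band's
    scalar is multiplied by that filter's 0-1 min-max-normalised gain
    spectrum and accumulated onto its electrode.  Returns
    ``(relevance, freqs)`` with relevance of shape (n_classes, Ne, n_freqs).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    cfg = model.config
    spectra = frequency_gain(model, X)
    freqs = spectra[0].freqs
    n_freqs = freqs.size

    def norm_gain(gs: GainSpectrum) -> np.ndarray:
        if gs.discarded or gs.gain_db is None:
            return np.zeros(n_freqs)
        g = gs.gain_db
        lo, hi = g.min(), g.max()
        return np.zeros(n_freqs) if hi <= lo else (g - lo) / (hi - lo)

    gains = {}
    for gs in spectra:
        gains[(gs.band, gs.electrode)] = norm_gain(gs)

    rel = np.zeros((cfg.n_classes, cfg.Ne, n_freqs))
    for c in range(cfg.n_classes):
        G = model.score_gradient_wrt_pool(X, c)  # (B, n, n)
        row_scalars = G.sum(axis=2).mean(axis=0)  # (Nf*Ne,)
        for r, scalar in enumerate(row_scalars):
            band, elec = divmod(r, cfg.Ne)
            key = (band, elec if cfg.specificity == "ChSpec" else None)
            rel[c, elec] += scalar * gains[key]
    return rel, freqs
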