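"""End-to-end SPD network: filterbank -> SCM pooling -> SPDNet -> classifier.

The network is a second-order convolutional architecture.  A temporal
filterbank (free conv kernels or sinc-parameterised bandpass filters)
filters each electrode signal, a covariance pooling layer turns the
filtered trial into an SPD matrix, and a stack of BiMap/ReEig pairs
followed by LogEig, half-vectorisation and an affine map produces class
scores.

Automatic differentiation is implemented by hand: every layer caches its
forward pass and implements the exact adjoint, including the
Daleckii-Krein gradient of the two spectral layers (ReEig, LogEig) and the
bilinear-map gradients.  BiMap weights live on the Stiefel manifold
(orthonormal columns); the optimiser in :mod:`eegspd.training` keeps them
there by QR retraction.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.signal import fftconvolve

from .core_spd import sym
from .filterbank import FilterbankSpec, default_kernel_len, sinc_kernel

__all__ = [
    "NetworkConfig",
    "Parameter",
    "EEGSPDNet",
    "layer_widths",
    "bimap_forward",
    "softmax_cross_entropy",
]


def _as_batch(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X[None] if X.ndim == 2 else X


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _softplus_inv(y: np.ndarray) -> np.ndarray:
    # inverse of log(1+exp(x)); valid for y > 0
    return np.log(np.expm1(np.maximum(y, 1e-8)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class Parameter:
    """A learnable array plus its accumulated gradient.

    ``manifold`` is ``"euclidean"`` for ordinary parameters and
    ``"stiefel"`` for BiMap weights with the orthonormal-columns constraint.
    """

    value: np.ndarray
    manifold: Literal["euclidean", "stiefel"] = "euclidean"
    name: str = ""
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


@dataclass
class NetworkConfig:
    """Architecture hyperparameters of the end-to-end network."""

    Ne: int
    n_classes: int
    fs: float
    Nf: int = 1
    NBiRe: int = 3
    kind: Literal["conv", "sinc"] = "conv"
    specificity: Literal["ChInd", "ChSpec"] = "ChInd"
    keep_interband: bool = True
    reeig_eps: float = 1e-4
    kernel_len: int | None = None
    center_scm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.NBiRe < 0:
            raise ValueError("NBiRe must be >= 0")
        if self.Nf < 1:
            raise ValueError("Nf must be >= 1")
        if self.kernel_len is None:
            self.kernel_len = default_kernel_len(self.fs)


def layer_widths(config: NetworkConfig) -> list[int]:
    """SPD feature dimensions through the BiMap stack: ``Nf*Ne`` then floor-halvings."""
    widths = [config.Nf * config.Ne]
    for _ in range(config.NBiRe):
        widths.append(widths[-1] // 2)
    if widths[-1] < 1:
        raise ValueError(f"network too deep: layer widths reach zero ({widths})")
    return widths


def bimap_forward(S: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Bilinear map ``W^T S W`` (batched on leading axes of S)."""
    S = np.asarray(S, dtype=float)
    W = np.asarray(W, dtype=float)
    if S.shape[-1] != W.shape[0]:
        raise ValueError(f"dimension mismatch: S {S.shape} vs W {W.shape}")
    return sym(np.swapaxes(W, 0, 1) @ S @ W) if S.ndim == 2 else sym(
        np.einsum("pi,...pq,qj->...ij", W, S, W)
    )


# ---------------------------------------------------------------------------
# layers


class _ConvFilterbank:
    """Temporal filterbank layer with learnable parameters.

    ``conv`` learns the kernel taps directly; ``sinc`` learns (low,
    bandwidth) per filter through softplus reparameterisations with the
    upper cutoff clamped below Nyquist, so gradient steps can never produce
    an invalid ``low >= high`` pair.
    """

    MIN_BAND = 1.0  # Hz

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.cfg = config
        Ne, Nf, L = config.Ne, config.Nf, config.kernel_len
        n_units = Nf if config.specificity == "ChInd" else Nf * Ne
        self.n_units = n_units
        if config.kind == "conv":
            k = rng.normal(0.0, 1.0 / np.sqrt(L), size=(n_units, L))
            self.kernels = Parameter(k, name="conv_kernels")
            self.params = [self.kernels]
        else:
            nyq = config.fs / 2.0
            self.hmax = 0.99 * nyq
            # spread initial low cutoffs over the usable spectrum, jittered
            lows = np.linspace(1.0, 0.6 * nyq, Nf)
            lows = np.tile(lows, n_units // Nf) + rng.uniform(0, 1.0, n_units)
            bands = np.full(n_units, max(nyq / 4.0, 2.0)) + rng.uniform(0, 1.0, n_units)
            self.theta_low = Parameter(_softplus_inv(lows), name="sinc_low")
            self.theta_band = Parameter(
                _softplus_inv(np.maximum(bands - self.MIN_BAND, 0.5)), name="sinc_band"
            )
            self.params = [self.theta_low, self.theta_band]
        self._cache: dict = {}

    # -- sinc parameter -> cutoffs ------------------------------------------
    def cutoffs(self) -> tuple[np.ndarray, np.ndarray]:
        """Current (low, high) cutoffs in Hz, clamp applied (sinc only)."""
        low_raw = _softplus(self.theta_low.value)
        low = np.minimum(low_raw, self.hmax - self.MIN_BAND)
        high_raw = low + self.MIN_BAND + _softplus(self.theta_band.value)
        high = np.minimum(high_raw, self.hmax)
        return low, high

    def materialise_kernels(self) -> np.ndarray:
        """Kernels as (n_units, L)."""
        if self.cfg.kind == "conv":
            return self.kernels.value
        L, fs = self.cfg.kernel_len, self.cfg.fs
        low, high = self.cutoffs()
        return np.stack([sinc_kernel(lo, hi, L, fs) for lo, hi in zip(low, high)])

    def spec(self) -> FilterbankSpec:
        """Snapshot of the current filterbank as a static spec."""
        cfg = self.cfg
        if cfg.kind == "sinc":
            low, high = self.cutoffs()
            return FilterbankSpec(
                kind="sinc", Nf=cfg.Nf, specificity=cfg.specificity, fs=cfg.fs,
                kernel_len=cfg.kernel_len, cutoffs=list(zip(low.tolist(), high.tolist())),
            )
        K = self.kernels.value
        kern = K if cfg.specificity == "ChInd" else K.reshape(cfg.Nf, cfg.Ne, -1)
        return FilterbankSpec(
            kind="conv", Nf=cfg.Nf, specificity=cfg.specificity, fs=cfg.fs,
            kernel_len=cfg.kernel_len, kernels=kern.copy(),
        )

    def _unit_kernels_to_rows(self, K: np.ndarray) -> np.ndarray:
        """Expand unit kernels to one kernel per output row (Nf*Ne, L), band-major."""
        cfg = self.cfg
        if cfg.specificity == "ChInd":
            return np.repeat(K, cfg.Ne, axis=0)
        return K  # ChSpec units are already (Nf*Ne) in band-major order

    def forward(self, X: np.ndarray) -> np.ndarray:
        """(B, Ne, Nt) -> (B, Nf*Ne, Nt') band-major filtered batch."""
        X = np.asarray(X, dtype=float)
        B, Ne, Nt = X.shape
        cfg = self.cfg
        if Nt < cfg.kernel_len:
            raise ValueError(f"trial length {Nt} < kernel length {cfg.kernel_len}")
        K = self.materialise_kernels()
        Krows = self._unit_kernels_to_rows(K)  # (Nf*Ne, L)
        Xrep = np.tile(X, (1, cfg.Nf, 1))  # row f*Ne+e holds electrode e
        Y = fftconvolve(Xrep, Krows[None, :, ::-1], mode="valid", axes=-1)
        self._cache = {"Xrep": Xrep, "K": K}
        return Y

    def backward(self, G: np.ndarray) -> None:
        """Accumulate parameter gradients; input gradients are not needed."""
        cfg = self.cfg
        Xrep = self._cache["Xrep"]
        L = cfg.kernel_len
        # dL/dKrow[l] = sum_{b,t} G[b,row,t] * Xrep[b,row,t+l]
        gK_rows = fftconvolve(Xrep, G[:, :, ::-1], mode="valid", axes=-1).sum(axis=0)
        if cfg.specificity == "ChInd":
            gK = gK_rows.reshape(cfg.Nf, cfg.Ne, L).sum(axis=1)
        else:
            gK = gK_rows
        if cfg.kind == "conv":
            self.kernels.grad += gK
            return
        # chain through the sinc construction
        fs = cfg.fs
        t = (np.arange(L) - (L - 1) / 2.0) / fs
        w = np.hamming(L)
        low, high = self.cutoffs()
        dk_dhigh = 2.0 * np.cos(2.0 * np.pi * high[:, None] * t[None, :]) * w / fs
        dk_dlow = -2.0 * np.cos(2.0 * np.pi * low[:, None] * t[None, :]) * w / fs
        g_high = np.sum(gK * dk_dhigh, axis=1)
        g_low_direct = np.sum(gK * dk_dlow, axis=1)
        # clamp subgradients: zero where the min() was active
        low_raw = _softplus(self.theta_low.value)
        low_active = low_raw < self.hmax - self.MIN_BAND
        high_raw = low + self.MIN_BAND + _softplus(self.theta_band.value)
        high_active = high_raw < self.hmax
        g_high = g_high * high_active
        # high depends on low (when both unclamped) and on theta_band
        g_low_total = g_low_direct + g_high
        self.theta_low.grad += g_low_total * low_active * _sigmoid(self.theta_low.value)
        self.theta_band.grad += g_high * _sigmoid(self.theta_band.value)


class _SCMPool:
    """Covariance pooling of the band-major filtered batch."""

    def __init__(self, config: NetworkConfig):
        self.cfg = config
        self._cache: dict = {}

    def _block_mask(self, n: int) -> np.ndarray:
        cfg = self.cfg
        mask = np.zeros((n, n), dtype=bool)
        for f in range(cfg.Nf):
            a = f * cfg.Ne
            mask[a : a + cfg.Ne, a : a + cfg.Ne] = True
        return mask

    def forward(self, Y: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        ntp = Y.shape[-1]
        Yc = Y - Y.mean(axis=-1, keepdims=True) if cfg.center_scm else Y
        C = Yc @ np.swapaxes(Yc, -1, -2) / (ntp - 1)
        C = sym(C)
        if not cfg.keep_interband and cfg.Nf > 1:
            C = np.where(self._block_mask(C.shape[-1]), C, 0.0)
        self._cache = {"Yc": Yc, "ntp": ntp}
        return C

    def backward(self, G: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        Yc, ntp = self._cache["Yc"], self._cache["ntp"]
        Gs = sym(G)
        if not cfg.keep_interband and cfg.Nf > 1:
            Gs = np.where(self._block_mask(Gs.shape[-1]), Gs, 0.0)
        gY = 2.0 * Gs @ Yc / (ntp - 1)
        if cfg.center_scm:
            gY = gY - gY.mean(axis=-1, keepdims=True)
        return gY


class _BiMap:
    """Bilinear layer ``W^T S W`` with a Stiefel-constrained weight."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, idx: int):
        A = rng.normal(size=(d_in, d_out))
        Q, R = np.linalg.qr(A)
        Q = Q * np.sign(np.diag(R))
        self.W = Parameter(Q, manifold="stiefel", name=f"bimap{idx}_W")
        self.params = [self.W]
        self._cache: dict = {}

    def forward(self, S: np.ndarray) -> np.ndarray:
        W = self.W.value
        out = sym(np.einsum("pi,bpq,qj->bij", W, S, W, optimize=True))
        self._cache = {"S": S}
        return out

    def backward(self, G: np.ndarray) -> np.ndarray:
        W, S = self.W.value, self._cache["S"]
        Gs = sym(G)
        self.W.grad += 2.0 * np.einsum("bpq,qi,bij->pj", S, W, Gs, optimize=True)
        return np.einsum("pi,bij,qj->bpq", W, Gs, W, optimize=True)


class _Spectral:
    """Shared machinery for eigenvalue-function layers (ReEig, LogEig).

    Backward uses the Daleckii-Krein theorem: for ``f(S) = U f(L) U^T``,
    ``grad_S = U (K o (U^T G U)) U^T`` with the Loewner matrix ``K`` of
    divided differences of ``f`` (derivative on near-coincident pairs).
    """

    #: spacing below which divided differences switch to the derivative
    GAP_TOL = 1e-12

    def _fn(self, w: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def _dfn(self, w: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def forward(self, S: np.ndarray) -> np.ndarray:
        w, U = np.linalg.eigh(sym(S))
        fw = self._fn(w)
        out = sym(np.einsum("bij,bj,bkj->bik", U, fw, U, optimize=True))
        self._cache = {"w": w, "U": U, "fw": fw}
        return out

    def backward(self, G: np.ndarray) -> np.ndarray:
        w, U, fw = self._cache["w"], self._cache["U"], self._cache["fw"]
        Gs = sym(G)
        P = np.einsum("bji,bjk,bkl->bil", U, Gs, U, optimize=True)
        diff = w[:, :, None] - w[:, None, :]
        fdiff = fw[:, :, None] - fw[:, None, :]
        dmid = self._dfn(0.5 * (w[:, :, None] + w[:, None, :]))
        small = np.abs(diff) < self.GAP_TOL
        K = np.where(small, dmid, fdiff / np.where(small, 1.0, diff))
        return sym(np.einsum("bij,bjk,blk->bil", U, K * P, U, optimize=True))


class _ReEig(_Spectral):
    def __init__(self, eps: float):
        self.eps = float(eps)
        self._cache: dict = {}

    def _fn(self, w: np.ndarray) -> np.ndarray:
        return np.maximum(w, self.eps)

    def _dfn(self, w: np.ndarray) -> np.ndarray:
        return (w > self.eps).astype(float)


class _LogEig(_Spectral):
    #: eigenvalue floor applied inside log to survive numerically-PSD inputs
    FLOOR = 1e-300

    def __init__(self) -> None:
        self._cache: dict = {}

    def _fn(self, w: np.ndarray) -> np.ndarray:
        return np.log(np.maximum(w, self.FLOOR))

    def _dfn(self, w: np.ndarray) -> np.ndarray:
        return 1.0 / np.maximum(w, self.FLOOR)


class _Vect:
    """Norm-preserving half-vectorisation layer."""

    def __init__(self, n: int):
        self.n = n
        self.iu, self.ju = np.triu_indices(n)
        self.scale = np.where(self.iu == self.ju, 1.0, np.sqrt(2.0))

    def forward(self, S: np.ndarray) -> np.ndarray:
        return S[:, self.iu, self.ju] * self.scale

    def backward(self, G: np.ndarray) -> np.ndarray:
        B = G.shape[0]
        out = np.zeros((B, self.n, self.n))
        vals = G * self.scale
        # distribute symmetric halves; diagonal gets the full value
        half = np.where(self.iu == self.ju, vals, vals / 2.0)
        out[:, self.iu, self.ju] = half
        out[:, self.ju, self.iu] += np.where(self.iu == self.ju, 0.0, vals / 2.0)
        return out


class _Affine:
    """Final fully connected map to class scores."""

    def __init__(self, d_in: int, n_classes: int, rng: np.random.Generator):
        self.Wc = Parameter(rng.normal(0.0, 1.0 / np.sqrt(d_in), (d_in, n_classes)), name="fc_W")
        self.bc = Parameter(np.zeros(n_classes), name="fc_b")
        self.params = [self.Wc, self.bc]
        self._cache: dict = {}

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._cache = {"X": X}
        return X @ self.Wc.value + self.bc.value

    def backward(self, G: np.ndarray) -> np.ndarray:
        X = self._cache["X"]
        self.Wc.grad += X.T @ G
        self.bc.grad += G.sum(axis=0)
        return G @ self.Wc.value.T


def softmax_cross_entropy(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy loss and its gradient w.r.t. the scores."""
    z = scores - scores.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    B = scores.shape[0]
    loss = -float(logp[np.arange(B), y].mean())
    p = np.exp(logp)
    g = p.copy()
    g[np.arange(B), y] -= 1.0
    return loss, g / B


class EEGSPDNet:
    """The full end-to-end network.

    Pipeline: filterbank -> SCM pool -> (BiMap -> ReEig) x NBiRe -> LogEig
    -> Vect -> affine scores.  Deterministic given ``config.seed`` and the
    input; all randomness is confined to parameter initialisation.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.widths = layer_widths(config)
        self.filterbank = _ConvFilterbank(config, rng)
        self.pool = _SCMPool(config)
        self.bimaps: list[_BiMap] = []
        self.reeigs: list[_ReEig] = []
        for i in range(config.NBiRe):
            self.bimaps.append(_BiMap(self.widths[i], self.widths[i + 1], rng, i + 1))
            self.reeigs.append(_ReEig(config.reeig_eps))
        self.logeig = _LogEig()
        n_last = self.widths[-1]
        self.vect = _Vect(n_last)
        self.affine = _Affine(n_last * (n_last + 1) // 2, config.n_classes, rng)

    # -- parameter plumbing --------------------------------------------------
    def parameters(self) -> list[Parameter]:
        ps = list(self.filterbank.params)
        for bm in self.bimaps:
            ps.extend(bm.params)
        ps.extend(self.affine.params)
        return ps

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- forward / backward --------------------------------------------------
    def forward(self, X: np.ndarray) -> np.ndarray:
        """(B, Ne, Nt) batch of trials -> (B, n_classes) scores."""
        Z = self.filterbank.forward(_as_batch(X))
        S = self.pool.forward(Z)
        for bm, re in zip(self.bimaps, self.reeigs):
            S = bm.forward(S)
            S = re.forward(S)
        S = self.logeig.forward(S)
        v = self.vect.forward(S)
        return self.affine.forward(v)

    def backward(self, grad_scores: np.ndarray) -> None:
        """Backpropagate from score gradients into every parameter's ``.grad``."""
        G = self.affine.backward(grad_scores)
        G = self.vect.backward(G)
        G = self.logeig.backward(G)
        for bm, re in zip(reversed(self.bimaps), reversed(self.reeigs)):
            G = re.backward(G)
            G = bm.backward(G)
        G = self.pool.backward(G)
        self.filterbank.backward(G)

    def loss_and_grad(self, X: np.ndarray, y: np.ndarray) -> float:
        """Forward + backward for one batch; returns the mean CE loss."""
        self.zero_grad()
        scores = self.forward(X)
        loss, g = softmax_cross_entropy(scores, np.asarray(y))
        self.backward(g)
        return loss

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(X), axis=1)

    # -- analysis hooks ------------------------------------------------------
    def intermediate_maps(self, X: np.ndarray) -> "OrderedDict[str, np.ndarray]":
        """Per-layer feature maps for the analysis module.

        SPD stages are the pooled covariance plus one map after every BiMap
        and every ReEig (``1 + 2*NBiRe`` in total); the LogEig output and
        vectorised features are appended for Euclidean probes.
        """
        maps: "OrderedDict[str, np.ndarray]" = OrderedDict()
        Z = self.filterbank.forward(_as_batch(X))
        S = self.pool.forward(Z)
        maps["pool"] = S
        for i, (bm, re) in enumerate(zip(self.bimaps, self.reeigs), start=1):
            S = bm.forward(S)
            maps[f"bimap{i}"] = S
            S = re.forward(S)
            maps[f"reeig{i}"] = S
        L = self.logeig.forward(S)
        maps["logeig"] = L
        maps["vect"] = self.vect.forward(L)
        return maps

    def pooled_covariance(self, X: np.ndarray) -> np.ndarray:
        """The post-pool SPD feature map (no gradient caching side effects kept)."""
        Z = self.filterbank.forward(_as_batch(X))
        return self.pool.forward(Z)

    def score_gradient_wrt_pool(self, X: np.ndarray, class_index: int) -> np.ndarray:
        """Gradient of the summed class score w.r.t. the pooled covariance.

        Used by the electrode-frequency relevance analysis: differentiates
        the (pre-softmax) score of ``class_index`` through the SPDNet stage
        only, back to the covariance input of the first BiMap.
        """
        Z = self.filterbank.forward(_as_batch(X))
        S0 = self.pool.forward(Z)
        S = S0
        for bm, re in zip(self.bimaps, self.reeigs):
            S = bm.forward(S)
            S = re.forward(S)
        S = self.logeig.forward(S)
        v = self.vect.forward(S)
        scores = self.affine.forward(v)
        g = np.zeros_like(scores)
        g[:, class_index] = 1.0
        # walk back without touching parameter grads
        saved = [p.grad.copy() for p in self.parameters()]
        G = self.affine.backward(g)
        G = self.vect.backward(G)
        G = self.logeig.backward(G)
        for bm, re in zip(reversed(self.bimaps), reversed(self.reeigs)):
            G = re.backward(G)
            G = bm.backward(G)
        for p, s in zip(self.parameters(), saved):
            p.grad[...] = s
        return G


def save_checkpoint(model: EEGSPDNet, path) -> None:
    """Write all weights plus the architecture config to an HDF5 checkpoint."""
    import json
    from dataclasses import asdict

    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(asdict(model.config))
        for p in model.parameters():
            f.create_dataset(p.name, data=p.value)


def load_checkpoint(path) -> EEGSPDNet:
    """Rebuild a network from an HDF5 checkpoint."""
    import json

    import h5py

    with h5py.File(path, "r") as f:
        cfg = NetworkConfig(**json.loads(f.attrs["config"]))
        model = EEGSPDNet(cfg)
        for p in model.parameters():
            p.value[...] = f[p.name][...]
    return model
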