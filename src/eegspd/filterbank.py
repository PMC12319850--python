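"""Learnable filterbank front-end: free conv kernels and sinc bandpass filters.

Each input electrode signal is duplicated ``Nf`` times and temporally
filtered, either channel-independently (each filter applied to every
electrode) or channel-specifically (filter *(f, e)* applied only to
electrode *e*).  The filtered rows are stacked band-major — all electrodes
of band 1, then band 2, ... — and pooled into a sample covariance matrix of
size ``Nf*Ne``, optionally with the interband (off-diagonal-block)
covariance removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .core_spd import BlockStructure, interband_scm, scm

__all__ = [
    "FilterbankSpec",
    "FilteredTrial",
    "sinc_kernel",
    "default_kernel_len",
    "filterbank_forward",
    "scm_pool",
]


def default_kernel_len(fs: float) -> int:
    """Default temporal kernel length: fs/4 rounded to the nearest odd integer.

    A ~250 ms window resolves spectral structure down to roughly 4 Hz while
    keeping the valid-mode output long relative to typical trial lengths.
    """
    n = int(round(fs / 4.0))
    if n % 2 == 0:
        n += 1
    return max(n, 3)


def sinc_kernel(low: float, high: float, kernel_len: int, fs: float) -> np.ndarray:
    """Windowed difference-of-sincs bandpass FIR kernel.

    ``k = 2*high*sinc(2*high*t) - 2*low*sinc(2*low*t)`` on a symmetric time
    grid, multiplied by a Hamming window.  ``low = 0`` degenerates to a pure
    low-pass kernel.  The kernel is exactly symmetric about its centre
    (linear phase), so filtering cannot introduce phase distortion.
    """
    nyq = fs / 2.0
    if not (0.0 <= low < high <= nyq):
        raise ValueError(
            f"cutoffs must satisfy 0 <= low < high <= fs/2, got ({low}, {high}) at fs={fs}"
        )
    kernel_len = int(kernel_len)
    if kernel_len < 3 or kernel_len % 2 == 0:
        raise ValueError(f"kernel_len must be an odd integer >= 3, got {kernel_len}")
    t = (np.arange(kernel_len) - (kernel_len - 1) / 2.0) / fs
    k = 2.0 * high * np.sinc(2.0 * high * t) - 2.0 * low * np.sinc(2.0 * low * t)
    k *= np.hamming(kernel_len)
    return k / fs  # sample the continuous-time impulse response at unit passband gain


@dataclass
class FilterbankSpec:
    """Static description of a filterbank.

    ``kind="sinc"`` carries ``Nf`` (ChInd) or ``Nf*Ne`` (ChSpec) cutoff
    pairs; ``kind="conv"`` carries the kernels themselves with shape
    (Nf, kernel_len) or (Nf, Ne, kernel_len).
    """

    kind: Literal["conv", "sinc"]
    Nf: int
    specificity: Literal["ChInd", "ChSpec"]
    fs: float
    kernel_len: int
    cutoffs: list[tuple[float, float]] | None = None  # sinc only, band-major
    kernels: np.ndarray | None = None  # conv only

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "sinc"):
            raise ValueError(f"kind must be 'conv' or 'sinc', got {self.kind!r}")
        if self.specificity not in ("ChInd", "ChSpec"):
            raise ValueError(f"specificity must be 'ChInd' or 'ChSpec', got {self.specificity!r}")
        if self.Nf < 1:
            raise ValueError("Nf must be >= 1")
        if self.kernel_len % 2 == 0 or self.kernel_len < 3:
            raise ValueError("kernel_len must be an odd integer >= 3")
        if self.kind == "sinc":
            if self.cutoffs is None:
                raise ValueError("sinc spec requires cutoffs")
            nyq = self.fs / 2.0
            for lo, hi in self.cutoffs:
                if not (0.0 <= lo < hi <= nyq):
                    raise ValueError(f"invalid cutoff pair ({lo}, {hi}) for fs={self.fs}")
        if self.kind == "conv" and self.kernels is None:
            raise ValueError("conv spec requires kernels")

    def expected_cutoff_count(self, Ne: int) -> int:
        return self.Nf if self.specificity == "ChInd" else self.Nf * Ne

    def materialise_kernels(self, Ne: int) -> np.ndarray:
        """Kernels as an (Nf, Ne, kernel_len) array, whatever the storage form."""
        if self.kind == "sinc":
            pairs = list(self.cutoffs)
            if len(pairs) == self.Nf:
                ks = np.stack([sinc_kernel(lo, hi, self.kernel_len, self.fs) for lo, hi in pairs])
                return np.repeat(ks[:, None, :], Ne, axis=1)
            if len(pairs) == self.Nf * Ne:
                ks = np.stack([sinc_kernel(lo, hi, self.kernel_len, self.fs) for lo, hi in pairs])
                return ks.reshape(self.Nf, Ne, self.kernel_len)
            raise ValueError(
                f"expected {self.Nf} or {self.Nf * Ne} cutoff pairs, got {len(pairs)}"
            )
        K = np.asarray(self.kernels, dtype=float)
        if K.ndim == 2:
            if K.shape != (self.Nf, self.kernel_len):
                raise ValueError(f"conv kernels shape {K.shape} != (Nf, kernel_len)")
            return np.repeat(K[:, None, :], Ne, axis=1)
        if K.shape[0] != self.Nf or K.shape[2] != self.kernel_len:
            raise ValueError(f"conv kernels shape {K.shape} inconsistent with spec")
        return K

    # -- JSON round trip (conv kernels live in HDF5, not JSON) --------------
    def to_json(self) -> str:
        d = {
            "kind": self.kind,
            "Nf": self.Nf,
            "specificity": self.specificity,
            "fs": self.fs,
            "kernel_len": self.kernel_len,
            "cutoffs": [list(map(float, p)) for p in self.cutoffs] if self.cutoffs else None,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str, kernels: np.ndarray | None = None) -> "FilterbankSpec":
        d = json.loads(s)
        cut = [tuple(p) for p in d["cutoffs"]] if d.get("cutoffs") else None
        return cls(
            kind=d["kind"], Nf=d["Nf"], specificity=d["specificity"], fs=d["fs"],
            kernel_len=d["kernel_len"], cutoffs=cut, kernels=kernels,
        )


@dataclass
class FilteredTrial:
    """Band-major stack of filtered electrode signals.

    Row ``f * Ne + e`` holds electrode ``e`` filtered through band ``f``;
    the index maps make the convention explicit for downstream analyses.
    """

    data: np.ndarray  # (Nf*Ne, Nt')
    band_of_row: np.ndarray
    electrode_of_row: np.ndarray
    Nf: int
    Ne: int

    @property
    def structure(self) -> BlockStructure:
        return BlockStructure([self.Ne] * self.Nf)


def _valid_filter_rows(X: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Valid-mode cross-correlation of each row of X with its kernel row."""
    # fftconvolve with a flipped kernel == correlation; kernels here are used
    # as-is (convention: correlation), which is what the network layer also uses.
    out = fftconvolve(X[None, :, :], kernels[:, :, ::-1], mode="valid", axes=-1)
    return out  # (Nf, Ne, Nt')


def filterbank_forward(trial: np.ndarray, spec: FilterbankSpec) -> FilteredTrial:
    """Apply a static filterbank to one trial, returning the band-major stack.

    ChInd applies each of the ``Nf`` filters to all electrodes; ChSpec
    applies kernel *(f, e)* only to electrode *e*.  Both modes produce
    ``Nf*Ne`` output rows of length ``Nt - kernel_len + 1`` (valid mode, no
    padding), so downstream covariance sizes never depend on specificity.
    """
    X = np.asarray(trial, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"trial must be (Ne, Nt), got {X.shape}")
    Ne, Nt = X.shape
    if Nt < spec.kernel_len:
        raise ValueError(f"trial length {Nt} shorter than kernel ({spec.kernel_len})")
    K = spec.materialise_kernels(Ne)  # (Nf, Ne, L)
    Y = _valid_filter_rows(X, K)  # (Nf, Ne, Nt')
    Nf = spec.Nf
    data = Y.reshape(Nf * Ne, -1)
    band = np.repeat(np.arange(Nf), Ne)
    elec = np.tile(np.arange(Ne), Nf)
    return FilteredTrial(data=data, band_of_row=band, electrode_of_row=elec, Nf=Nf, Ne=Ne)


def scm_pool(
    filtered: FilteredTrial,
    keep_interband: bool = True,
    center: bool = True,
) -> np.ndarray:
    """Pool a filtered trial into its (Nf*Ne) sample covariance matrix.

    With ``keep_interband`` this is the plain covariance of the stacked
    rows; without it, the off-diagonal (between-band) blocks are zeroed,
    which equals concatenating the per-band covariances.  For ``Nf = 1``
    both reduce to the ordinary SCM of the filtered trial.
    """
    if filtered.Nf == 1 or keep_interband:
        return scm(filtered.data, center=center)
    return interband_scm(
        filtered.data, filtered.structure, keep_interband=False, center=center
    )
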