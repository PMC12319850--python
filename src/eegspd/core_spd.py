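"""Deterministic SPD linear algebra.

Covariance estimation, eigenvalue rectification, matrix logarithm,
norm-preserving vectorisation, block-diagonal concatenation and interband
covariance — the primitive operations every other module builds on.

All functions accept and return plain ``numpy`` arrays.  Matrices are
validated for symmetry (to a relative tolerance) and symmetrised before any
eigendecomposition, so downstream consumers never see the asymmetric
round-off that ``A @ A.T`` style products can accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BlockStructure",
    "scm",
    "reeig_rectify",
    "regularize",
    "logeig_map",
    "expm_spd",
    "logm_spd",
    "vect",
    "unvect",
    "conc",
    "interband_scm",
    "sym",
    "check_symmetric",
    "is_pd",
]

#: default ReEig rectification threshold (dimensionless eigenvalue floor)
DEFAULT_EPS = 1e-4

#: relative asymmetry above which an input is rejected instead of symmetrised
ASYM_TOL = 1e-8


def sym(S: np.ndarray) -> np.ndarray:
    """Symmetrise ``(S + S.T) / 2`` (batched on the last two axes)."""
    return 0.5 * (S + np.swapaxes(S, -1, -2))


def check_symmetric(S: np.ndarray, tol: float = ASYM_TOL) -> np.ndarray:
    """Validate symmetry to relative tolerance and return the symmetrised matrix.

    Raises
    ------
    ValueError
        If ``S`` is not square, contains non-finite entries, or its
        asymmetry exceeds ``tol`` relative to its norm.
    """
    S = np.asarray(S, dtype=float)
    if S.shape[-1] != S.shape[-2]:
        raise ValueError(f"expected a square matrix, got shape {S.shape}")
    if not np.all(np.isfinite(S)):
        raise ValueError("matrix contains non-finite entries")
    scale = np.linalg.norm(S) + np.finfo(float).tiny
    asym = np.linalg.norm(S - np.swapaxes(S, -1, -2)) / scale
    if asym > tol:
        raise ValueError(f"matrix asymmetry {asym:.3e} exceeds tolerance {tol:.1e}")
    return sym(S)


def is_pd(S: np.ndarray, tol: float = 0.0) -> bool:
    """True when all eigenvalues of the symmetrised input exceed ``tol``."""
    w = np.linalg.eigvalsh(sym(np.asarray(S, dtype=float)))
    return bool(np.all(w > tol))


@dataclass(frozen=True)
class BlockStructure:
    """Ordered block sizes of a band-major block matrix.

    Rows of a multi-band stacked trial are ordered band-major: all
    electrodes of band 1, then all electrodes of band 2, and so on.  The
    block sizes record where one band's electrodes end and the next begin.
    """

    block_sizes: tuple[int, ...]

    def __init__(self, block_sizes: Sequence[int]):
        sizes = tuple(int(b) for b in block_sizes)
        if not sizes or any(b <= 0 for b in sizes):
            raise ValueError("block sizes must be a nonempty list of positive ints")
        object.__setattr__(self, "block_sizes", sizes)

    @property
    def dim(self) -> int:
        return sum(self.block_sizes)

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)

    def offsets(self) -> list[tuple[int, int]]:
        """(start, stop) row ranges of each block."""
        out, start = [], 0
        for b in self.block_sizes:
            out.append((start, start + b))
            start += b
        return out


def scm(trial: np.ndarray, center: bool = True) -> np.ndarray:
    """Sample covariance matrix ``T @ T.T / (Nt - 1)`` of a trial.

    Parameters
    ----------
    trial : (Ne, Nt) array
        Multichannel signal, electrodes along rows.
    center : bool
        Remove the per-channel mean first (default).  With centering the
        result is the textbook sample covariance; without it the raw
        second-moment matrix, which matches signals that are already
        zero-mean.

    The output is symmetric PSD by construction and strictly PD whenever
    ``Nt > Ne`` and the rows are linearly independent.
    """
    T = np.asarray(trial, dtype=float)
    if T.ndim != 2:
        raise ValueError(f"trial must be 2-D (Ne, Nt), got shape {T.shape}")
    if not np.all(np.isfinite(T)):
        raise ValueError("trial contains non-finite entries")
    nt = T.shape[1]
    if nt < 2:
        raise ValueError(f"need at least 2 samples for a covariance, got {nt}")
    if center:
        T = T - T.mean(axis=1, keepdims=True)
    return sym(T @ T.T / (nt - 1))


def reeig_rectify(S: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Eigenvalue rectification ``U max(eps*I, Sigma) U^T``.

    The SPD-manifold analogue of a ReLU: eigenvalues below ``eps`` are
    floored at ``eps``, keeping the matrix away from the singular boundary.
    Idempotent; leaves matrices whose spectrum already clears the floor
    untouched (up to the symmetric eigendecomposition round-trip).
    """
    if eps <= 0:
        raise ValueError("rectification threshold must be positive")
    S = check_symmetric(S)
    w, U = np.linalg.eigh(S)
    if np.all(w >= eps):
        return S
    return sym((U * np.maximum(w, eps)) @ U.T)


def regularize(S: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Regularise a PSD matrix to strict PD by eigenvalue flooring.

    Identical to :func:`reeig_rectify`; provided under the name used when
    the operation serves as a pre-analysis regulariser rather than a
    network layer.
    """
    return reeig_rectify(S, eps)


def logeig_map(S: np.ndarray) -> np.ndarray:
    """Matrix logarithm ``U log(Sigma) U^T`` of a strictly PD matrix.

    Maps the SPD cone onto the vector space of symmetric matrices; the
    matrix exponential inverts it exactly on this domain.
    """
    S = check_symmetric(S)
    w, U = np.linalg.eigh(S)
    if np.any(w <= 0):
        raise ValueError(
            f"matrix is not strictly positive definite (min eigenvalue {w.min():.3e}); "
            "regularize() it first"
        )
    return sym((U * np.log(w)) @ U.T)


def logm_spd(S: np.ndarray) -> np.ndarray:
    """Alias of :func:`logeig_map` under the conventional name."""
    return logeig_map(S)


def expm_spd(X: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (returns an SPD matrix)."""
    X = check_symmetric(X)
    w, U = np.linalg.eigh(X)
    return sym((U * np.exp(w)) @ U.T)


def _triu_idx(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n)


def vect(S: np.ndarray) -> np.ndarray:
    """Norm-preserving half-vectorisation of a symmetric matrix.

    Stacks the ``n(n+1)/2`` unique upper-triangular elements row by row,
    scaling off-diagonal entries by ``sqrt(2)`` so that the Euclidean norm
    of the vector equals the Frobenius norm of the matrix.
    """
    S = check_symmetric(S)
    n = S.shape[-1]
    iu, ju = _triu_idx(n)
    v = S[..., iu, ju].copy()
    off = iu != ju
    v[..., off] *= np.sqrt(2.0)
    return v


def unvect(v: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vect`: rebuild the symmetric matrix from its vector."""
    v = np.asarray(v, dtype=float)
    iu, ju = _triu_idx(n)
    if v.shape[-1] != iu.size:
        raise ValueError(f"vector length {v.shape[-1]} != n(n+1)/2 = {iu.size}")
    S = np.zeros(v.shape[:-1] + (n, n))
    w = v.copy()
    off = iu != ju
    w[..., off] /= np.sqrt(2.0)
    S[..., iu, ju] = w
    S[..., ju, iu] = w
    return S


def conc(blocks: Sequence[np.ndarray]) -> tuple[np.ndarray, BlockStructure]:
    """Block-diagonal concatenation of SPD matrices.

    The output is SPD with spectrum equal to the union of the block
    spectra, so concatenating per-band covariances yields a single valid
    SPD feature matrix.
    """
    if len(blocks) == 0:
        raise ValueError("conc requires at least one block")
    mats = [check_symmetric(B) for B in blocks]
    structure = BlockStructure([B.shape[0] for B in mats])
    out = np.zeros((structure.dim, structure.dim))
    for (a, b), B in zip(structure.offsets(), mats):
        out[a:b, a:b] = B
    return out, structure


def zero_offdiag_blocks(S: np.ndarray, structure: BlockStructure) -> np.ndarray:
    """Zero every off-diagonal block of ``S`` under ``structure`` (batched)."""
    S = np.asarray(S, dtype=float)
    if S.shape[-1] != structure.dim:
        raise ValueError("block structure inconsistent with matrix dimension")
    mask = np.zeros((structure.dim, structure.dim), dtype=bool)
    for a, b in structure.offsets():
        mask[a:b, a:b] = True
    return np.where(mask, S, 0.0)


def interband_scm(
    stacked: np.ndarray,
    structure: BlockStructure,
    keep_interband: bool = True,
    center: bool = True,
) -> np.ndarray:
    """Covariance of a band-major stacked trial, with or without interband blocks.

    ``stacked`` holds the same trial filtered through several bands, rows
    ordered band-major.  With ``keep_interband`` the full covariance is
    returned; its off-diagonal blocks are the covariances between
    electrodes of *different* frequency bands.  Without it the result is
    the block-diagonal concatenation of the per-band covariances — built
    directly from the per-band rows, so it matches that concatenation
    bit-for-bit.
    """
    stacked = np.asarray(stacked, dtype=float)
    if stacked.ndim != 2 or stacked.shape[0] != structure.dim:
        raise ValueError(
            f"stacked rows {stacked.shape} inconsistent with block structure dim {structure.dim}"
        )
    if keep_interband:
        return scm(stacked, center=center)
    blocks = [scm(stacked[a:b], center=center) for a, b in structure.offsets()]
    return conc(blocks)[0]
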