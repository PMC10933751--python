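"""Block-Hankel lifting of multi-shot-group k-space and SVD thresholding.

``lift`` slides a ``k1 x k2`` window over each group's ky-kz plane
(valid windows only, no wrap-around); each window position contributes
one row whose columns are the vectorized patch, with the per-group
blocks concatenated side by side.  Smooth inter-group phase differences
make this matrix low-rank, which the singular-value thresholding
operators exploit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "HankelConfig",
    "NumericalError",
    "lift",
    "unlift",
    "coverage_counts",
    "lifted_shape",
    "svdvals",
    "sv_hard_threshold",
    "sv_soft_threshold",
]


class NumericalError(RuntimeError):
    """A dense linear-algebra routine failed to converge."""


@dataclass(frozen=True)
class HankelConfig:
    """Sliding-window kernel size of the block-Hankel lifting (default 6x6)."""

    k1: int = 6
    k2: int = 6

    def validate(self, grid: tuple[int, int]) -> None:
        ny, nz = grid
        if not (1 <= self.k1 <= ny and 1 <= self.k2 <= nz):
            raise ValueError(
                f"kernel {self.k1}x{self.k2} invalid for {ny}x{nz} grid"
            )


def lifted_shape(grid: tuple[int, int], cfg: HankelConfig, n_groups: int) -> tuple[int, int]:
    ny, nz = grid
    return ((ny - cfg.k1 + 1) * (nz - cfg.k2 + 1), cfg.k1 * cfg.k2 * n_groups)


def lift(x: np.ndarray, cfg: HankelConfig = HankelConfig()) -> np.ndarray:
    """Block-Hankel lifting of ``x`` with shape (groups, ny, nz).

    Returns a matrix of shape
    ``[(ny-k1+1)*(nz-k2+1), k1*k2*groups]``; column block ``g`` holds
    the vectorized patches of group ``g``.
    """
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError(f"X must be (groups, ny, nz), got shape {x.shape}")
    g = x.shape[0]
    cfg.validate(x.shape[1:])
    win = sliding_window_view(x, (cfg.k1, cfg.k2), axis=(1, 2))  # (G, P, Q, k1, k2)
    p, q = win.shape[1], win.shape[2]
    rows = win.reshape(g, p * q, cfg.k1 * cfg.k2)
    return rows.transpose(1, 0, 2).reshape(p * q, g * cfg.k1 * cfg.k2)


def unlift(
    m: np.ndarray, cfg: HankelConfig, grid: tuple[int, int], n_groups: int
) -> np.ndarray:
    """Adjoint of :func:`lift`: sum every matrix entry back onto its
    originating k-space location.  ``unlift(lift(X)) = coverage_counts * X``.
    """
    m = np.asarray(m)
    cfg.validate(grid)
    ny, nz = grid
    p, q = ny - cfg.k1 + 1, nz - cfg.k2 + 1
    expect = (p * q, cfg.k1 * cfg.k2 * n_groups)
    if m.shape != expect:
        raise ValueError(f"lifted matrix has shape {m.shape}, expected {expect}")
    blocks = m.reshape(p, q, n_groups, cfg.k1, cfg.k2)
    x = np.zeros((n_groups, ny, nz), dtype=m.dtype)
    for i in range(cfg.k1):
        for j in range(cfg.k2):
            x[:, i : i + p, j : j + q] += blocks[:, :, :, i, j].transpose(2, 0, 1)
    return x


def coverage_counts(grid: tuple[int, int], cfg: HankelConfig) -> np.ndarray:
    """Diagonal of ``H^H H``: how many sliding windows cover each location.

    Separable product of 1D window counts; interior entries of a large
    grid equal ``k1 * k2``.
    """
    cfg.validate(grid)

    def counts_1d(n: int, k: int) -> np.ndarray:
        idx = np.arange(n)
        return np.minimum(idx, n - k) - np.maximum(idx - k + 1, 0) + 1

    return np.outer(counts_1d(grid[0], cfg.k1), counts_1d(grid[1], cfg.k2)).astype(float)


def _svd(m: np.ndarray):
    if not np.all(np.isfinite(m)):
        raise NumericalError("lifted matrix contains non-finite entries")
    try:
        return scipy.linalg.svd(m, full_matrices=False)
    except np.linalg.LinAlgError:
        pass
    try:  # gesdd occasionally fails where the slower gesvd succeeds
        return scipy.linalg.svd(m, full_matrices=False, lapack_driver="gesvd")
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological input
        raise NumericalError(
            f"SVD failed on matrix of shape {m.shape} (norm {np.linalg.norm(m):.3e})"
        ) from exc


def svdvals(m: np.ndarray) -> np.ndarray:
    """Singular values of the lifted matrix, descending."""
    return _svd(np.asarray(m))[1]


def sv_hard_threshold(
    m: np.ndarray, tau: float | None = None, rank: int | None = None
) -> np.ndarray:
    """Zero all singular values below ``tau``, or keep only the top ``rank``.

    Exactly one of ``tau`` (value mode, kept iff sigma >= tau) or
    ``rank`` (rank mode) must be given.
    """
    if (tau is None) == (rank is None):
        raise ValueError("specify exactly one of tau or rank")
    u, s, vh = _svd(np.asarray(m))
    if tau is not None:
        if tau < 0:
            raise ValueError("tau must be nonnegative")
        s = np.where(s >= tau, s, 0.0)
    else:
        if rank < 0:
            raise ValueError("rank must be nonnegative")
        s = np.where(np.arange(s.size) < rank, s, 0.0)
    return (u * s) @ vh


def sv_soft_threshold(m: np.ndarray, tau: float) -> np.ndarray:
    """Shrink every singular value by ``tau`` (floored at zero)."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    u, s, vh = _svd(np.asarray(m))
    return (u * np.maximum(s - tau, 0.0)) @ vh
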