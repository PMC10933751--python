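"""SENSE forward model on the ky-kz plane.

The encoding operator maps per-shot-group single-("virtual")-coil k-space
to masked multi-coil measurements:

    E = M . F . S . F^-1

applied independently to each shot group.  All transforms are centered
(DC at ``n // 2``) and unitary, which is the declared Fourier convention
of the whole package: it keeps ``E`` norm-bounded so regularization
weights are scale-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "fft2c",
    "ifft2c",
    "normalize_maps",
    "AcquiredData",
    "forward",
    "adjoint",
    "coil_combine_kspace",
]

log = logging.getLogger(__name__)

_AXES = (-2, -1)


def fft2c(x: np.ndarray, axes: tuple[int, int] = _AXES) -> np.ndarray:
    """Centered, unitary 2D FFT over ``axes``."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def ifft2c(x: np.ndarray, axes: tuple[int, int] = _AXES) -> np.ndarray:
    """Centered, unitary 2D inverse FFT over ``axes``."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def normalize_maps(maps: np.ndarray, support_tol: float = 1e-8) -> np.ndarray:
    """Scale coil maps so the root-sum-of-squares is 1 on support, 0 off it.

    ``maps`` has shape ``(coils, ny, nz)``.  Voxels whose RSS falls below
    ``support_tol * max(RSS)`` are treated as outside the coil support
    and zeroed.
    """
    maps = np.asarray(maps, dtype=np.complex128)
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    inside = rss > support_tol * rss.max()
    out = np.zeros_like(maps)
    np.divide(maps, rss[None], out=out, where=inside[None])
    return out


@dataclass
class AcquiredData:
    """Measured multi-coil multi-shot-group k-space plus sampling masks.

    Attributes
    ----------
    y : complex ndarray, shape (groups, coils, ny, nz)
        Measured samples, zero wherever the group mask is zero.
    masks : bool ndarray, shape (groups, ny, nz)
    """

    y: np.ndarray
    masks: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.complex128)
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.y.ndim != 4 or self.masks.ndim != 3:
            raise ValueError("y must be (groups, coils, ny, nz); masks (groups, ny, nz)")
        if self.y.shape[0] != self.masks.shape[0] or self.y.shape[2:] != self.masks.shape[1:]:
            raise ValueError(
                f"shape mismatch between y {self.y.shape} and masks {self.masks.shape}"
            )

    @property
    def n_groups(self) -> int:
        return self.y.shape[0]

    @property
    def n_coils(self) -> int:
        return self.y.shape[1]

    @property
    def grid(self) -> tuple[int, int]:
        return self.y.shape[2:]

    def check_off_mask_zero(self, atol: float = 0.0) -> bool:
        off = self.y * ~self.masks[:, None]
        return bool(np.abs(off).max(initial=0.0) <= atol)


def _check_shapes(x: np.ndarray, maps: np.ndarray, masks: np.ndarray) -> None:
    if x.ndim != 3:
        raise ValueError(f"X must be (groups, ny, nz), got shape {x.shape}")
    if maps.ndim != 3:
        raise ValueError(f"maps must be (coils, ny, nz), got shape {maps.shape}")
    if masks.ndim != 3:
        raise ValueError(f"masks must be (groups, ny, nz), got shape {masks.shape}")
    if x.shape[1:] != maps.shape[1:] or x.shape[1:] != masks.shape[1:]:
        raise ValueError(
            f"grid mismatch: X {x.shape[1:]}, maps {maps.shape[1:]}, masks {masks.shape[1:]}"
        )
    if x.shape[0] != masks.shape[0]:
        raise ValueError(f"group mismatch: X has {x.shape[0]}, masks have {masks.shape[0]}")


def forward(x: np.ndarray, maps: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Apply ``E``: virtual-coil group k-space -> masked multi-coil k-space.

    Parameters
    ----------
    x : (groups, ny, nz) complex
    maps : (coils, ny, nz) complex
    masks : (groups, ny, nz) bool

    Returns
    -------
    (groups, coils, ny, nz) complex
    """
    x = np.asarray(x)
    maps = np.asarray(maps)
    masks = np.asarray(masks, dtype=bool)
    _check_shapes(x, maps, masks)
    img = ifft2c(x)  # (G, ny, nz)
    y = fft2c(img[:, None, :, :] * maps[None, :, :, :])
    return y * masks[:, None, :, :]


def adjoint(y: np.ndarray, maps: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Apply ``E^H``: masked multi-coil k-space -> virtual-coil group k-space."""
    y = np.asarray(y)
    maps = np.asarray(maps)
    masks = np.asarray(masks, dtype=bool)
    if y.ndim != 4:
        raise ValueError(f"Y must be (groups, coils, ny, nz), got shape {y.shape}")
    _check_shapes(np.empty((y.shape[0], *y.shape[2:])), maps, masks)
    if y.shape[1] != maps.shape[0]:
        raise ValueError(f"coil mismatch: Y has {y.shape[1]}, maps have {maps.shape[0]}")
    img = ifft2c(y * masks[:, None, :, :])
    combined = (np.conj(maps)[None] * img).sum(axis=1)
    return fft2c(combined)


def coil_combine_kspace(
    kspace: np.ndarray, maps: np.ndarray, floor_rel: float = 1e-12
) -> np.ndarray:
    """Combine multi-coil k-space into a single virtual-coil k-space.

    The combination happens in image space using conjugate coil maps
    normalized by the sum of squared magnitudes; the denominator is
    floored at ``floor_rel * max|S|^2`` so voxels without coil support
    come out as zero instead of dividing by zero.

    Parameters
    ----------
    kspace : (coils, ny, nz) complex
    maps : (coils, ny, nz) complex
    """
    kspace = np.asarray(kspace)
    maps = np.asarray(maps)
    if kspace.shape != maps.shape:
        raise ValueError(f"kspace {kspace.shape} and maps {maps.shape} must match")
    imgs = ifft2c(kspace)
    ss = (np.abs(maps) ** 2).sum(axis=0)
    floor = floor_rel * ss.max() if ss.max() > 0 else 1.0
    if np.any(ss <= 0):
        log.debug("coil_combine_kspace: voxels with zero coil support floored to 0")
    combined = (np.conj(maps) * imgs).sum(axis=0) / np.maximum(ss, floor)
    combined[ss == 0] = 0.0
    return fft2c(combined)
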