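"""Temporal SNR and frequency-spectrum summaries of magnitude series.

tSNR of a voxel is its temporal mean divided by its temporal standard
deviation (N-1 denominator); zero-variance voxels are flagged invalid
and excluded from every summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TSNRMap",
    "tsnr_map",
    "mean_tsnr",
    "mean_power_spectrum",
    "support_mask",
]


@dataclass
class TSNRMap:
    mean: np.ndarray
    std: np.ndarray
    tsnr: np.ndarray
    valid: np.ndarray  # bool; False where std == 0 or outside the given mask


def tsnr_map(series: np.ndarray, mask: np.ndarray | None = None) -> TSNRMap:
    """Per-voxel temporal mean / std / tSNR of a (frames, ...) magnitude
    series with at least 3 frames."""
    series = np.asarray(series, dtype=float)
    if series.ndim < 2 or series.shape[0] < 3:
        raise ValueError("series must be (frames >= 3, ...spatial)")
    mean = series.mean(axis=0)
    std = series.std(axis=0, ddof=1)
    valid = std > 0
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    tsnr = np.zeros_like(mean)
    np.divide(mean, std, out=tsnr, where=valid)
    return TSNRMap(mean=mean, std=std, tsnr=tsnr, valid=valid)


def mean_tsnr(tmap: TSNRMap, mask: np.ndarray | None = None) -> float:
    """Arithmetic mean tSNR over valid voxels of ``mask``."""
    sel = tmap.valid if mask is None else (tmap.valid & np.asarray(mask, dtype=bool))
    if not sel.any():
        raise ValueError("no valid voxels selected")
    return float(tmap.tsnr[sel].mean())


def mean_power_spectrum(
    series: np.ndarray,
    mask: np.ndarray,
    volume_tr: float,
    window: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean one-sided power spectrum across masked voxels.

    Each voxel's time course is demeaned (optionally windowed), Fourier
    transformed, and its squared magnitude divided by (N - 1); the
    two-sided power is folded onto nonnegative frequencies so the sum of
    the returned spectrum equals N times the mean temporal variance.

    Returns
    -------
    freqs : Hz, up to the Nyquist frequency 1 / (2 * volume_tr)
    power : mean folded power per frequency bin
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 8:
        raise ValueError("need at least 8 frames for a spectrum")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    n = series.shape[0]
    x = series[:, mask] - series[:, mask].mean(axis=0, keepdims=True)
    if window is not None:
        from scipy.signal import get_window

        x = x * get_window(window, n)[:, None]
    spec = np.abs(np.fft.fft(x, axis=0)) ** 2 / (n - 1)
    n_keep = n // 2 + 1
    folded = spec[:n_keep].copy()
    # fold negative frequencies onto their positive counterparts
    folded[1 : (n + 1) // 2] += spec[-1 : -((n + 1) // 2) : -1]
    freqs = np.fft.rfftfreq(n, d=volume_tr)
    return freqs, folded.mean(axis=1)


def support_mask(mean_image: np.ndarray, fraction: float = 0.1) -> np.ndarray:
    """Voxels whose mean magnitude reaches ``fraction`` of the peak."""
    mean_image = np.abs(np.asarray(mean_image))
    return mean_image >= fraction * mean_image.max()
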