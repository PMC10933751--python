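"""Synthetic multi-shot fMRI data generation.

Builds everything the reconstruction needs end-to-end: a complex
ground-truth phantom, smooth coil sensitivity maps, a second-order
2D-harmonic respiratory phase model, per-shot k-space synthesis for any
shot schedule, calibrated complex Gaussian thermal noise, and paired
phase-free reference series sharing identical noise draws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np

from .encoding import AcquiredData, fft2c, normalize_maps
from .sampling import ShotSchedule, group_masks

__all__ = [
    "PhantomSpec",
    "PhaseModel",
    "NoiseSpec",
    "make_phantom",
    "make_coil_maps",
    "harmonic_basis",
    "phase_map_at",
    "shot_time",
    "group_mean_times",
    "simulate_timeseries",
    "simulate_pair",
    "snr_calibrate",
]

# second-order real 2D harmonics on normalized [-1, 1]^2 coordinates
N_BASIS = 6


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth image recipe: magnitude in [0, 1], support strictly
    inside the grid, optional low-order polynomial baseline phase."""

    ny: int = 48
    nz: int = 48
    structure: str = "shepp_logan_variant"
    # baseline phase = c0 + c1*u + c2*v + c3*u*v (radians), u,v in [-1,1]
    phase_coeffs: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    # shrink the whole object by this factor (object support scales with
    # support_scale^2; small objects make the lifted matrix near-low-rank)
    support_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.structure not in ("shepp_logan_variant", "smooth_blobs"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if not 0 < self.support_scale <= 1.0:
            raise ValueError("support_scale must be in (0, 1]")


@dataclass(frozen=True)
class PhaseModel:
    """Second-order-harmonic phase fluctuation model.

    The spatial pattern is ``sum_i amplitudes[i] * basis_i(u, v)`` with
    basis ``{1, u, v, u*v, u^2 - v^2, u^2 + v^2}``; the temporal trace is
    a respiratory sinusoid plus a linear drift:

        trace(t) = sin(2 pi freq_hz t + phase_lag) + drift_per_s * t

    and the phase map at time ``t`` is ``trace(t) * spatial pattern``
    (radians).  ``shot_tr`` spaces consecutive shots in seconds; time
    advances continuously across volumes.
    """

    amplitudes: tuple[float, ...] = (0.0,) * N_BASIS
    freq_hz: float = 0.25
    phase_lag: float = 0.0
    drift_per_s: float = 0.0
    jitter_std: float = 0.0
    jitter_seed: int = 0
    jitter_band: tuple[float, float] = (0.05, 0.5)
    shot_tr: float = 0.06

    def __post_init__(self) -> None:
        if len(self.amplitudes) != N_BASIS:
            raise ValueError(f"amplitudes must have {N_BASIS} entries")
        if self.shot_tr <= 0:
            raise ValueError("shot_tr must be > 0")
        if self.jitter_std < 0:
            raise ValueError("jitter_std must be >= 0")
        # broadband jitter: a fixed bank of random sinusoids (deterministic
        # given jitter_seed), std jitter_std over long windows
        rng = np.random.default_rng(self.jitter_seed)
        k = 16
        freqs = rng.uniform(self.jitter_band[0], self.jitter_band[1], size=k)
        phases = rng.uniform(0.0, 2 * np.pi, size=k)
        object.__setattr__(self, "_jitter_freqs", tuple(freqs))
        object.__setattr__(self, "_jitter_phases", tuple(phases))

    def trace(self, t: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.sin(2 * np.pi * self.freq_hz * t + self.phase_lag) + self.drift_per_s * t
        if self.jitter_std > 0:
            f = np.asarray(self._jitter_freqs)
            p = np.asarray(self._jitter_phases)
            comps = np.sin(2 * np.pi * np.multiply.outer(t, f) + p)
            out = out + self.jitter_std * np.sqrt(2.0 / f.size) * comps.sum(axis=-1)
        return out if out.ndim else float(out)

    def zeroed(self) -> "PhaseModel":
        """Matched phase-free model (all amplitudes zero)."""
        return replace(self, amplitudes=(0.0,) * N_BASIS)


@dataclass(frozen=True)
class NoiseSpec:
    """Complex Gaussian noise std per k-space sample (real and imaginary
    parts each have std ``sigma / sqrt(2)``), plus the base seed."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _grid_uv(ny: int, nz: int) -> tuple[np.ndarray, np.ndarray]:
    u = np.linspace(-1.0, 1.0, ny)
    v = np.linspace(-1.0, 1.0, nz)
    return np.meshgrid(u, v, indexing="ij")


def _ellipse(u, v, cu, cv, a, b, angle=0.0):
    ca, sa = np.cos(angle), np.sin(angle)
    ur = ca * (u - cu) + sa * (v - cv)
    vr = -sa * (u - cu) + ca * (v - cv)
    return (ur / a) ** 2 + (vr / b) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> np.ndarray:
    """Deterministic complex phantom with internal structure.

    ``shepp_logan_variant`` stacks ellipses of different intensities so
    ghosting artifacts are visible; ``smooth_blobs`` sums Gaussian lobes.
    Magnitude is normalized to max 1 and vanishes strictly inside the grid.
    """
    u, v = _grid_uv(spec.ny, spec.nz)
    u, v = u / spec.support_scale, v / spec.support_scale
    if spec.structure == "shepp_logan_variant":
        mag = np.zeros((spec.ny, spec.nz))
        mag += 0.8 * _ellipse(u, v, 0.0, 0.0, 0.78, 0.88)
        mag += 0.2 * _ellipse(u, v, 0.0, 0.02, 0.66, 0.76)
        mag -= 0.35 * _ellipse(u, v, -0.22, 0.0, 0.16, 0.32, angle=0.3)
        mag -= 0.35 * _ellipse(u, v, 0.22, 0.0, 0.12, 0.32, angle=-0.3)
        mag += 0.25 * _ellipse(u, v, 0.0, -0.45, 0.14, 0.14)
        mag += 0.4 * _ellipse(u, v, 0.0, 0.38, 0.08, 0.12)
        mag += 0.3 * _ellipse(u, v, -0.35, 0.45, 0.07, 0.07)
        mag = np.clip(mag, 0.0, None)
    else:
        mag = np.zeros((spec.ny, spec.nz))
        for cu, cv, s, a in [
            (-0.3, -0.3, 0.25, 1.0),
            (0.35, 0.1, 0.2, 0.8),
            (-0.05, 0.4, 0.18, 0.9),
            (0.1, -0.25, 0.3, 0.6),
        ]:
            mag += a * np.exp(-(((u - cu) ** 2 + (v - cv) ** 2) / (2 * s**2)))
        mag *= _ellipse(u, v, 0.0, 0.0, 0.85, 0.85)  # keep support inside grid
    peak = mag.max()
    if peak > 0:
        mag = mag / peak
    c0, c1, c2, c3 = spec.phase_coeffs
    phase = c0 + c1 * u + c2 * v + c3 * u * v
    out = mag * np.exp(1j * phase)
    if np.allclose(spec.phase_coeffs, 0.0):
        out = out.real.astype(np.complex128)  # exactly real-valued
    return out


def make_coil_maps(n_coils: int, grid: tuple[int, int], seed: int = 0) -> np.ndarray:
    """Smooth complex coil profiles: Gaussian magnitude lobes placed on a
    ring around the FOV with per-coil linear phase, normalized so the
    root-sum-of-squares is exactly 1 everywhere."""
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    ny, nz = grid
    u, v = _grid_uv(ny, nz)
    rng = np.random.default_rng(seed)
    maps = np.empty((n_coils, ny, nz), dtype=np.complex128)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(-0.15, 0.15)
        cu, cv = 1.15 * np.cos(ang), 1.15 * np.sin(ang)
        sig = 0.9 + rng.uniform(-0.1, 0.1)
        mag = np.exp(-(((u - cu) ** 2 + (v - cv) ** 2) / (2 * sig**2)))
        lin = rng.uniform(-1.0, 1.0, size=2)
        maps[c] = mag * np.exp(1j * (lin[0] * u + lin[1] * v))
    return normalize_maps(maps)


def harmonic_basis(grid: tuple[int, int]) -> np.ndarray:
    """The 6 second-order 2D harmonic maps ``{1, u, v, uv, u^2-v^2,
    u^2+v^2}`` on normalized coordinates, shape (6, ny, nz)."""
    u, v = _grid_uv(*grid)
    return np.stack([np.ones_like(u), u, v, u * v, u**2 - v**2, u**2 + v**2])


def phase_map_at(t: float, model: PhaseModel, grid: tuple[int, int]) -> np.ndarray:
    """Evaluate the phase map (radians) at time ``t`` seconds."""
    basis = harmonic_basis(grid)
    spatial = np.tensordot(np.asarray(model.amplitudes), basis, axes=1)
    return float(model.trace(t)) * spatial


def shot_time(timestamp: int, model: PhaseModel, volume: int, n_shots: int) -> float:
    """Acquisition time of a shot: continuous across volumes."""
    return (volume * n_shots + timestamp) * model.shot_tr


def group_mean_times(
    schedule: ShotSchedule, model: PhaseModel, volume: int = 0
) -> np.ndarray:
    """Mean acquisition time per shot group within one volume."""
    n = len(schedule.shots)
    times = np.zeros(schedule.n_groups)
    counts = np.zeros(schedule.n_groups)
    for s in schedule.shots:
        times[s.group] += shot_time(s.timestamp, model, volume, n)
        counts[s.group] += 1
    return times / counts


def simulate_timeseries(
    phantom: np.ndarray,
    maps: np.ndarray,
    schedule: ShotSchedule,
    model: PhaseModel,
    noise: NoiseSpec = NoiseSpec(),
    n_volumes: int = 1,
    start_volume: int = 0,
) -> list[AcquiredData]:
    """Synthesize per-volume multi-coil shot-group k-space.

    Each shot, at its continuous acquisition time, sees the phantom
    modulated by the instantaneous phase map; the modulated image is
    weighted by every coil map, Fourier transformed, and the shot's
    (ky, kz) lines are extracted into its group's k-space.  Complex
    Gaussian noise is added on acquired samples only; the draws depend
    only on ``(noise.seed, volume index)``, never on the phase model, so
    a phase-free rerun with the same spec sees identical noise.
    """
    phantom = np.asarray(phantom, dtype=np.complex128)
    c = schedule.config
    if phantom.shape != (c.ny, c.nz):
        raise ValueError(
            f"phantom shape {phantom.shape} does not match schedule grid {(c.ny, c.nz)}"
        )
    masks = np.stack(group_masks(schedule))
    n_coils = maps.shape[0]
    n_shots = len(schedule.shots)
    basis = harmonic_basis((c.ny, c.nz))
    spatial = np.tensordot(np.asarray(model.amplitudes), basis, axes=1)
    volumes: list[AcquiredData] = []
    for vi in range(n_volumes):
        vol = start_volume + vi
        y = np.zeros((schedule.n_groups, n_coils, c.ny, c.nz), dtype=np.complex128)
        for shot in schedule.shots:
            t = shot_time(shot.timestamp, model, vol, n_shots)
            img = phantom * np.exp(1j * float(model.trace(t)) * spatial)
            k = fft2c(maps * img[None])
            ky, kz = shot.lines[:, 0], shot.lines[:, 1]
            y[shot.group][:, ky, kz] = k[:, ky, kz]
        if noise.sigma > 0:
            rng = np.random.default_rng([noise.seed, vol])
            draw = rng.standard_normal(y.shape) + 1j * rng.standard_normal(y.shape)
            y += noise.sigma / np.sqrt(2.0) * draw * masks[:, None]
        volumes.append(AcquiredData(y=y, masks=masks.copy()))
    return volumes


def simulate_pair(
    phantom: np.ndarray,
    maps: np.ndarray,
    schedule: ShotSchedule,
    model: PhaseModel,
    noise: NoiseSpec = NoiseSpec(),
    n_volumes: int = 1,
) -> tuple[list[AcquiredData], list[AcquiredData]]:
    """Corrupted series plus the matched phase-free reference series
    (identical noise draws)."""
    corrupted = simulate_timeseries(phantom, maps, schedule, model, noise, n_volumes)
    reference = simulate_timeseries(
        phantom, maps, schedule, model.zeroed(), noise, n_volumes
    )
    return corrupted, reference


def snr_calibrate(
    target_snr: float,
    phantom: np.ndarray,
    maps: np.ndarray | None = None,
    support_fraction: float = 0.1,
    seed: int = 0,
) -> NoiseSpec:
    """Noise std achieving a target image-domain support SNR.

    SNR is defined as the mean phantom magnitude over its support
    (voxels >= ``support_fraction`` of the peak) divided by the complex
    noise std of the coil-combined image.  Under unitary transforms and
    unit-RSS maps that image noise std equals the per-sample k-space
    std, so ``sigma = mean_support / target`` in closed form.
    """
    if target_snr <= 0:
        raise ValueError("target_snr must be > 0")
    mag = np.abs(np.asarray(phantom))
    support = mag >= support_fraction * mag.max()
    mean_signal = float(mag[support].mean())
    return NoiseSpec(sigma=mean_signal / target_snr, seed=seed)
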