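"""Shot-schedule generation for multi-shot 3D-EPI ky-kz sampling.

Two schemes are supported on the ky-kz phase-encoding plane:

``standard``
    Conventional blipped-CAIPI with sequential kz ordering: consecutive
    shots are offset by ``rz`` along kz, each shot spans a kz band of
    height ``rz`` through which the per-line CAIPI blip cycles.

``seg_caipi``
    Segmented CAIPI: the kz axis is traversed in ``N = width / rz``
    interleaves.  Consecutive shots of one interleave are offset by
    ``width`` along kz and each shot spans a band of height ``width``,
    so blip sizes >= ``rz`` are permitted.  Interleave ``j`` is offset
    by ``j * rz`` along kz.  Shots of one interleave form one shot
    group, giving every group a near-uniform ``ry x width`` lattice.

Within a shot, line ``n`` (sampled ky index ``n * ry``) sits at kz
offset ``(n * dkz) mod width`` inside the shot's band; band positions
wrap modulo ``nz`` at the top edge of the grid so every scheme covers
exactly the same combined lattice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
import numpy as np

__all__ = [
    "SCHEMES",
    "ConfigurationError",
    "ScheduleIntegrityError",
    "TrajectoryConfig",
    "Shot",
    "ShotSchedule",
    "build_schedule",
    "group_masks",
    "combined_mask",
    "suggest_dkz",
    "schedule_to_json",
    "schedule_from_json",
    "save_masks_png",
    "save_masks_hdf5",
]

SCHEMES = ("standard", "seg_caipi")


class ConfigurationError(ValueError):
    """A trajectory configuration violates a divisibility or range constraint."""


class ScheduleIntegrityError(RuntimeError):
    """A schedule's shots overlap or fail to partition the combined lattice."""


@dataclass(frozen=True)
class TrajectoryConfig:
    """Geometry and under-sampling parameters of a ky-kz shot schedule.

    Parameters
    ----------
    ny, nz : int
        Grid size along ky and kz.
    ry, rz : int
        Under-sampling factors along ky and along the shot (kz) dimension.
    width : int, optional
        kz offset between two consecutive shots with identical
        trajectories; also the kz span of each shot.  Defaults to ``rz``
        (mandatory value for the ``standard`` scheme).  For
        ``seg_caipi`` it must be an integer multiple of ``rz``.
    dkz : int
        CAIPI blip size along kz applied per sampled ky line.
    scheme : {"standard", "seg_caipi"}
    ky_offset : int
        Global ky phase offset of the sampled ky comb (0 <= offset < ry).
    """

    ny: int
    nz: int
    ry: int = 1
    rz: int = 1
    width: int | None = None
    dkz: int = 0
    scheme: str = "standard"
    ky_offset: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ConfigurationError(
                f"scheme must be one of {SCHEMES}, got {self.scheme!r}"
            )
        for name in ("ny", "nz", "ry", "rz"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        if self.width is None:
            object.__setattr__(self, "width", self.rz)
        w = self.width
        if not isinstance(w, (int, np.integer)) or w < 1:
            raise ConfigurationError(f"width must be a positive integer, got {w!r}")
        if self.scheme == "standard" and w != self.rz:
            raise ConfigurationError(
                f"standard scheme requires width == rz ({self.rz}), got width={w}"
            )
        if self.scheme == "seg_caipi" and w % self.rz != 0:
            raise ConfigurationError(
                f"seg_caipi requires width to be a multiple of rz={self.rz}, got width={w}"
            )
        # ky under-sampling tolerates non-divisible ny (ceil(ny/ry) lines,
        # as acquired matrices are not always multiples of ry)
        if self.ny < self.ry:
            raise ConfigurationError(f"ny={self.ny} smaller than ry={self.ry}")
        if self.nz % w != 0:
            raise ConfigurationError(f"nz={self.nz} not divisible by width={w}")
        if self.nz % self.rz != 0:
            raise ConfigurationError(f"nz={self.nz} not divisible by rz={self.rz}")
        if not 0 <= self.dkz < w:
            raise ConfigurationError(
                f"dkz must satisfy 0 <= dkz < width={w}, got dkz={self.dkz}"
            )
        if not 0 <= self.ky_offset < self.ry:
            raise ConfigurationError(
                f"ky_offset must satisfy 0 <= ky_offset < ry={self.ry}, got {self.ky_offset}"
            )

    # -- derived counts ---------------------------------------------------
    @property
    def n_interleaves(self) -> int:
        return self.width // self.rz

    @property
    def n_groups(self) -> int:
        """Shot groups = interleaves (width / rz)."""
        return self.n_interleaves

    @property
    def n_shots(self) -> int:
        return self.nz // self.rz

    @property
    def shots_per_group(self) -> int:
        return self.nz // self.width

    @property
    def lines_per_shot(self) -> int:
        return -(-self.ny // self.ry)  # ceil: ky comb covers the whole grid


@dataclass(frozen=True)
class Shot:
    """One excitation's readout train on the ky-kz plane.

    ``lines`` is an ``(n_lines, 2)`` integer array of (ky, kz) indices in
    acquisition order; ``timestamp`` is the global shot acquisition index.
    """

    lines: np.ndarray
    interleave: int
    group: int
    timestamp: int


@dataclass(frozen=True)
class ShotSchedule:
    """An ordered collection of shots plus the generating configuration."""

    config: TrajectoryConfig
    shots: tuple[Shot, ...]

    @property
    def n_groups(self) -> int:
        return len({s.group for s in self.shots})

    def shots_in_group(self, group: int) -> list[Shot]:
        return [s for s in self.shots if s.group == group]


def build_schedule(config: TrajectoryConfig) -> ShotSchedule:
    """Generate the full shot schedule for ``config``.

    Shots are emitted interleave-major: all shots of interleave 0 in
    ascending kz-origin order, then interleave 1, and so on; the global
    timestamp records that ordering.  Each interleave is one shot group.
    """
    c = config
    w = c.width
    n = np.arange(c.lines_per_shot)
    ky = c.ky_offset + n * c.ry
    blip = (n * c.dkz) % w
    shots: list[Shot] = []
    ts = 0
    for j in range(c.n_interleaves):
        for s in range(c.shots_per_group):
            origin = j * c.rz + s * w
            kz = (origin + blip) % c.nz
            lines = np.stack([ky, kz], axis=1)
            lines.setflags(write=False)
            shots.append(Shot(lines=lines, interleave=j, group=j, timestamp=ts))
            ts += 1
    return ShotSchedule(config=c, shots=tuple(shots))


def group_masks(schedule: ShotSchedule) -> list[np.ndarray]:
    """Binary ``(ny, nz)`` sampling mask per shot group.

    Raises
    ------
    ScheduleIntegrityError
        If any line is claimed twice (within or across groups).
    """
    c = schedule.config
    counts = np.zeros((c.n_groups, c.ny, c.nz), dtype=np.int64)
    for shot in schedule.shots:
        counts[shot.group, shot.lines[:, 0], shot.lines[:, 1]] += 1
    if counts.max() > 1:
        raise ScheduleIntegrityError("a (ky, kz) line was acquired more than once within a group")
    total = counts.sum(axis=0)
    if total.max() > 1:
        raise ScheduleIntegrityError("shot groups overlap: a line appears in multiple groups")
    return [counts[g].astype(bool) for g in range(c.n_groups)]


def combined_mask(schedule: ShotSchedule) -> np.ndarray:
    """Union of all shots' lines; has exactly ``(ny/ry) * (nz/rz)`` ones."""
    c = schedule.config
    mask = np.zeros((c.ny, c.nz), dtype=bool)
    for shot in schedule.shots:
        mask[shot.lines[:, 0], shot.lines[:, 1]] = True
    expected = c.lines_per_shot * c.n_shots
    if int(mask.sum()) != expected:
        raise ScheduleIntegrityError(
            f"combined mask has {int(mask.sum())} ones, expected {expected}"
        )
    return mask


def suggest_dkz(config: TrajectoryConfig) -> int:
    """Advisory blip-size search: pick dkz in [1, width) minimizing the
    largest distance from any grid point to its nearest sample within a
    single shot-group mask.  Configurations always take an explicit dkz;
    this helper only reports the minimizer (ties broken by smaller dkz).
    """
    from scipy.ndimage import distance_transform_edt

    best_dkz, best_cost = None, np.inf
    for dkz in range(1, config.width):
        try:
            cand = replace(config, dkz=dkz)
        except ConfigurationError:
            continue
        mask = group_masks(build_schedule(cand))[0]
        # covering radius of the group lattice (wrap-agnostic, advisory)
        cost = float(distance_transform_edt(~mask).max())
        if cost < best_cost - 1e-12:
            best_dkz, best_cost = dkz, cost
    if best_dkz is None:
        raise ConfigurationError("no admissible dkz in [1, width)")
    return best_dkz


# -- serialization --------------------------------------------------------

def schedule_to_json(schedule: ShotSchedule) -> str:
    c = schedule.config
    payload = {
        "config": {
            "ny": c.ny, "nz": c.nz, "ry": c.ry, "rz": c.rz,
            "width": c.width, "dkz": c.dkz, "scheme": c.scheme,
            "ky_offset": c.ky_offset,
        },
        "shots": [
            {
                "timestamp": s.timestamp,
                "interleave": s.interleave,
                "group": s.group,
                "lines": s.lines.tolist(),
            }
            for s in schedule.shots
        ],
    }
    return json.dumps(payload, indent=1)


def schedule_from_json(text: str) -> ShotSchedule:
    payload = json.loads(text)
    config = TrajectoryConfig(**payload["config"])
    shots = tuple(
        Shot(
            lines=np.asarray(s["lines"], dtype=np.int64),
            interleave=s["interleave"],
            group=s["group"],
            timestamp=s["timestamp"],
        )
        for s in sorted(payload["shots"], key=lambda s: s["timestamp"])
    )
    return ShotSchedule(config=config, shots=shots)


def save_masks_png(schedule: ShotSchedule, path: str) -> None:
    """Render the per-group masks side by side (group index as gray level)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    masks = group_masks(schedule)
    img = np.zeros(masks[0].shape, dtype=float)
    for g, m in enumerate(masks):
        img[m] = g + 1
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(img.T, origin="lower", interpolation="nearest", cmap="viridis")
    ax.set_xlabel("ky")
    ax.set_ylabel("kz")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_masks_hdf5(schedule: ShotSchedule, path: str) -> None:
    import h5py

    masks = np.stack(group_masks(schedule)).astype(np.uint8)
    with h5py.File(path, "w") as f:
        f.create_dataset("masks", data=masks)
        f.create_dataset("combined_mask", data=combined_mask(schedule).astype(np.uint8))
        for k, v in vars(schedule.config).items():
            f.attrs[k] = v
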