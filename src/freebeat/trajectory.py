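"""Ordered pseudo-radial (OPRA) Cartesian sampling schedules.

The readout direction (kx, feet-head) is always fully sampled; undersampling
happens in the (ky, kz) phase-encode plane.  Phase encodes are acquired along
"L"-shaped leaflets — two perpendicular arms meeting at the k-space center —
that rotate by the golden angle from one leaflet to the next.  Sample radii
follow a power law so low spatial frequencies are revisited far more often
than high ones, giving a variable-density pattern with small jumps between
consecutive readouts (gentle on eddy currents).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Golden-angle increment in degrees, 180 / golden ratio ~ 111.246 (the
#: radial-MRI convention); successive leaflet orientations tile [0, 180)
#: as uniformly as possible.
GOLDEN_ANGLE_DEG: float = 180.0 * (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class SamplingSchedule:
    """Ordered phase-encode schedule for a Cartesian acquisition.

    ``readouts`` is an (n, 2) integer array of (ky, kz) grid coordinates in
    acquisition order; each readout spans the full kx line.
    """

    readouts: np.ndarray
    matrix: tuple[int, int, int]  # (Nx, Ny, Nz)
    tr_ms: float
    golden_angle_deg: float = GOLDEN_ANGLE_DEG

    def __post_init__(self) -> None:
        r = np.asarray(self.readouts)
        if r.ndim != 2 or r.shape[1] != 2:
            raise ValueError("readouts must be an (n, 2) array of (ky, kz)")
        _, ny, nz = self.matrix
        if r.size and ((r[:, 0] < 0).any() or (r[:, 0] >= ny).any()
                       or (r[:, 1] < 0).any() or (r[:, 1] >= nz).any()):
            raise ValueError("readout coordinates outside the k-space matrix")

    def __len__(self) -> int:
        return self.readouts.shape[0]

    @property
    def timestamps_ms(self) -> np.ndarray:
        return np.arange(len(self)) * self.tr_ms


@dataclass(frozen=True)
class FrameBinning:
    """Grouping of consecutive readouts into real-time frames."""

    readouts_per_frame: int
    n_frames: int
    frame_duration_ms: float
    frame_rate_hz: float
    frame_indices: np.ndarray = field(repr=False, default=None)  # (n_frames, per_frame)

    def frame_mid_times_s(self) -> np.ndarray:
        """Midpoint time of each frame in seconds from acquisition start."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_duration_ms / 1000.0


def golden_angle_sequence(n_leaflets: int) -> np.ndarray:
    """Leaflet rotation angles in degrees, wrapped to [0, 360)."""
    if n_leaflets < 1:
        raise ValueError("n_leaflets must be >= 1")
    return (np.arange(n_leaflets) * GOLDEN_ANGLE_DEG) % 360.0


def _snap_unique(points: np.ndarray, taken: set, ny: int, nz: int) -> list[tuple[int, int]]:
    """Round continuous (ky, kz) points to grid, resolving in-leaflet duplicates
    by the nearest grid point not yet used in this leaflet."""
    out = []
    for p in points:
        iy, iz = int(round(p[0])), int(round(p[1]))
        iy = min(max(iy, 0), ny - 1)
        iz = min(max(iz, 0), nz - 1)
        if (iy, iz) not in taken:
            taken.add((iy, iz))
            out.append((iy, iz))
            continue
        # expanding square search for the nearest free grid point
        found = None
        for radius in range(1, max(ny, nz)):
            best = None
            for dy in range(-radius, radius + 1):
                for dz in range(-radius, radius + 1):
                    if max(abs(dy), abs(dz)) != radius:
                        continue
                    cy, cz = iy + dy, iz + dz
                    if not (0 <= cy < ny and 0 <= cz < nz):
                        continue
                    if (cy, cz) in taken:
                        continue
                    d2 = (cy - p[0]) ** 2 + (cz - p[1]) ** 2
                    if best is None or d2 < best[0]:
                        best = (d2, cy, cz)
            if best is not None:
                found = (best[1], best[2])
                break
        if found is None:
            raise ValueError("samples_per_leaflet exceeds grid capacity")
        taken.add(found)
        out.append(found)
    return out


def make_leaflet(
    matrix: tuple[int, int, int],
    angle_deg: float,
    samples_per_leaflet: int,
    density_exponent: float = 2.0,
) -> np.ndarray:
    """One "L"-shaped leaflet of (ky, kz) samples, rotated by ``angle_deg``.

    Two perpendicular arms meet at the k-space center; radii along each arm
    scale as (j / J_arm) ** density_exponent so samples cluster near the
    center.  The returned order traverses the first arm inward, passes the
    center exactly once, then the second arm outward — consecutive jumps
    stay small.
    """
    _, ny, nz = matrix
    J = samples_per_leaflet
    if J < 2:
        raise ValueError("samples_per_leaflet must be >= 2")
    if J > ny * nz:
        raise ValueError("samples_per_leaflet exceeds grid capacity")
    cy, cz = ny // 2, nz // 2
    r_max = min(ny, nz) / 2.0 - 1.0
    if r_max <= 0:
        raise ValueError("matrix too small for a leaflet")

    n_arm1 = (J - 1 + 1) // 2
    n_arm2 = (J - 1) - n_arm1
    theta = np.deg2rad(angle_deg)
    dirs = [
        np.array([np.cos(theta), np.sin(theta)]),
        np.array([-np.sin(theta), np.cos(theta)]),
    ]

    def arm(n: int, d: np.ndarray) -> np.ndarray:
        if n == 0:
            return np.empty((0, 2))
        j = np.arange(1, n + 1)
        r = r_max * (j / n) ** density_exponent
        return np.array([cy, cz]) + r[:, None] * d[None, :]

    a1 = arm(n_arm1, dirs[0])[::-1]  # outermost -> innermost
    a2 = arm(n_arm2, dirs[1])        # innermost -> outermost
    taken: set = {(cy, cz)}  # center reserved; emitted between the arms
    pts = _snap_unique(a1, taken, ny, nz) + [(cy, cz)] + _snap_unique(a2, taken, ny, nz)
    return np.asarray(pts, dtype=np.int64)


def build_schedule(
    n_readouts: int,
    matrix: tuple[int, int, int],
    tr_ms: float,
    samples_per_leaflet: int = 20,
    density_exponent: float = 2.0,
) -> SamplingSchedule:
    """Concatenate golden-angle-rotated leaflets, truncated to ``n_readouts``."""
    if n_readouts < samples_per_leaflet:
        raise ValueError("n_readouts must be >= samples_per_leaflet")
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    n_leaflets = int(np.ceil(n_readouts / samples_per_leaflet))
    angles = golden_angle_sequence(n_leaflets)
    parts = [
        make_leaflet(matrix, a, samples_per_leaflet, density_exponent)
        for a in angles
    ]
    readouts = np.concatenate(parts, axis=0)[:n_readouts]
    return SamplingSchedule(readouts=readouts, matrix=tuple(matrix), tr_ms=float(tr_ms))


def bin_frames(schedule: SamplingSchedule, readouts_per_frame: int) -> FrameBinning:
    """Group consecutive readouts into frames; a trailing incomplete frame is
    discarded."""
    total = len(schedule)
    if readouts_per_frame < 1:
        raise ValueError("readouts_per_frame must be >= 1")
    if readouts_per_frame > total:
        raise ValueError("readouts_per_frame exceeds total readouts")
    n_frames = total // readouts_per_frame
    duration, rate = frame_timing(schedule.tr_ms, readouts_per_frame)
    idx = np.arange(n_frames * readouts_per_frame).reshape(n_frames, readouts_per_frame)
    return FrameBinning(
        readouts_per_frame=readouts_per_frame,
        n_frames=n_frames,
        frame_duration_ms=duration,
        frame_rate_hz=rate,
        frame_indices=idx,
    )


def frame_timing(tr_ms: float, readouts_per_frame: int) -> tuple[float, float]:
    """(frame duration in ms, frame rate in Hz) for a given TR and binning."""
    if tr_ms <= 0 or readouts_per_frame <= 0:
        raise ValueError("tr_ms and readouts_per_frame must be positive")
    duration = tr_ms * readouts_per_frame
    return duration, 1000.0 / duration
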