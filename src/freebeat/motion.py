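"""Explicit low-rank representation of real-time 3D displacement fields.

The space-time displacement matrix D (N voxels x 3 components by M frames)
is factored as D = Phi @ Psi.T with R << min(M, 3N): Phi holds R spatial
basis fields, Psi the matching temporal weights.  Expanding a single frame
is one small matrix-vector product, and the factorization keeps the
parameter count at (3N + M) * R instead of 3N * M.

Temporal smoothness is enforced by projecting Psi through a zero-phase
Butterworth low-pass filter (default cutoff 4 Hz, well above cardiac
frequencies); spatial resolution follows a dyadic coarse-to-fine pyramid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal


@dataclass
class LowRankMotion:
    """Low-rank displacement model D = Phi @ Psi.T.

    Phi : (3 * prod(grid_shape), R) spatial basis, displacements in voxels
          of the *current* grid.
    Psi : (M, R) temporal basis.
    """

    Phi: np.ndarray
    Psi: np.ndarray
    grid_shape: tuple[int, int, int]
    full_shape: tuple[int, int, int]
    rank: int
    frame_rate_hz: float

    def __post_init__(self) -> None:
        n = 3 * int(np.prod(self.grid_shape))
        if self.Phi.shape != (n, self.rank):
            raise ValueError(f"Phi must have shape ({n}, {self.rank})")
        if self.Psi.ndim != 2 or self.Psi.shape[1] != self.rank:
            raise ValueError("Psi must be (M, R)")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")

    @property
    def n_frames(self) -> int:
        return self.Psi.shape[0]

    def expand(self, t: int) -> np.ndarray:
        """Dense displacement field (3, *grid_shape) at frame index ``t``."""
        if not 0 <= t < self.n_frames:
            raise IndexError(f"frame index {t} out of range [0, {self.n_frames})")
        return (self.Phi @ self.Psi[t]).reshape((3,) + tuple(self.grid_shape))

    def n_parameters(self) -> int:
        return self.Phi.size + self.Psi.size


@dataclass(frozen=True)
class PyramidSchedule:
    """Coarse-to-fine grids and how many motion iterations to spend on each."""

    levels: list[tuple[tuple[int, int, int], int]]

    @property
    def total_iterations(self) -> int:
        return sum(n for _, n in self.levels)


def init_temporal(
    M: int,
    R: int,
    frame_rate_hz: float,
    f_lo: float = 0.5,
    f_hi: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Random smooth oscillations: Psi[:, r] = sin(2 pi f_r t + phi_r),
    f_r ~ U(f_lo, f_hi), phi_r ~ U(0, 2 pi)."""
    if M < 2 or R < 1:
        raise ValueError("need M >= 2 and R >= 1")
    if f_hi > frame_rate_hz / 2:
        raise ValueError("f_hi exceeds the Nyquist frequency")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(f_lo, f_hi, size=R)
    phases = rng.uniform(0.0, 2 * np.pi, size=R)
    t = np.arange(M) / frame_rate_hz
    return np.sin(2 * np.pi * freqs[None, :] * t[:, None] + phases[None, :])


def lowpass_temporal(
    Psi: np.ndarray,
    frame_rate_hz: float,
    cutoff_hz: float = 4.0,
    order: int = 5,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass applied to each temporal basis column.

    Forward-backward filtering (filtfilt) squares the magnitude response and
    cancels phase; DC gain is exactly 1, so constant columns pass unchanged.
    """
    if cutoff_hz >= frame_rate_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    b, a = signal.butter(order, cutoff_hz, fs=frame_rate_hz, btype="low")
    return signal.filtfilt(b, a, Psi, axis=0)


def _resize_field(field: np.ndarray, to_grid: tuple[int, int, int]) -> np.ndarray:
    """Trilinear, align-corners resize of a (3, *grid) field with per-axis
    magnitude rescaling so physical (mm) displacements are preserved."""
    src = field.shape[1:]
    coords = np.meshgrid(
        *[
            np.linspace(0.0, s - 1.0, t) if t > 1 else np.zeros(1)
            for s, t in zip(src, to_grid)
        ],
        indexing="ij",
    )
    out = np.empty((3,) + tuple(to_grid), dtype=field.dtype)
    for c in range(3):
        ratio = to_grid[c] / src[c]
        out[c] = ndimage.map_coordinates(
            field[c], coords, order=1, mode="nearest"
        ) * ratio
    return out


def upsample_spatial(model: LowRankMotion, to_grid: tuple[int, int, int]) -> LowRankMotion:
    """Interpolate every spatial basis column to a finer grid.

    Displacement values are multiplied by the per-axis grid ratio so that the
    represented physical displacement is unchanged; Psi is untouched.
    """
    to_grid = tuple(int(g) for g in to_grid)
    if any(t < c for t, c in zip(to_grid, model.grid_shape)):
        raise ValueError("upsample_spatial cannot reduce the grid")
    if to_grid == tuple(model.grid_shape):
        return model
    n_new = 3 * int(np.prod(to_grid))
    Phi_new = np.empty((n_new, model.rank), dtype=model.Phi.dtype)
    for r in range(model.rank):
        col = model.Phi[:, r].reshape((3,) + tuple(model.grid_shape))
        Phi_new[:, r] = _resize_field(col, to_grid).ravel()
    return replace(model, Phi=Phi_new, grid_shape=to_grid)


def make_pyramid(
    full_grid: tuple[int, int, int],
    n_levels: int = 3,
    coarse_iters: int = 30,
    min_size: int = 8,
) -> PyramidSchedule:
    """Dyadic coarse-to-fine schedule: grids full/2^(L-1) ... full, with
    ``coarse_iters`` split evenly (remainder to the coarsest level)."""
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    grids = []
    for lvl in range(n_levels):
        factor = 2 ** (n_levels - 1 - lvl)
        g = tuple(max(1, s // factor) for s in full_grid)
        grids.append(g)
    # drop leading levels that undershoot the minimum usable size
    usable = [g for g in grids if min(g) >= min_size or g == grids[-1]]
    if len(usable) < len(grids):
        warnings.warn(
            f"grid too small to halve {len(grids) - len(usable)} time(s); "
            f"using {len(usable)} pyramid level(s)",
            stacklevel=2,
        )
    grids = usable
    L = len(grids)
    base, rem = divmod(coarse_iters, L)
    iters = [base + (1 if lvl < rem else 0) for lvl in range(L)]
    return PyramidSchedule(levels=list(zip(grids, iters)))
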