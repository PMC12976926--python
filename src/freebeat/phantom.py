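"""Deformable two-ventricle digital phantom with analytic ground truth.

The phantom mimics a silicone cardiac insert: a soft "body" ellipsoid
containing two fluid-filled cavities shaped like the right and left
ventricles, each wrapped in a thin darker shell.  A piston-like drive scales
every ventricle's semi-axes by

    s(t) = 1 - a * m_k * (1 - cos(2 pi phase)) / 2

within beat k (amplitude multiplier m_k), so t = 0 is end-diastole (s = 1,
zero displacement) and the cavity volume follows s(t)**3 exactly.  The
displacement field is analytic and — by design — exactly low-rank: one fixed
spatial profile per ventricle modulated by a scalar amplitude

    u(x, t) = alpha_v(t) * (x - c_v) * w(rho_v(x)),   alpha = 1/s - 1,

where rho is the reference-ellipsoid normalized radius and w a C^1
smoothstep falloff (1 inside the cavity, 0 beyond ``falloff_rho``).  On the
cavity interior this is pure semi-axis scaling, so ground-truth volumes,
per-beat ejection fractions and EF statistics all have closed forms.

An irregular-beat mode (``pvc_schedule``) draws premature-contraction beats
with reduced amplitude and shortened interval, producing the bimodal
per-beat EF distributions characteristic of arrhythmia.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from freebeat.motion import LowRankMotion


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    intensity: float = 1.0


@dataclass(frozen=True)
class BeatSchedule:
    """Per-beat (interval_s, amplitude_multiplier) pairs, repeated cyclically."""

    intervals_s: np.ndarray
    amplitude_mults: np.ndarray

    def __post_init__(self) -> None:
        if len(self.intervals_s) != len(self.amplitude_mults) or len(self.intervals_s) == 0:
            raise ValueError("schedule arrays must be non-empty and equal length")
        if (np.asarray(self.intervals_s) <= 0).any():
            raise ValueError("beat intervals must be positive")

    @property
    def n_beats(self) -> int:
        return len(self.intervals_s)

    @property
    def total_duration_s(self) -> float:
        return float(np.sum(self.intervals_s))


def uniform_schedule(n_beats: int, beat_rate_cpm: float) -> BeatSchedule:
    interval = 60.0 / beat_rate_cpm
    return BeatSchedule(
        intervals_s=np.full(n_beats, interval),
        amplitude_mults=np.ones(n_beats),
    )


def pvc_schedule(
    n_beats: int,
    base_interval_s: float,
    pvc_fraction: float,
    pvc_amplitude_mult: float,
    pvc_interval_mult: float = 0.7,
    seed: int = 0,
) -> BeatSchedule:
    """Random beat schedule with a fraction of premature (PVC-like) beats.

    PVC beats have their contraction amplitude multiplied by
    ``pvc_amplitude_mult`` and their interval by ``pvc_interval_mult``.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if not (0.0 <= pvc_fraction <= 1.0 and 0.0 <= pvc_amplitude_mult <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    if pvc_interval_mult <= 0:
        raise ValueError("pvc_interval_mult must be positive")
    rng = np.random.default_rng(seed)
    is_pvc = rng.random(n_beats) < pvc_fraction
    intervals = np.where(is_pvc, base_interval_s * pvc_interval_mult, base_interval_s)
    mults = np.where(is_pvc, pvc_amplitude_mult, 1.0)
    return BeatSchedule(intervals_s=intervals, amplitude_mults=mults)


def amplitude_for_ef(ef_pct: float) -> float:
    """Contraction amplitude giving a target EF under isotropic scaling
    (V proportional to s**3): EF = 1 - (1 - a)**3."""
    if not 0.0 <= ef_pct < 100.0:
        raise ValueError("ef_pct must be in [0, 100)")
    return 1.0 - (1.0 - ef_pct / 100.0) ** (1.0 / 3.0)


def beat_efs(schedule: BeatSchedule, amplitude: float) -> np.ndarray:
    """Closed-form per-beat EF (%) for a ventricle of the given amplitude."""
    s_min = 1.0 - amplitude * schedule.amplitude_mults
    return (1.0 - s_min**3) * 100.0


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    body: Ellipsoid = Ellipsoid((23.5, 23.5, 23.5), (21.0, 22.0, 21.0), 0.35)
    ventricles: tuple[Ellipsoid, Ellipsoid] = (
        Ellipsoid((16.0, 24.0, 24.0), (7.0, 6.0, 6.0), 1.0),   # right ventricle
        Ellipsoid((32.0, 24.0, 24.0), (6.0, 6.0, 6.0), 1.0),   # left ventricle
    )
    ventricle_labels: tuple[str, str] = ("rv", "lv")
    target_label: str = "rv"
    myocardium_shell_thickness: float = 1.5
    shell_intensity: float = 0.15
    beat_rate_cpm: float = 60.0
    contraction_amplitude: float = dfield(default_factory=lambda: amplitude_for_ef(21.9))
    ef_ratio: float = 2.0  # target-ventricle EF / other-ventricle EF
    beat_schedule: BeatSchedule | None = None
    respiratory_amp_voxels: float = 0.0
    respiratory_rate_cpm: float = 15.0
    falloff_rho: float = 1.5
    edge_smoothness: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contraction_amplitude < 1.0:
            raise ValueError("contraction_amplitude must be in [0, 1)")
        if self.beat_rate_cpm <= 0:
            raise ValueError("beat_rate must be positive")
        if self.falloff_rho <= 1.0:
            raise ValueError("falloff_rho must exceed 1")
        for v in self.ventricles:
            if not _influence_inside(v, self.body, self.falloff_rho):
                raise ValueError(
                    f"ventricle at {v.center} (falloff x{self.falloff_rho}) "
                    "is not strictly inside the body ellipsoid"
                )


def _influence_inside(v: Ellipsoid, body: Ellipsoid, rho_out: float, n_dirs: int = 2000) -> bool:
    """Numeric ellipsoid-in-ellipsoid check on an angular sample of the
    ventricle's influence surface (semi-axes scaled by rho_out)."""
    rng = np.random.default_rng(12345)
    d = rng.standard_normal((n_dirs, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    pts = np.asarray(v.center) + rho_out * d * np.asarray(v.semi_axes)
    rho_body = np.sqrt(
        (((pts - np.asarray(body.center)) / np.asarray(body.semi_axes)) ** 2).sum(axis=1)
    )
    return bool((rho_body < 1.0).all())


def _smoothstep(z: np.ndarray) -> np.ndarray:
    z = np.clip(z, 0.0, 1.0)
    return z * z * (3.0 - 2.0 * z)


def _normalized_radius(grid: np.ndarray, e: Ellipsoid) -> np.ndarray:
    c = np.asarray(e.center, dtype=float)
    a = np.asarray(e.semi_axes, dtype=float)
    return np.sqrt((((grid - c[:, None, None, None]) / a[:, None, None, None]) ** 2).sum(axis=0))


def _soft_indicator(rho: np.ndarray, semi_axes, width: float) -> np.ndarray:
    # approximate signed distance (voxels) from the ellipsoid surface
    d = (rho - 1.0) * min(semi_axes)
    return _smoothstep(0.5 - d / max(width, 1e-6))


class PhantomScene:
    """Realized phantom: static reference anatomy plus analytic motion.

    All dynamics live in ``gt_displacement``; the reference volume is
    time-independent (end-diastolic).
    """

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        shape = tuple(spec.grid_shape)
        grid = np.stack(
            np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
        )
        # --- anatomy -------------------------------------------------------
        w = spec.edge_smoothness
        vol = spec.body.intensity * _soft_indicator(
            _normalized_radius(grid, spec.body), spec.body.semi_axes, w
        )
        self.gt_masks: dict[str, np.ndarray] = {}
        self._profiles: list[np.ndarray] = []
        self._amplitudes: dict[str, float] = {}
        target_ef = (1.0 - (1.0 - spec.contraction_amplitude) ** 3) * 100.0
        for label, vent in zip(spec.ventricle_labels, spec.ventricles):
            rho = _normalized_radius(grid, vent)
            shell = Ellipsoid(
                vent.center,
                tuple(a + spec.myocardium_shell_thickness for a in vent.semi_axes),
                spec.shell_intensity,
            )
            ind_shell = _soft_indicator(_normalized_radius(grid, shell), shell.semi_axes, w)
            ind_vent = _soft_indicator(rho, vent.semi_axes, w)
            vol = vol * (1 - ind_shell) + shell.intensity * ind_shell
            vol = vol * (1 - ind_vent) + vent.intensity * ind_vent
            self.gt_masks[label] = (rho <= 1.0).astype(np.uint8)
            # C^1 falloff weight in the *reference* normalized radius, so the
            # spatial profile of each ventricle is time-independent (rank 1).
            z = (rho - 1.0) / (spec.falloff_rho - 1.0)
            weight = np.where(rho <= 1.0, 1.0, 1.0 - _smoothstep(z))
            profile = (grid - np.asarray(vent.center)[:, None, None, None]) * weight[None]
            self._profiles.append(profile)
            if label == spec.target_label:
                self._amplitudes[label] = spec.contraction_amplitude
            else:
                self._amplitudes[label] = amplitude_for_ef(target_ef / spec.ef_ratio)
        self.reference_volume = vol.astype(np.complex128)
        self.voxel_size_mm = tuple(spec.voxel_size_mm)
        self._labels = list(spec.ventricle_labels)
        self.schedule = spec.beat_schedule or uniform_schedule(1, spec.beat_rate_cpm)
        target = spec.ventricles[self._labels.index(spec.target_label)]
        self._target_ref_volume_ml = (
            4.0 / 3.0 * np.pi * float(np.prod(target.semi_axes))
            * float(np.prod(spec.voxel_size_mm)) / 1000.0
        )
        self.gt_ef = target_ef

    # --- temporal dynamics ------------------------------------------------

    def _beat_phase(self, t: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(phase in [0,1), amplitude multiplier) of the beat containing t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        sched = self.schedule
        total = sched.total_duration_s
        tm = np.mod(t, total)
        ends = np.cumsum(sched.intervals_s)
        starts = ends - sched.intervals_s
        k = np.searchsorted(ends, tm, side="right")
        k = np.clip(k, 0, sched.n_beats - 1)
        phase = (tm - starts[k]) / sched.intervals_s[k]
        return phase, sched.amplitude_mults[k]

    def scale(self, t: float | np.ndarray, label: str | None = None) -> np.ndarray:
        """Semi-axis scale factor s(t) of a ventricle (default: target)."""
        label = label or self.spec.target_label
        a = self._amplitudes[label]
        phase, mult = self._beat_phase(t)
        s = 1.0 - a * mult * (1.0 - np.cos(2 * np.pi * phase)) / 2.0
        return s if np.ndim(t) else s[0]

    def gt_displacement(self, t_s: float) -> np.ndarray:
        """Dense backward displacement field (3, *grid) in voxels at time t."""
        field = np.zeros((3,) + tuple(self.spec.grid_shape))
        for label, profile in zip(self._labels, self._profiles):
            s = float(np.asarray(self.scale(t_s, label)).reshape(-1)[0])
            alpha = 1.0 / s - 1.0
            if alpha != 0.0:
                field += alpha * profile
        if self.spec.respiratory_amp_voxels:
            f = self.spec.respiratory_rate_cpm / 60.0
            field[0] += -self.spec.respiratory_amp_voxels * np.sin(2 * np.pi * f * t_s)
        return field

    def gt_volume(self, t_s: float | np.ndarray) -> np.ndarray:
        """Analytic target-ventricle volume (ml) at time(s) t."""
        return self._target_ref_volume_ml * self.scale(t_s) ** 3

    @property
    def target_mask(self) -> np.ndarray:
        return self.gt_masks[self.spec.target_label]

    def beat_efs(self) -> np.ndarray:
        """Closed-form per-beat EF (%) of the target ventricle."""
        return beat_efs(self.schedule, self._amplitudes[self.spec.target_label])

    def gt_motion_model(self, n_frames: int, frame_rate_hz: float) -> LowRankMotion:
        """Exact low-rank factorization of the ground-truth motion sampled at
        frame midpoints (one column per ventricle, plus drift if enabled)."""
        times = (np.arange(n_frames) + 0.5) / frame_rate_hz
        cols_phi, cols_psi = [], []
        for label, profile in zip(self._labels, self._profiles):
            s = self.scale(times, label)
            cols_phi.append(profile.reshape(-1))
            cols_psi.append(1.0 / s - 1.0)
        if self.spec.respiratory_amp_voxels:
            prof = np.zeros((3,) + tuple(self.spec.grid_shape))
            prof[0] = 1.0
            f = self.spec.respiratory_rate_cpm / 60.0
            cols_phi.append(prof.reshape(-1))
            cols_psi.append(-self.spec.respiratory_amp_voxels * np.sin(2 * np.pi * f * times))
        Phi = np.stack(cols_phi, axis=1)
        Psi = np.stack(cols_psi, axis=1)
        shape = tuple(self.spec.grid_shape)
        return LowRankMotion(
            Phi=Phi, Psi=Psi, grid_shape=shape, full_shape=shape,
            rank=Phi.shape[1], frame_rate_hz=frame_rate_hz,
        )


def make_phantom(spec: PhantomSpec) -> PhantomScene:
    """Build the phantom scene (validates the spec invariants)."""
    return PhantomScene(spec)


def gt_volume_curve(scene: PhantomScene, times_s: np.ndarray):
    """Analytic target-ventricle volume curve at the given times."""
    from freebeat.volumetrics import VolumeCurve

    times_s = np.asarray(times_s, dtype=float)
    if times_s.size == 0:
        raise ValueError("times must be non-empty")
    if times_s.size > 1 and not (np.diff(times_s) > 0).all():
        raise ValueError("times must be strictly increasing")
    dt = np.median(np.diff(times_s)) if times_s.size > 1 else 1.0
    return VolumeCurve(
        times_s=times_s,
        volumes_ml=np.asarray(scene.gt_volume(times_s)),
        frame_rate_hz=1.0 / dt,
    )
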