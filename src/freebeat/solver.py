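"""Alternating reconstruction of the reference image and low-rank motion.

Two subproblems are alternated:

  image step    min_q   sum_t || S_t F C W(u_t) q - s_t ||_2^2
  motion step   min_Phi,Psi  sum_t || S_t F C W(u_t) q - s_t ||_l
                             + lambda * TV(u_t),   u_t = reshape(Phi Psi_t)

The image step is a conjugate-gradient solve of the normal equations with
the motion frozen; the motion step runs mini-batch stochastic gradient
descent on (Phi, Psi) with the image frozen, projecting Psi through a
zero-phase Butterworth low-pass after every update.  The data norm is l2
for clean (phantom-like) data and l1 for data with localized outliers such
as inflow enhancement.  All gradients are computed analytically: the
derivative of the warped image w.r.t. the displacement is the exact spatial
derivative of the trilinear interpolant, so finite-difference checks agree
to first order.

Motion is estimated coarse-to-fine on a dyadic spatial pyramid; at coarse
levels the expanded field is linearly upsampled to the full grid (with
per-axis magnitude rescaling) before entering the encoding operator, and
the data gradient is pulled back through the exact adjoint of that
upsampling.  The TV term and its gradient act on the model's own grid.

The regularization weight is specified relative to the data term
(``lambda_rel``) and converted to an absolute weight from the cost values
at the start of every pyramid level, which makes one relative weight
transfer across matrix sizes and noise levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield, replace as dc_replace

import numpy as np

from freebeat.encoding import (
    AcquisitionSet,
    CoilMaps,
    ReferenceImage,
    TrilinearOp,
    adjoint,
    forward,
    time_averaged_recon,
    warp_op,
)
from freebeat.motion import (
    LowRankMotion,
    init_temporal,
    lowpass_temporal,
    make_pyramid,
    upsample_spatial,
)

logger = logging.getLogger(__name__)

_L1_EPS = 1e-12
_TV_EPS = 1e-8


@dataclass
class ReconConfig:
    """Tunable parameters of the alternating reconstruction."""

    rank: int = 16
    max_iters: int = 120
    coarse_iters: int = 30
    batch_frames: int = 40
    norm: str = "l2"  # "l2" for clean data, "l1" for outlier robustness
    precision: str = "single"  # motion-step arithmetic: "single" or "double"
    lambda_rel: float = 1e-3
    cutoff_hz: float = 4.0
    butter_order: int = 5
    pyramid_levels: int = 3
    lr_phi: float = 0.15  # per-iteration step in voxels (adaptive SGD)
    lr_psi: float = 0.15  # per-iteration step in temporal-basis units
    momentum: float = 0.9  # first-moment (gradient averaging) coefficient
    beta2: float = 0.99  # second-moment coefficient of the adaptive scaling
    adaptive_eps: float = 1e-2  # relative epsilon of the adaptive scaling
    grad_smooth_vox: float = 3.0  # Sobolev-gradient smoothing sigma (voxels)
    grad_smooth_vox_final: float | None = 0.5  # anneal target (None: constant)
    lr_decay_iters: float = 120.0  # lr halves after this many iterations
    lr_q: float = 1.0  # reserved; image step is a CG solve
    image_inner_iters: int = 8  # CG iterations of the initial/full image solves
    image_refresh_inner: int = 4  # CG iterations of interleaved warm refreshes
    image_every: int = 10
    image_batch_frames: int | None = None  # default: batch_frames
    init_image_frames: int = 100  # frame subset of the initial image solve
    temporal_refine: bool = True  # Gauss-Newton pass over Psi at the end
    refine_newton: int = 2
    refine_band_sigma: float = 0.8  # band-matching width (voxels); 0 disables
    plateau_tol: float = 0.0  # 0 disables early stopping
    seed: int = 0

    def __post_init__(self) -> None:
        if self.norm not in ("l1", "l2"):
            raise ValueError("norm must be 'l1' or 'l2'")
        if self.precision not in ("single", "double"):
            raise ValueError("precision must be 'single' or 'double'")
        if self.coarse_iters > self.max_iters:
            raise ValueError("coarse_iters cannot exceed max_iters")
        if self.lambda_rel < 0:
            raise ValueError("lambda_rel must be >= 0")


@dataclass
class CostTrace:
    data_cost: list[float] = dfield(default_factory=list)
    tv_cost: list[float] = dfield(default_factory=list)
    total: list[float] = dfield(default_factory=list)
    grid_level: list[tuple[int, int, int]] = dfield(default_factory=list)

    def append(self, data: float, tv: float, grid: tuple[int, int, int]) -> None:
        for v in (data, tv):
            if not np.isfinite(v):
                raise FloatingPointError("non-finite cost encountered")
        self.data_cost.append(float(data))
        self.tv_cost.append(float(tv))
        self.total.append(float(data + tv))
        self.grid_level.append(tuple(grid))

    def __len__(self) -> int:
        return len(self.total)


# ---------------------------------------------------------------------------
# Isotropic total variation
# ---------------------------------------------------------------------------

def _forward_diff(x: np.ndarray, axis: int) -> np.ndarray:
    """Forward difference with zero beyond the last index (Neumann)."""
    d = np.zeros_like(x)
    sl_lo = [slice(None)] * x.ndim
    sl_hi = [slice(None)] * x.ndim
    sl_lo[axis] = slice(0, -1)
    sl_hi[axis] = slice(1, None)
    d[tuple(sl_lo)] = x[tuple(sl_hi)] - x[tuple(sl_lo)]
    return d


def _forward_diff_adjoint(v: np.ndarray, axis: int) -> np.ndarray:
    """Exact adjoint of :func:`_forward_diff` (negative divergence)."""
    w = v.copy()
    sl_last = [slice(None)] * v.ndim
    sl_last[axis] = slice(-1, None)
    w[tuple(sl_last)] = 0.0  # last-row differences are structurally zero
    out = -w
    sl_lo = [slice(None)] * v.ndim
    sl_hi = [slice(None)] * v.ndim
    sl_lo[axis] = slice(0, -1)
    sl_hi[axis] = slice(1, None)
    out[tuple(sl_hi)] += w[tuple(sl_lo)]
    return out


def tv_iso(field: np.ndarray) -> float:
    """Isotropic spatial TV of a (3, *grid) displacement field: the sum over
    voxels of the Euclidean norm of all 9 forward differences."""
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    sq = np.zeros(field.shape[1:])
    for c in range(3):
        for a in range(3):
            sq += _forward_diff(field[c], a) ** 2
    return float(np.sqrt(sq).sum())


def tv_iso_grad(field: np.ndarray, eps: float = _TV_EPS) -> np.ndarray:
    """Gradient of :func:`tv_iso` with an epsilon-smoothed norm at zero."""
    diffs = np.empty((3, 3) + field.shape[1:])
    sq = np.zeros(field.shape[1:])
    for c in range(3):
        for a in range(3):
            diffs[c, a] = _forward_diff(field[c], a)
            sq += diffs[c, a] ** 2
    denom = np.sqrt(sq + eps * eps)
    grad = np.zeros_like(field)
    for c in range(3):
        for a in range(3):
            grad[c] += _forward_diff_adjoint(diffs[c, a] / denom, a)
    return grad


# ---------------------------------------------------------------------------
# Field up/down-sampling between pyramid grids (exact adjoint pair)
# ---------------------------------------------------------------------------

class FieldUpsampler:
    """Align-corners trilinear upsampling of (3, *coarse) fields to the full
    grid with per-axis displacement rescaling, plus its exact adjoint."""

    def __init__(self, coarse: tuple[int, int, int], fine: tuple[int, int, int]):
        self.coarse = tuple(coarse)
        self.fine = tuple(fine)
        self.identity = self.coarse == self.fine
        if not self.identity:
            axes = [
                np.linspace(0.0, c - 1.0, f) if f > 1 else np.zeros(1)
                for c, f in zip(coarse, fine)
            ]
            mesh = np.meshgrid(*axes, indexing="ij")
            coords = np.stack([m.ravel() for m in mesh])
            self._op = TrilinearOp(coords, self.coarse)
            self.ratios = np.array([f / c for c, f in zip(coarse, fine)])

    def up(self, field: np.ndarray) -> np.ndarray:
        if self.identity:
            return field
        out = np.empty((3,) + self.fine)
        for c in range(3):
            out[c] = self._op.gather(field[c]).reshape(self.fine) * self.ratios[c]
        return out

    def down_adjoint(self, g_fine: np.ndarray) -> np.ndarray:
        if self.identity:
            return g_fine
        out = np.empty((3,) + self.coarse)
        for c in range(3):
            out[c] = self._op.scatter(g_fine[c].ravel()) * self.ratios[c]
        return out


# ---------------------------------------------------------------------------
# Costs
# ---------------------------------------------------------------------------

def _residual_norm(r: np.ndarray, norm: str) -> float:
    if norm == "l2":
        return float((np.abs(r) ** 2).sum())
    return float(np.abs(r).sum())


def data_cost(
    acq: AcquisitionSet,
    q: ReferenceImage | np.ndarray,
    model: LowRankMotion,
    maps: CoilMaps,
    frame_subset: np.ndarray,
    norm: str = "l2",
    upsampler: FieldUpsampler | None = None,
) -> float:
    """Per-sample-normalized data-consistency cost over a subset of frames."""
    frame_subset = np.asarray(frame_subset)
    if frame_subset.size == 0:
        raise ValueError("frame subset must be non-empty")
    if norm not in ("l1", "l2"):
        raise ValueError("norm must be 'l1' or 'l2'")
    img = q.data if isinstance(q, ReferenceImage) else q
    total = 0.0
    n = 0
    for t in frame_subset:
        u = model.expand(int(t))
        if upsampler is not None:
            u = upsampler.up(u)
        pred = forward(img, u, maps, acq.frame_lines(int(t)))
        r = pred - acq.frame_samples(int(t))
        total += _residual_norm(r, norm)
        n += r.size
    return total / n


def scale_lambda(
    lambda_rel: float,
    q0: ReferenceImage | np.ndarray,
    model0: LowRankMotion,
    acq: AcquisitionSet,
    maps: CoilMaps,
    norm: str = "l2",
    frame_subset: np.ndarray | None = None,
    upsampler: FieldUpsampler | None = None,
    eps: float = 1.0,
) -> float:
    """Absolute TV weight: lambda_rel * data_cost(init) / max(TV(u_0), eps).

    ``eps`` guards the zero-motion initialization (TV = 0), where the ratio
    degenerates; there the data cost itself sets the scale.
    """
    if lambda_rel == 0:
        return 0.0
    if frame_subset is None:
        frame_subset = np.arange(min(model0.n_frames, 40))
    dc = data_cost(acq, q0, model0, maps, frame_subset, norm, upsampler)
    tv0 = tv_iso(model0.expand(0))
    return lambda_rel * dc / max(tv0, eps)


# ---------------------------------------------------------------------------
# Image step (CG on the normal equations)
# ---------------------------------------------------------------------------

def image_step(
    acq: AcquisitionSet,
    model: LowRankMotion,
    maps: CoilMaps,
    q_init: ReferenceImage,
    cfg: ReconConfig,
    frame_subset: np.ndarray | None = None,
    upsampler: FieldUpsampler | None = None,
) -> ReferenceImage:
    """Approximate least-squares update of the reference image by CG on
    A^H A q = A^H s with the motion frozen, warm-started at ``q_init``."""
    if frame_subset is None:
        frame_subset = np.arange(model.n_frames)
    frame_subset = np.asarray(frame_subset, dtype=int)
    shape = q_init.data.shape
    warps = []
    lines = []
    for t in frame_subset:
        u = model.expand(int(t))
        if upsampler is not None:
            u = upsampler.up(u)
        warps.append(warp_op(u))
        lines.append(acq.frame_lines(int(t)))

    def AHA(x: np.ndarray) -> np.ndarray:
        out = np.zeros(shape, dtype=np.complex128)
        for w, ln in zip(warps, lines):
            pred = forward(x, None, maps, ln, warp=w)
            out += adjoint(pred, None, maps, ln, shape=shape, warp=w)
        return out

    b = np.zeros(shape, dtype=np.complex128)
    for t, w, ln in zip(frame_subset, warps, lines):
        b += adjoint(acq.frame_samples(int(t)), None, maps, ln, shape=shape, warp=w)

    x = q_init.data.astype(np.complex128).copy()
    r = b - AHA(x)
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    rs0 = rs
    for _ in range(cfg.image_inner_iters):
        if rs == 0:
            break
        Ap = AHA(p)
        alpha = rs / float(np.vdot(p, Ap).real)
        x += alpha * p
        r -= alpha * Ap
        rs_new = float(np.vdot(r, r).real)
        if rs_new > 10.0 * rs0:
            raise FloatingPointError("CG diverged in image step")
        p = r + (rs_new / rs) * p
        rs = rs_new
    return ReferenceImage(data=x, voxel_size_mm=q_init.voxel_size_mm)


# ---------------------------------------------------------------------------
# Motion step (mini-batch SGD with analytic gradients)
# ---------------------------------------------------------------------------

def _frame_motion_gradient(
    acq: AcquisitionSet,
    img: np.ndarray,
    u_full: np.ndarray,
    maps: CoilMaps,
    t: int,
    norm: str,
    n_total: int,
    smooth_vox: float = 0.0,
) -> tuple[np.ndarray, float]:
    """(gradient of the data cost w.r.t. the full-grid field, residual norm).

    ``smooth_vox`` > 0 returns the Sobolev-preconditioned gradient (Gaussian
    smoothing per component): the stationary points of the objective are
    unchanged, but edge-localized constraints are diffused into homogeneous
    regions, where the raw data gradient carries no information.
    """
    op = warp_op(u_full)
    lines = acq.frame_lines(t)
    warped, grad_interp = op.gather_with_grad(img)
    pred = forward(warped.reshape(img.shape), None, maps, lines)
    r = pred - acq.frame_samples(t)
    cost = _residual_norm(r, norm)
    if norm == "l2":
        rv = r
        factor = 2.0 / n_total
    else:
        rv = r / (np.abs(r) + _L1_EPS)
        factor = 1.0 / n_total
    bimg = adjoint(rv, None, maps, lines, shape=img.shape)  # no warp transpose here
    b_flat = bimg.reshape(-1)
    g = factor * np.real(np.conj(b_flat)[None, :] * grad_interp)
    g = g.reshape((3,) + img.shape)
    if smooth_vox > 0:
        from scipy import ndimage

        for c in range(3):
            g[c] = ndimage.gaussian_filter(g[c], smooth_vox, mode="constant")
    return g, cost


def motion_step(
    acq: AcquisitionSet,
    q: ReferenceImage,
    model: LowRankMotion,
    maps: CoilMaps,
    cfg: ReconConfig,
    n_iters: int,
    lambda_abs: float = 0.0,
    upsampler: FieldUpsampler | None = None,
    trace: CostTrace | None = None,
    iter_offset: int = 0,
    grad_state: dict | None = None,
) -> LowRankMotion:
    """``n_iters`` SGD updates of (Phi, Psi) with the image frozen.

    Each iteration samples ``batch_frames`` frames without replacement
    (reseeded per iteration from cfg.seed), accumulates the analytic
    gradient of data + TV cost, takes an SGD step, and projects Psi through
    the Butterworth low-pass.

    Step sizes are made transferable across matrix sizes and signal scales
    by normalizing each factor's gradient by its largest component, so
    ``lr_phi`` is the per-iteration displacement step in voxels (and
    ``lr_psi`` the step in temporal-basis units), decayed as
    1 / (1 + iteration / lr_decay_iters).
    """
    img = q.data
    if cfg.precision == "single":
        img = img.astype(np.complex64)
        maps = CoilMaps(maps.maps.astype(np.complex64))
        acq = AcquisitionSet(
            samples=acq.samples.astype(np.complex64),
            schedule=acq.schedule, binning=acq.binning,
            noise_sigma=acq.noise_sigma,
        )
    M = model.n_frames
    B = min(cfg.batch_frames, M)
    Phi = model.Phi.copy()
    Psi = model.Psi.copy()
    grid = tuple(model.grid_shape)
    if upsampler is None:
        upsampler = FieldUpsampler(grid, img.shape)
    lines_per_frame = acq.binning.readouts_per_frame
    n_total = B * lines_per_frame * maps.n_coils * img.shape[0]
    if grad_state is None:
        grad_state = {}
    grad_state.setdefault("step", 0)
    for name, ref in (("phi", Phi), ("psi", Psi)):
        grad_state.setdefault(f"m_{name}", np.zeros_like(ref))
        grad_state.setdefault(f"v_{name}", np.zeros_like(ref))
    for it in range(n_iters):
        rng = np.random.default_rng([cfg.seed, iter_offset + it])
        batch = rng.choice(M, size=B, replace=False)
        if cfg.grad_smooth_vox_final is None:
            sigma = cfg.grad_smooth_vox
        else:
            # linear anneal from the initial to the final smoothing width
            # over the configured iteration budget (coarse first, sharp last)
            frac = min((iter_offset + it) / max(cfg.max_iters - 1, 1), 1.0)
            sigma = (
                cfg.grad_smooth_vox
                + (cfg.grad_smooth_vox_final - cfg.grad_smooth_vox) * frac
            )
        gPhi = np.zeros_like(Phi)
        gPsi = np.zeros_like(Psi)
        dsum = 0.0
        tvsum = 0.0
        for t in batch:
            u = (Phi @ Psi[t]).reshape((3,) + grid)
            u_full = upsampler.up(u)
            g_full, cost_t = _frame_motion_gradient(
                acq, img, u_full, maps, int(t), cfg.norm, n_total,
                smooth_vox=sigma,
            )
            g = upsampler.down_adjoint(g_full)
            dsum += cost_t
            if lambda_abs > 0:
                tvsum += tv_iso(u)
                g = g + (lambda_abs / B) * tv_iso_grad(u)
            g_flat = g.reshape(-1)
            gPhi += np.outer(g_flat, Psi[t])
            gPsi[t] += Phi.T @ g_flat
        if not (np.all(np.isfinite(gPhi)) and np.all(np.isfinite(gPsi))):
            raise FloatingPointError("non-finite motion gradient")
        # Adaptive per-parameter steps (Adam-style moments with an epsilon
        # relative to the largest parameter scale): the data gradient is
        # orders of magnitude stronger at intensity edges than in flat
        # regions, and a single global step size cannot serve both.  lr is
        # the per-iteration step in voxel (Phi) / basis (Psi) units.
        grad_state["step"] += 1
        k = grad_state["step"]
        decay = 1.0 / (1.0 + (iter_offset + it) / cfg.lr_decay_iters)
        for name, param, g, lr in (
            ("phi", Phi, gPhi, cfg.lr_phi),
            ("psi", Psi, gPsi, cfg.lr_psi),
        ):
            m = grad_state[f"m_{name}"]
            v = grad_state[f"v_{name}"]
            m *= cfg.momentum
            m += (1 - cfg.momentum) * g
            v *= cfg.beta2
            v += (1 - cfg.beta2) * g * g
            mhat = m / (1 - cfg.momentum**k)
            vhat = np.sqrt(v / (1 - cfg.beta2**k))
            vmax = vhat.max()
            if vmax > 0:
                param -= (lr * decay) * mhat / (vhat + cfg.adaptive_eps * vmax)
        Psi = lowpass_temporal(Psi, model.frame_rate_hz, cfg.cutoff_hz, cfg.butter_order)
        if trace is not None:
            trace.append(dsum / n_total, lambda_abs * tvsum / B, grid)
    return LowRankMotion(
        Phi=Phi, Psi=Psi, grid_shape=grid, full_shape=model.full_shape,
        rank=model.rank, frame_rate_hz=model.frame_rate_hz,
    )


def refine_temporal(
    acq: AcquisitionSet,
    q: ReferenceImage,
    model: LowRankMotion,
    maps: CoilMaps,
    cfg: ReconConfig,
    upsampler: FieldUpsampler | None = None,
    n_newton: int = 2,
    damping: float = 1e-3,
    kspace_weight_radius: float | None = 0.35,
) -> LowRankMotion:
    """Gauss-Newton refinement of every temporal weight vector.

    With the spatial basis frozen, the temporal weights of each frame are an
    independent R-dimensional nonlinear least-squares problem in that
    frame's k-space data.  Mini-batch SGD touches each frame only a handful
    of times when M >> batch size, leaving the weights noisy; a couple of
    damped Gauss-Newton steps per frame (l2, or IRLS-weighted for l1)
    converge them essentially exactly.  Psi is passed through the
    Butterworth projection afterwards, as after any motion update.

    ``kspace_weight_radius`` applies a radial low-pass weight
    1 / (1 + (|k| / r0)^4) (r0 relative to the Nyquist radius) to the
    least-squares fit.  The reference image is itself estimated from
    undersampled data, and its aliasing error concentrates at high spatial
    frequencies; weighting the fit toward the well-determined low
    frequencies counters the amplitude attenuation that regressor error
    would otherwise cause (errors-in-variables dilution).  ``None`` fits
    all samples equally.
    """
    img = q.data
    if cfg.precision == "single":
        img = img.astype(np.complex64)
        maps = CoilMaps(maps.maps.astype(np.complex64))
        acq = AcquisitionSet(
            samples=acq.samples.astype(np.complex64),
            schedule=acq.schedule, binning=acq.binning,
            noise_sigma=acq.noise_sigma,
        )
    grid = tuple(model.grid_shape)
    R = model.rank
    if upsampler is None:
        upsampler = FieldUpsampler(grid, img.shape)
    # upsampled spatial basis columns, (R, 3, *full_grid)
    basis_full = np.stack([
        upsampler.up(model.Phi[:, r].reshape((3,) + grid)) for r in range(R)
    ])
    Psi = model.Psi.copy()
    M = model.n_frames
    nx, ny, nz = img.shape
    kx = np.arange(nx) - nx // 2
    for t in range(M):
        lines = acq.frame_lines(t)
        s_t = acq.frame_samples(t)
        if kspace_weight_radius is not None:
            kr = np.sqrt(
                (kx[None, :] / (nx / 2)) ** 2
                + ((lines[:, 0] - ny // 2) / (ny / 2))[:, None] ** 2
                + ((lines[:, 1] - nz // 2) / (nz / 2))[:, None] ** 2
            )
            wk = 1.0 / (1.0 + (kr / kspace_weight_radius) ** 4)
            wk = np.broadcast_to(
                wk[None, :, :], (maps.n_coils,) + wk.shape
            ).reshape(-1).astype(np.float32 if cfg.precision == "single" else np.float64)
        else:
            wk = None
        psi = Psi[t].copy()
        for _ in range(n_newton):
            u_full = np.tensordot(psi, basis_full, axes=(0, 0))
            op = warp_op(u_full)
            pred = forward(img, None, maps, lines, warp=op)
            r = (pred - s_t).reshape(-1)
            G = op.gather_grad(img)  # (3, N) derivative of warped image
            J = np.empty((R, r.size), dtype=r.dtype)
            for k in range(R):
                dw = (G * basis_full[k].reshape(3, -1)).sum(axis=0).reshape(img.shape)
                J[k] = forward(dw, None, maps, lines).reshape(-1)
            if cfg.norm == "l1":
                w = 1.0 / (np.abs(r) + _L1_EPS)
            else:
                w = None
            if wk is not None:
                w = wk if w is None else w * wk
            if w is None:
                A = np.real(J @ np.conj(J).T)
                b = np.real(J @ np.conj(r))
            else:
                A = np.real((J * w) @ np.conj(J).T)
                b = np.real((J * w) @ np.conj(r))
            A[np.diag_indices_from(A)] += damping * max(np.trace(A) / R, 1e-30)
            try:
                delta = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                break
            psi = psi - delta
        Psi[t] = psi
    Psi = lowpass_temporal(Psi, model.frame_rate_hz, cfg.cutoff_hz, cfg.butter_order)
    return LowRankMotion(
        Phi=model.Phi, Psi=Psi, grid_shape=grid, full_shape=model.full_shape,
        rank=R, frame_rate_hz=model.frame_rate_hz,
    )


def band_matched(
    acq: AcquisitionSet, q: ReferenceImage, sigma_vox: float
) -> tuple[AcquisitionSet, ReferenceImage]:
    """Filter the reference image and the k-space data with the *same*
    Gaussian transfer function.

    The reference is estimated from undersampled data, so its error
    concentrates at high spatial frequencies (aliasing from unsampled
    k-space).  Fitting motion against the raw reference treats that error
    as anatomy and attenuates the fitted amplitudes (errors-in-variables).
    Applying one Gaussian (std ``sigma_vox`` voxels) to the reference in
    image space and its exact transfer function to every k-space sample
    makes both sides of the fit see the same band-limited anatomy; sub-voxel
    edge displacements remain fully observable.
    """
    from scipy import ndimage

    qs = ndimage.gaussian_filter(q.data.real, sigma_vox, mode="constant") + 1j * (
        ndimage.gaussian_filter(q.data.imag, sigma_vox, mode="constant")
    )
    nx, ny, nz = acq.schedule.matrix
    fx = (np.arange(nx) - nx // 2) / nx
    fy = (acq.schedule.readouts[:, 0] - ny // 2) / ny
    fz = (acq.schedule.readouts[:, 1] - nz // 2) / nz
    t_yz = np.exp(-2 * np.pi**2 * sigma_vox**2 * (fy**2 + fz**2))
    t_x = np.exp(-2 * np.pi**2 * sigma_vox**2 * fx**2)
    samples = acq.samples * t_yz[:, None, None] * t_x[None, None, :]
    acq_s = AcquisitionSet(
        samples=samples, schedule=acq.schedule, binning=acq.binning,
        noise_sigma=acq.noise_sigma,
    )
    return acq_s, ReferenceImage(data=qs, voxel_size_mm=q.voxel_size_mm)


# ---------------------------------------------------------------------------
# Full alternation
# ---------------------------------------------------------------------------

def _plateaued(trace: CostTrace, tol: float, window: int = 10) -> bool:
    if tol <= 0 or len(trace) < 2 * window:
        return False
    recent = np.mean(trace.total[-window:])
    previous = np.mean(trace.total[-2 * window : -window])
    if previous == 0:
        return False
    return abs(previous - recent) / abs(previous) < tol


def run(
    acq: AcquisitionSet,
    maps: CoilMaps,
    cfg: ReconConfig,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[ReferenceImage, LowRankMotion, CostTrace]:
    """Full alternating reconstruction.

    Stages:

    1. Initialize the reference from the density-compensated time average,
       normalize the problem so its 99th-percentile image magnitude is 1
       (making step sizes transferable across datasets), and solve the
       static SENSE problem by CG on a random frame subset.
    2. Motion: adaptive mini-batch SGD over the coarse-to-fine pyramid with
       annealed Sobolev gradient smoothing; a warm CG image refresh runs
       every ``image_every`` motion iterations.
    3. Temporal Gauss-Newton refinement of Psi (band-matched against the
       estimated reference), then a final warm image refresh.
    """
    full_grid = tuple(acq.schedule.matrix)
    q0 = time_averaged_recon(acq, maps, voxel_size_mm)
    scale = np.percentile(np.abs(q0.data), 99)
    if scale == 0:
        scale = 1.0
    q = ReferenceImage(data=q0.data / scale, voxel_size_mm=q0.voxel_size_mm)
    acq = AcquisitionSet(
        samples=acq.samples / scale,
        schedule=acq.schedule,
        binning=acq.binning,
        noise_sigma=acq.noise_sigma / scale,
    )
    M = acq.binning.n_frames
    frame_rate = acq.binning.frame_rate_hz
    pyramid = make_pyramid(full_grid, cfg.pyramid_levels, cfg.coarse_iters)
    grids = [g for g, _ in pyramid.levels]
    iters = [n for _, n in pyramid.levels]
    iters[-1] += cfg.max_iters - cfg.coarse_iters  # full-grid remainder

    Psi = init_temporal(M, cfg.rank, frame_rate, seed=[cfg.seed, 101])
    Psi = lowpass_temporal(Psi, frame_rate, cfg.cutoff_hz, cfg.butter_order)
    model = LowRankMotion(
        Phi=np.zeros((3 * int(np.prod(grids[0])), cfg.rank)),
        Psi=Psi,
        grid_shape=grids[0],
        full_shape=full_grid,
        rank=cfg.rank,
        frame_rate_hz=frame_rate,
    )
    trace = CostTrace()
    if cfg.max_iters == 0:
        return q, model, trace

    rng_init = np.random.default_rng([cfg.seed, 4000])
    subset_init = rng_init.choice(M, size=min(cfg.init_image_frames, M), replace=False)
    ups0 = FieldUpsampler(tuple(grids[0]), full_grid)
    q = image_step(acq, model, maps, q, cfg, frame_subset=subset_init, upsampler=ups0)
    logger.info("initial image solve done (%d frames)", len(subset_init))

    img_batch = min(cfg.image_batch_frames or cfg.batch_frames, M)
    refresh_cfg = dc_replace(cfg, image_inner_iters=cfg.image_refresh_inner)
    iter_global = 0
    stop = False
    for lvl, (grid, n_lvl) in enumerate(zip(grids, iters)):
        if tuple(model.grid_shape) != tuple(grid):
            model = upsample_spatial(model, grid)
        ups = FieldUpsampler(tuple(grid), full_grid)
        rng_lambda = np.random.default_rng([cfg.seed, 9000 + lvl])
        subset = rng_lambda.choice(M, size=min(cfg.batch_frames, M), replace=False)
        lambda_abs = scale_lambda(
            cfg.lambda_rel, q, model, acq, maps, cfg.norm,
            frame_subset=subset, upsampler=ups,
        )
        logger.info("level %s grid=%s iters=%d lambda_abs=%.3e", lvl, grid, n_lvl, lambda_abs)
        grad_state: dict = {}
        done = 0
        while done < n_lvl and not stop:
            chunk = min(cfg.image_every, n_lvl - done)
            model = motion_step(
                acq, q, model, maps, cfg, chunk,
                lambda_abs=lambda_abs, upsampler=ups,
                trace=trace, iter_offset=iter_global, grad_state=grad_state,
            )
            done += chunk
            iter_global += chunk
            rng_img = np.random.default_rng([cfg.seed, 5000 + iter_global])
            subset_img = rng_img.choice(M, size=img_batch, replace=False)
            q = image_step(
                acq, model, maps, q, refresh_cfg,
                frame_subset=subset_img, upsampler=ups,
            )
            if trace.total:
                logger.info(
                    "iter %d/%d data=%.4e tv=%.4e",
                    iter_global, cfg.max_iters, trace.data_cost[-1], trace.tv_cost[-1],
                )
            if _plateaued(trace, cfg.plateau_tol):
                logger.info("cost plateau reached at iteration %d", iter_global)
                stop = True
        if stop:
            break
    if tuple(model.grid_shape) != full_grid:
        model = upsample_spatial(model, full_grid)
    if cfg.temporal_refine:
        # a strong motion-corrected image solve anchors the refinement:
        # residual reference error is what biases the temporal fits
        rng_img = np.random.default_rng([cfg.seed, 5998])
        subset_img = rng_img.choice(
            M, size=min(cfg.init_image_frames, M), replace=False
        )
        q = image_step(acq, model, maps, q, cfg, frame_subset=subset_img)
        if cfg.refine_band_sigma > 0:
            acq_bm, q_bm = band_matched(acq, q, cfg.refine_band_sigma)
        else:
            acq_bm, q_bm = acq, q
        model = refine_temporal(acq_bm, q_bm, model, maps, cfg, n_newton=cfg.refine_newton)
        logger.info("temporal refinement done")
        rng_img = np.random.default_rng([cfg.seed, 5999])
        subset_img = rng_img.choice(M, size=img_batch, replace=False)
        q = image_step(acq, model, maps, q, refresh_cfg, frame_subset=subset_img)
    return q, model, trace
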