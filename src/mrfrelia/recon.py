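"""Subspace reconstruction with locally-low-rank regularization.

Solves

    min_c  1/2 || A c - y ||^2  +  lambda * sum_p || R_p c ||_*

where ``A`` is the subspace encoding operator and ``R_p`` extracts small
spatial patches of the stacked K coefficient maps (nuclear norm = locally
low rank).  The solver is an accelerated proximal-gradient (FISTA)
iteration with a monotone safeguard: whenever the momentum step would
increase the objective, the iteration restarts from a plain descent
step, so the recorded objective is non-increasing after the first
iteration.  The proximal map of the LLR term is singular-value soft
thresholding on non-overlapping patches with a random per-iteration
shift (cycle spinning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .encoding import KSpaceData, SubspaceEncodingOperator
from .sampling import SamplingScheme
from .signal_model import SubspaceBasis
from .transforms import RigidTransform

__all__ = [
    "ReconConfig",
    "CoefficientMaps",
    "ReconDivergence",
    "reconstruct_subspace",
    "reconstruct_subspace_b0",
    "combine_acquisitions",
]


log = logging.getLogger(__name__)


class ReconDivergence(RuntimeError):
    """Raised when the objective increases for several consecutive iterations."""


@dataclass
class ReconConfig:
    """Solver settings.

    ``lam_rel`` scales the regularization weight relative to the peak
    adjoint amplitude: lambda = lam_rel * max|A^H y|.  Set ``lam_rel = 0``
    for an unregularized least-squares fit.  ``b0_segments`` is the number
    of off-resonance time segments L (0 disables the correction).
    """

    lam_rel: float = 0.05
    llr_patch: int = 8
    n_iters: int = 50
    b0_segments: int = 0
    step: float | None = None
    seed: int = 0
    llr_shift_mode: str = "fixed"  # "fixed" (one seeded shift) or "per_iteration"
    warm_start_cg: int = 0  # unregularized CG iterations used as initialization
    lam_abs: float | None = None  # absolute lambda; overrides the lam_rel scaling

    def __post_init__(self) -> None:
        if self.lam_rel < 0:
            raise ValueError("lam_rel must be >= 0")
        if self.llr_patch < 2:
            raise ValueError("llr_patch must be >= 2")
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")


@dataclass
class CoefficientMaps:
    """K complex subspace-coefficient volumes plus solver diagnostics."""

    c: np.ndarray  # (K, nx, ny, nz)
    space: str = "native"
    objectives: np.ndarray | None = None
    lam: float = 0.0

    @property
    def k(self) -> int:
        return self.c.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.c.shape[1:]

    def magnitude(self, index: int) -> np.ndarray:
        return np.abs(self.c[index])


def _estimate_lipschitz(op: SubspaceEncodingOperator, seed: int, n_iter: int = 12) -> float:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x11]))
    x = rng.standard_normal((op.k,) + op.shape) + 1j * rng.standard_normal((op.k,) + op.shape)
    x /= np.linalg.norm(x)
    lam = 1.0
    for _ in range(n_iter):
        x = op.adjoint(op.forward(x))
        lam = np.linalg.norm(x)
        if lam == 0:
            return 1.0
        x /= lam
    return float(lam)


def _llr_prox(c: np.ndarray, patch: int, thresh: float, shift: tuple[int, int]) -> np.ndarray:
    """Singular-value soft thresholding on shifted non-overlapping patches."""
    k, nx, ny, nz = c.shape
    p = patch
    px, py = (-nx) % p, (-ny) % p
    v = np.roll(c, shift, axis=(1, 2))
    v = np.pad(v, ((0, 0), (0, px), (0, py), (0, 0)))
    mx, my = v.shape[1] // p, v.shape[2] // p
    # (mx, my, nz, p*p, k) patch matrices
    w = v.reshape(k, mx, p, my, p, nz).transpose(1, 3, 5, 2, 4, 0).reshape(mx, my, nz, p * p, k)
    u, s, vh = np.linalg.svd(w, full_matrices=False)
    s = np.maximum(s - thresh, 0.0)
    w = (u * s[..., None, :]) @ vh
    v = w.reshape(mx, my, nz, p, p, k).transpose(5, 0, 3, 1, 4, 2).reshape(
        k, mx * p, my * p, nz
    )
    v = v[:, :nx, :ny, :]
    return np.roll(v, (-shift[0], -shift[1]), axis=(1, 2))


def _llr_nuclear(c: np.ndarray, patch: int, shift: tuple[int, int]) -> float:
    k, nx, ny, nz = c.shape
    p = patch
    px, py = (-nx) % p, (-ny) % p
    v = np.roll(c, shift, axis=(1, 2))
    v = np.pad(v, ((0, 0), (0, px), (0, py), (0, 0)))
    mx, my = v.shape[1] // p, v.shape[2] // p
    w = v.reshape(k, mx, p, my, p, nz).transpose(1, 3, 5, 2, 4, 0).reshape(-1, p * p, k)
    s = np.linalg.svd(w, compute_uv=False)
    return float(s.sum())


def _solve_cg(op: SubspaceEncodingOperator, y: np.ndarray, config: ReconConfig) -> CoefficientMaps:
    """Conjugate gradient on the normal equations (unregularized fit)."""
    aty = op.adjoint(y)
    c = np.zeros_like(aty)
    r = aty.copy()
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    y2 = 0.5 * float(np.vdot(y, y).real)
    objs = []
    for _ in range(config.n_iters):
        q = op.adjoint(op.forward(p))
        denom = float(np.vdot(p, q).real)
        if denom <= 0:
            break
        alpha = rs / denom
        c += alpha * p
        r -= alpha * q
        # 0.5||Ac - y||^2 from maintained quantities: A^H A c = aty - r
        objs.append(
            y2 - float(np.vdot(aty, c).real) + 0.5 * float(np.vdot(c, aty - r).real)
        )
        rs_new = float(np.vdot(r, r).real)
        if rs_new < 1e-30:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return CoefficientMaps(c=c, objectives=np.asarray(objs), lam=0.0)


def _solve(
    op: SubspaceEncodingOperator,
    y: np.ndarray,
    config: ReconConfig,
) -> CoefficientMaps:
    if config.lam_rel == 0 and config.lam_abs is None:
        return _solve_cg(op, y, config)
    aty = op.adjoint(y)
    if config.lam_abs is not None:
        lam = config.lam_abs
    else:
        lam = config.lam_rel * float(np.max(np.abs(aty)))
    if lam == 0:
        return _solve_cg(op, y, config)
    if config.step is not None:
        step = config.step
    else:
        step = 1.0 / (1.05 * _estimate_lipschitz(op, config.seed))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x50]))
    p = config.llr_patch

    def objective(c, shift):
        r = op.forward(c) - y
        val = 0.5 * float(np.vdot(r, r).real)
        if lam > 0:
            val += lam * _llr_nuclear(c, p, shift)
        return val

    if config.warm_start_cg > 0:
        from dataclasses import replace as _replace

        x = _solve_cg(op, y, _replace(config, n_iters=config.warm_start_cg)).c
    else:
        x = np.zeros_like(aty)
    z = x.copy()
    t = 1.0
    objs = []
    prev_obj = np.inf
    n_up = 0
    fixed_shift = tuple(int(v) for v in rng.integers(0, p, size=2)) if lam > 0 else (0, 0)
    for it in range(config.n_iters):
        if lam > 0 and config.llr_shift_mode == "per_iteration":
            shift = tuple(int(v) for v in rng.integers(0, p, size=2))
        else:
            shift = fixed_shift

        def prox_step(point):
            g = op.adjoint(op.forward(point) - y)
            cand = point - step * g
            if lam > 0:
                cand = _llr_prox(cand, p, lam * step, shift)
            return cand

        cand = prox_step(z)
        obj = objective(cand, shift)
        if obj > prev_obj:
            # monotone safeguard: restart momentum, descend from x
            cand = prox_step(x)
            obj = objective(cand, shift)
            t = 1.0
        if obj > prev_obj * (1 + 1e-12):
            n_up += 1
            if n_up >= 5:
                raise ReconDivergence(
                    f"objective increased 5 consecutive iterations at iter {it}: "
                    f"{objs[-5:]} -> {obj}; step={step:.3e}, lambda={lam:.3e}"
                )
        else:
            n_up = 0
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        z = cand + ((t - 1.0) / t_next) * (cand - x)
        x = cand
        t = t_next
        objs.append(obj)
        prev_obj = obj

    return CoefficientMaps(c=x, objectives=np.asarray(objs), lam=lam)


def reconstruct_subspace(
    y: KSpaceData,
    basis: SubspaceBasis,
    coils: np.ndarray,
    scheme: SamplingScheme | None = None,
    config: ReconConfig | None = None,
) -> CoefficientMaps:
    """Subspace reconstruction without off-resonance correction."""
    config = config or ReconConfig()
    if config.b0_segments != 0:
        raise ValueError("use reconstruct_subspace_b0 when b0_segments >= 1")
    scheme = scheme or y.scheme
    op = SubspaceEncodingOperator(basis, coils, scheme)
    return _solve(op, y.samples, config)


def reconstruct_subspace_b0(
    y: KSpaceData,
    basis: SubspaceBasis,
    coils: np.ndarray,
    b0_map_hz: np.ndarray,
    scheme: SamplingScheme | None = None,
    config: ReconConfig | None = None,
) -> CoefficientMaps:
    """Subspace reconstruction with time-segmented B0 correction."""
    config = config or ReconConfig(b0_segments=8)
    if config.b0_segments < 1:
        raise ValueError("reconstruct_subspace_b0 requires b0_segments >= 1")
    scheme = scheme or y.scheme
    op = SubspaceEncodingOperator(
        basis, coils, scheme, b0_map_hz=b0_map_hz, n_segments=config.b0_segments
    )
    return _solve(op, y.samples, config)


def combine_acquisitions(
    y1: KSpaceData,
    y2: KSpaceData,
    rigid_transform: RigidTransform | None = None,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> KSpaceData:
    """Motion-compensated k-space combination of two complementary scans.

    The rigid transform maps scan-2 coordinates to scan-1 coordinates
    (the pull-back convention used when resampling scan 2 onto scan 1).
    Compensation happens natively in k-space: scan-2 sample coordinates
    are rotated by the transform's rotation, and a linear phase ramp
    removes the translation; the compensated samples are concatenated
    with scan 1's, and the result reconstructs in scan-1 space.
    """
    if rigid_transform is None:
        rigid_transform = RigidTransform.identity()
    if not isinstance(rigid_transform, RigidTransform):
        raise TypeError("motion compensation requires a RigidTransform")
    s1, s2 = y1.scheme, y2.scheme
    if s1.shape != s2.shape or s1.n_groups != s2.n_groups:
        raise ValueError("schemes are not compatible for combination")
    if not (s1.complementary and s2.complementary):
        raise ValueError("schemes must be a complementary pair")

    shape = np.asarray(s1.shape, dtype=float)
    if rigid_transform.angle_deg != 0 and s1.shape[0] != s1.shape[1]:
        raise ValueError("rotational compensation requires a square in-plane grid")
    center = (shape - 1) / 2.0
    r = rigid_transform.rotation_matrix()
    # image pull-back I2(r) = I1(R (r - c) + c + t)  =>  offset vector b
    t_vox = rigid_transform.translation_mm / np.asarray(voxel_size_mm, dtype=float)
    b = center - r @ center + t_vox

    new_coords = s2.coords @ r.T  # rotate each sample coordinate
    phase = np.exp(-2j * np.pi * (new_coords @ (b / shape)))
    samples2 = y2.samples * phase[None, :, :]
    # rotation can push extreme corner samples just past the Nyquist band;
    # their true content is negligible, so clip the coordinates into the
    # band and discard (zero) the data rather than extrapolating
    nyq = shape / 2.0
    oob = np.any(np.abs(new_coords) > nyq[None, None, :], axis=2)
    if np.any(oob):
        log.info("combine_acquisitions: %d rotated samples beyond Nyquist dropped", int(oob.sum()))
        new_coords = np.clip(new_coords, -nyq[None, None, :], nyq[None, None, :] - 1e-6)
        samples2 = samples2 * ~oob[None, :, :]

    scheme = SamplingScheme(
        shape=s1.shape,
        coords=np.concatenate([s1.coords, new_coords], axis=1),
        tr_index=np.concatenate([s1.tr_index, s2.tr_index], axis=1),
        time_ms=np.concatenate([s1.time_ms, s2.time_ms], axis=1),
        trs_per_group=s1.trs_per_group,
        readout_times_ms=s1.readout_times_ms,
        complementary=False,
    )
    samples = np.concatenate([y1.samples, samples2], axis=2)
    noise_sd = float(0.5 * (y1.noise_sd + y2.noise_sd))  # per-sample sd is unchanged
    return KSpaceData(samples=samples, scheme=scheme, noise_sd=noise_sd)
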