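"""Synthetic quantitative brain phantoms and a two-session paediatric cohort.

This module is the study's synthetic-data generator.  It builds desk-scale
digital phantoms with white matter, cortical gray matter, CSF ventricles,
five corpus-callosum segments (anterior to posterior, with an inverted-U
T1 profile) and tract-like mask channels; a smooth off-resonance (B0)
field with one high-inhomogeneity pocket mimicking the air-tissue
interface above the sinuses; smooth complex coil-sensitivity maps; and a
cohort of subjects aged 8-13 y whose white-matter R1 = 1/T1 increases
linearly with age, each scanned in two sessions 2-4 months apart with
rigid inter-session motion, a small developmental drift, and independent
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .transforms import RigidTransform

__all__ = [
    "QuantitativePhantom",
    "CohortSpec",
    "SessionRealization",
    "Subject",
    "make_phantom",
    "make_b0_map",
    "make_coil_sensitivities",
    "simulate_cohort",
    "LABELS",
    "CC_LABELS",
]

# label codes used throughout the package
LABELS = {"background": 0, "wm": 1, "gm": 2, "csf": 3}
CC_LABELS = (11, 12, 13, 14, 15)  # anterior -> posterior

# literature-style tissue defaults (ms / arbitrary units); config entries,
# overridable per call
TISSUE_T1 = {"wm": 850.0, "gm": 1400.0, "csf": 4200.0}
TISSUE_T2 = {"wm": 60.0, "gm": 80.0, "csf": 1500.0}
TISSUE_PD = {"wm": 0.70, "gm": 0.85, "csf": 1.00}
# CC segment T1 offsets (ms) relative to WM, anterior -> posterior:
# interior maximum at the mid-posterior segment (inverted U)
CC_T1_OFFSETS = (-30.0, 10.0, 45.0, 25.0, -15.0)


@dataclass
class QuantitativePhantom:
    """Ground-truth quantitative maps of one subject at one session."""

    t1_map: np.ndarray
    t2_map: np.ndarray
    pd_map: np.ndarray
    label_map: np.ndarray
    b0_map: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    tract_masks: dict[str, np.ndarray] = field(default_factory=dict)
    b0_pocket_mask: np.ndarray | None = None
    b0_pocket_center_vox: tuple[int, int, int] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.t1_map.shape

    @property
    def foreground(self) -> np.ndarray:
        return self.label_map > 0

    def wm_mask(self) -> np.ndarray:
        return (self.label_map == LABELS["wm"]) | np.isin(self.label_map, CC_LABELS)

    def copy(self) -> "QuantitativePhantom":
        return QuantitativePhantom(
            t1_map=self.t1_map.copy(),
            t2_map=self.t2_map.copy(),
            pd_map=self.pd_map.copy(),
            label_map=self.label_map.copy(),
            b0_map=self.b0_map.copy(),
            voxel_size_mm=self.voxel_size_mm,
            tract_masks={k: v.copy() for k, v in self.tract_masks.items()},
            b0_pocket_mask=None if self.b0_pocket_mask is None else self.b0_pocket_mask.copy(),
            b0_pocket_center_vox=self.b0_pocket_center_vox,
        )


def _smooth_noise(shape, rng, sigma_vox: float = 4.0) -> np.ndarray:
    """Zero-mean unit-RMS smooth random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    rms = np.sqrt(np.mean(f**2))
    return f / rms if rms > 0 else f


def make_phantom(
    shape: tuple[int, int, int] = (64, 64, 3),
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    seed: int = 0,
    wm_t1_ms: float = TISSUE_T1["wm"],
    texture_frac: float = 0.05,
    b0_pocket_amplitude_hz: float = 80.0,
) -> QuantitativePhantom:
    """Build an anatomy-like quantitative phantom.

    Axis conventions: axis 0 = left-right, axis 1 = anterior (low index)
    to posterior (high index), axis 2 = slice.  The corpus callosum is a
    para-midline band split into five equal anterior-posterior segments
    whose mean T1 follows an inverted U.
    """
    nx, ny, nz = shape
    if nx < 32 or ny < 32:
        raise ValueError("in-plane shape must be at least 32 voxels per axis")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF0]))

    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    rx, ry = 0.44 * nx, 0.46 * ny
    rho = np.sqrt(((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2)

    head = rho <= 1.0
    gm = (rho > 0.80) & head
    interior = rho <= 0.80

    # two lateral ventricles
    v1 = ((x - (cx - 0.16 * nx)) ** 2 / (0.06 * nx) ** 2
          + (y - cy) ** 2 / (0.14 * ny) ** 2) <= 1.0
    v2 = ((x - (cx + 0.16 * nx)) ** 2 / (0.06 * nx) ** 2
          + (y - cy) ** 2 / (0.14 * ny) ** 2) <= 1.0
    csf = (v1 | v2) & interior
    wm = interior & ~csf

    # corpus callosum: narrow para-midline band spanning anterior->posterior
    cc_band = (np.abs(x - cx) <= max(2, round(0.045 * nx))) & wm
    y0, y1 = cy - 0.30 * ny, cy + 0.30 * ny
    cc_band &= (y >= y0) & (y <= y1)

    label2d = np.zeros((nx, ny), dtype=np.int16)
    label2d[gm] = LABELS["gm"]
    label2d[wm] = LABELS["wm"]
    label2d[csf] = LABELS["csf"]
    edges = np.linspace(y0, y1, 6)
    for i, lab in enumerate(CC_LABELS):
        seg = cc_band & (y >= edges[i]) & (y < edges[i + 1] + (1 if i == 4 else 0))
        label2d[seg] = lab
    label_map = np.repeat(label2d[:, :, None], nz, axis=2)

    # tract-like mask channels inside WM (used by the tractometry module)
    tract2d_lr = (np.abs(y - cy) <= 1.5) & (np.abs(x - cx) <= 0.30 * nx)
    off = 0.26 * nx
    tract2d_ap_l = (np.abs(x - (cx - off)) <= 1.5) & (np.abs(y - cy) <= 0.30 * ny)
    tract2d_ap_r = (np.abs(x - (cx + off)) <= 1.5) & (np.abs(y - cy) <= 0.30 * ny)
    wm_any = (label_map == LABELS["wm"]) | np.isin(label_map, CC_LABELS)
    tract_masks = {
        "callosal_motor": np.repeat(tract2d_lr[:, :, None], nz, axis=2) & wm_any,
        "assoc_left": np.repeat(tract2d_ap_l[:, :, None], nz, axis=2) & wm_any,
        "assoc_right": np.repeat(tract2d_ap_r[:, :, None], nz, axis=2) & wm_any,
    }

    # quantitative maps with +/- texture_frac multiplicative texture
    t1 = np.zeros(shape)
    t2 = np.zeros(shape)
    pd = np.zeros(shape)
    tex = np.clip(texture_frac * _smooth_noise(shape, rng), -texture_frac, texture_frac)

    scale = wm_t1_ms / TISSUE_T1["wm"]
    class_t1 = {
        LABELS["wm"]: wm_t1_ms,
        LABELS["gm"]: TISSUE_T1["gm"],
        LABELS["csf"]: TISSUE_T1["csf"],
    }
    for i, lab in enumerate(CC_LABELS):
        class_t1[lab] = wm_t1_ms + CC_T1_OFFSETS[i] * scale
    class_t2 = {
        LABELS["wm"]: TISSUE_T2["wm"],
        LABELS["gm"]: TISSUE_T2["gm"],
        LABELS["csf"]: TISSUE_T2["csf"],
        **{lab: TISSUE_T2["wm"] for lab in CC_LABELS},
    }
    class_pd = {
        LABELS["wm"]: TISSUE_PD["wm"],
        LABELS["gm"]: TISSUE_PD["gm"],
        LABELS["csf"]: TISSUE_PD["csf"],
        **{lab: TISSUE_PD["wm"] for lab in CC_LABELS},
    }
    # texture perturbs T1 only; class T2 stays on the dictionary grid
    for lab, val in class_t1.items():
        m = label_map == lab
        t1[m] = val * (1 + tex[m])
        t2[m] = class_t2[lab]
        pd[m] = class_pd[lab]

    phantom = QuantitativePhantom(
        t1_map=t1,
        t2_map=t2,
        pd_map=pd,
        label_map=label_map,
        b0_map=np.zeros(shape),
        voxel_size_mm=voxel_size_mm,
        tract_masks=tract_masks,
    )
    make_b0_map(phantom, pocket_amplitude_hz=b0_pocket_amplitude_hz, seed=seed)
    return phantom


def make_b0_map(
    phantom: QuantitativePhantom,
    pocket_amplitude_hz: float = 80.0,
    background_rms_hz: float = 1.0,
    smooth_scale_vox: float = 8.0,
    pocket_sigma_vox: float = 2.5,
    seed: int = 0,
) -> np.ndarray:
    """Smooth off-resonance field plus one localised high-|B0| pocket.

    The pocket (a Gaussian bump) sits near the anterior boundary of the
    head, analogous to the field distortion above the sinuses.  The
    generated field, pocket mask (field above half the pocket amplitude)
    and pocket centre are stored on the phantom and returned.
    """
    if pocket_amplitude_hz < 0:
        raise ValueError("pocket_amplitude_hz must be >= 0")
    shape = phantom.shape
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB0]))
    if pocket_amplitude_hz == 0 and background_rms_hz == 0:
        field_hz = np.zeros(shape)
    else:
        field_hz = background_rms_hz * _smooth_noise(shape, rng, sigma_vox=smooth_scale_vox)

    nx, ny, nz = shape
    # the source (air cavity) sits at the anterior head boundary; its field
    # tail reaches into the adjacent anterior tissue
    center = (int(round((nx - 1) / 2)), int(round(0.08 * ny)), nz // 2)
    xx, yy, zz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    d2 = ((xx - center[0]) ** 2 + (yy - center[1]) ** 2) / pocket_sigma_vox**2
    if nz > 1:
        d2 = d2 + (zz - center[2]) ** 2 / (2.0 * pocket_sigma_vox) ** 2
    bump = pocket_amplitude_hz * np.exp(-0.5 * d2)
    field_hz = field_hz + bump

    phantom.b0_map = field_hz
    phantom.b0_pocket_mask = bump > pocket_amplitude_hz / 2.0 if pocket_amplitude_hz > 0 else np.zeros(shape, bool)
    phantom.b0_pocket_center_vox = center
    return field_hz


def make_coil_sensitivities(
    shape: tuple[int, int, int],
    n_coils: int = 4,
    seed: int = 0,
) -> np.ndarray:
    """Smooth complex coil maps, root-sum-of-squares 1 at every voxel."""
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    nx, ny, nz = shape
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    maps = np.empty((n_coils,) + tuple(shape), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(-0.2, 0.2)
        px = (nx - 1) / 2 + 0.6 * nx * np.cos(ang)
        py = (ny - 1) / 2 + 0.6 * ny * np.sin(ang)
        mag = np.exp(-(((xx - px) ** 2 + (yy - py) ** 2)) / (2 * (0.6 * nx) ** 2))
        gx, gy = rng.uniform(-np.pi, np.pi, size=2)
        phase = gx * (xx - px) / nx + gy * (yy - py) / ny + rng.uniform(0, 2 * np.pi)
        maps[c] = (mag * np.exp(1j * phase))[:, :, None] * np.ones(nz)[None, None, :]
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= rss[None]
    return maps


@dataclass
class CohortSpec:
    """Generative description of the simulated longitudinal cohort."""

    n_subjects: int = 40
    age_range_y: tuple[float, float] = (8.0, 13.0)
    r1_age_slope: float = 0.012  # 1/s per year of age, applied to WM R1
    r1_intercept: float = 1.05  # 1/s at age 0 (WM R1 ~ 1.18 at age 10.5)
    between_subject_sd: float = 0.02  # 1/s
    session_interval_months: tuple[float, float] = (2.0, 4.0)
    motion_sd: tuple[float, float] = (1.0, 1.0)  # (degrees, mm) inter-session
    noise_rel: float = 0.03  # k-space noise sd relative to RMS signal
    b0_pocket_amplitude_hz: float = 30.0  # sinus-analog field at the cohort's readout length
    shape: tuple[int, int, int] = (64, 64, 3)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.r1_age_slope < 0 or self.between_subject_sd < 0:
            raise ValueError("slope and between-subject sd must be >= 0")
        if any(s < 0 for s in self.motion_sd):
            raise ValueError("motion_sd components must be >= 0")


@dataclass
class SessionRealization:
    """One scan session: drifted phantom, pose vs session 1, noise seed."""

    phantom: QuantitativePhantom
    motion: RigidTransform
    noise_rel: float
    seed: int
    age_y: float
    wm_r1: float


@dataclass
class Subject:
    subject_id: int
    age_y: float
    sessions: list[SessionRealization]


def simulate_cohort(spec: CohortSpec) -> list[Subject]:
    """Draw a cohort of subjects, each with two scan sessions.

    White-matter R1 at session 1 is
    ``r1_intercept + r1_age_slope * age + b_i`` with subject effect
    ``b_i ~ N(0, between_subject_sd^2)``; session 2 adds a drift of
    ``r1_age_slope * interval`` along the same developmental slope, a
    random rigid motion, and an independent noise seed.
    """
    root = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0407]))
    subjects: list[Subject] = []
    for i in range(spec.n_subjects):
        rng = np.random.default_rng(root.integers(2**31))
        age = rng.uniform(*spec.age_range_y)
        b_i = rng.normal(0.0, spec.between_subject_sd) if spec.between_subject_sd > 0 else 0.0
        r1_s1 = spec.r1_intercept + spec.r1_age_slope * age + b_i
        interval_y = rng.uniform(*spec.session_interval_months) / 12.0
        r1_s2 = r1_s1 + spec.r1_age_slope * interval_y

        geom_seed = int(rng.integers(2**31))
        sessions = []
        for s, (r1, age_s) in enumerate([(r1_s1, age), (r1_s2, age + interval_y)]):
            ph = make_phantom(
                shape=spec.shape,
                voxel_size_mm=spec.voxel_size_mm,
                seed=geom_seed,  # same anatomy both sessions; only WM T1 drifts
                wm_t1_ms=1000.0 / r1,
                b0_pocket_amplitude_hz=spec.b0_pocket_amplitude_hz,
            )
            if s == 0 or (spec.motion_sd[0] == 0 and spec.motion_sd[1] == 0):
                motion = RigidTransform.identity()
            else:
                motion = RigidTransform(
                    angle_deg=rng.normal(0.0, spec.motion_sd[0]),
                    translation_mm=np.array(
                        [rng.normal(0.0, spec.motion_sd[1]),
                         rng.normal(0.0, spec.motion_sd[1]),
                         0.0]
                    ),
                )
            sessions.append(
                SessionRealization(
                    phantom=ph,
                    motion=motion,
                    noise_rel=spec.noise_rel,
                    seed=int(rng.integers(2**31)),
                    age_y=age_s,
                    wm_r1=r1,
                )
            )
        subjects.append(Subject(subject_id=i, age_y=age, sessions=sessions))
    return subjects
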