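"""Synthetic streamline bundles, along-tract profiles, and tract statistics.

Stands in for tractography: bundles are generated as smooth perturbations
of a core curve (plus optional gross outliers).  Cleaning mirrors the
standard tractometry rule — drop streamlines whose mean distance to the
tract core exceeds 3 standard deviations or whose length deviates by more
than 4 standard deviations, iterated up to five times.  Scalar maps are
sampled onto 100 equidistant arc-length nodes per streamline and combined
into a tract profile with distance-based weights; analyses use the middle
80 nodes, since end nodes suffer partial-volume mixing with gray matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "StreamlineBundle",
    "TractProfile",
    "generate_bundle",
    "clean_bundle",
    "tract_profile",
    "profile_reliability",
    "age_correlation",
    "default_tract_cores",
]

ANALYZED_NODES = slice(10, 90)  # middle 80 of 100


@dataclass
class StreamlineBundle:
    """A set of streamlines (mm coordinates) with their mean core curve."""

    streamlines: list[np.ndarray]
    name: str = "tract"
    orientation: str = "anterior-posterior"
    core_fiber: np.ndarray | None = None

    def __post_init__(self) -> None:
        for s in self.streamlines:
            if not np.all(np.isfinite(s)):
                raise ValueError("streamline contains non-finite points")
        if self.core_fiber is None and self.streamlines:
            self.core_fiber = _core(self.streamlines, 100)

    @property
    def n_streamlines(self) -> int:
        return len(self.streamlines)


@dataclass
class TractProfile:
    node_values: np.ndarray
    node_weights: np.ndarray  # (n_streamlines, n_nodes), columns sum to 1
    name: str = "tract"
    analyzed_slice: slice = field(default_factory=lambda: ANALYZED_NODES)

    def mean(self) -> float:
        return float(np.nanmean(self.node_values[self.analyzed_slice]))


def _resample(points: np.ndarray, n_nodes: int) -> np.ndarray:
    """Resample a polyline to equidistant arc-length nodes."""
    d = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    if s[-1] == 0:
        return np.repeat(points[:1], n_nodes, axis=0)
    u = np.linspace(0.0, s[-1], n_nodes)
    return np.stack([np.interp(u, s, points[:, i]) for i in range(3)], axis=1)


def _core(streamlines: list[np.ndarray], n_nodes: int) -> np.ndarray:
    rs = np.stack([_resample(s, n_nodes) for s in streamlines])
    return rs.mean(axis=0)


def generate_bundle(
    core_curve: np.ndarray,
    n_streamlines: int = 60,
    spread_mm: float = 2.0,
    outlier_frac: float = 0.0,
    seed: int = 0,
    name: str = "tract",
    orientation: str = "anterior-posterior",
) -> StreamlineBundle:
    """Perturb a smooth core curve into a bundle.

    Each streamline adds a smooth random displacement field of scale
    ``spread_mm`` (white noise heavily smoothed along the curve, i.e. a
    squared-exponential-like process).  A fraction ``outlier_frac`` of
    streamlines is additionally displaced by 8 x spread (well clear of
    the inlier distance distribution) so the cleaning step has
    unambiguously gross outliers to find.
    """
    core_curve = np.asarray(core_curve, dtype=float)
    if core_curve.shape[0] < 20:
        raise ValueError("core curve needs at least 20 points")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A]))
    n_pts = core_curve.shape[0]
    n_out = int(round(outlier_frac * n_streamlines))
    streamlines = []
    for i in range(n_streamlines):
        if spread_mm > 0:
            noise = rng.standard_normal((n_pts, 3))
            smooth = ndimage.gaussian_filter1d(noise, sigma=n_pts / 6, axis=0, mode="nearest")
            rms = np.sqrt(np.mean(smooth**2))
            disp = spread_mm * smooth / (rms if rms > 0 else 1.0)
        else:
            disp = np.zeros((n_pts, 3))
        sl = core_curve + disp
        if i < n_out:
            # gross outliers: displaced well beyond the bundle spread
            direction = rng.standard_normal(3)
            direction[2] = 0.0
            direction /= np.linalg.norm(direction)
            offset = max(8.0 * spread_mm, 8.0) * direction
            sl = sl + offset
        streamlines.append(sl)
    return StreamlineBundle(streamlines=streamlines, name=name, orientation=orientation,
                            core_fiber=core_curve.copy())


def clean_bundle(
    bundle: StreamlineBundle,
    core_sd: float = 3.0,
    length_sd: float = 4.0,
    iterations: int = 5,
    n_nodes: int = 100,
) -> StreamlineBundle:
    """Iteratively drop outlier streamlines.

    At each pass the node-wise mean core is recomputed; streamlines whose
    mean node distance to the core exceeds the distance distribution's
    centre by more than ``core_sd`` scale units, or whose length exceeds
    the mean length by more than ``length_sd`` standard deviations, are
    removed.  Both rules are one-sided ("deviates by more than",
    "longer than").  The distance scale is robust (sd of the bulk after a
    5-MAD pre-trim): with the ordinary sample sd, a 10% fraction of gross
    outliers inflates the scale to exactly the 3-sigma masking point
    (0.9 / sqrt(0.09) = 3), and arbitrarily gross outliers survive.
    Stops early once stable.
    """
    if bundle.n_streamlines < 10:
        raise ValueError("cleaning requires at least 10 streamlines")
    keep = list(bundle.streamlines)
    for _ in range(iterations):
        rs = np.stack([_resample(s, n_nodes) for s in keep])
        core = rs.mean(axis=0)
        dist = np.linalg.norm(rs - core[None], axis=2).mean(axis=1)
        lengths = np.array(
            [np.linalg.norm(np.diff(s, axis=0), axis=1).sum() for s in keep]
        )
        ok = np.ones(len(keep), dtype=bool)
        center = float(np.median(dist))
        mad = 1.4826 * float(np.median(np.abs(dist - center)))
        # scale = sd of the bulk after a generous MAD pre-trim: robust to
        # gross outliers without the skew bias of a raw MAD scale
        bulk = dist[dist <= center + 5 * mad] if mad > 0 else dist
        scale = float(bulk.std(ddof=1)) if bulk.size > 1 else 0.0
        if scale > 0:
            ok &= dist <= center + core_sd * scale
        if lengths.std(ddof=1) > 0:
            ok &= lengths <= lengths.mean() + length_sd * lengths.std(ddof=1)
        if np.all(ok):
            break
        keep = [s for s, k in zip(keep, ok) if k]
        if not keep:
            raise ValueError("cleaning removed every streamline (degenerate bundle)")
    return StreamlineBundle(
        streamlines=keep, name=bundle.name, orientation=bundle.orientation
    )


def tract_profile(
    bundle: StreamlineBundle,
    scalar_map: np.ndarray,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_nodes: int = 100,
    name: str | None = None,
) -> TractProfile:
    """Weighted along-tract profile of a scalar map.

    Every streamline is resampled to ``n_nodes`` equidistant arc-length
    nodes; the scalar is linearly interpolated at each node point and the
    node value is the weighted average across streamlines, with Gaussian
    weights on the distance from the node's cross-sectional centroid
    (scaled by the node's spread).  Node points outside the map are
    masked from the average.
    """
    rs = np.stack([_resample(s, n_nodes) for s in bundle.streamlines])  # (S, N, 3)
    if bundle.orientation == "anterior-posterior":
        axis = 1
    else:
        axis = 0
    # enforce consistent node ordering along the orientation axis
    flip = rs[:, -1, axis] < rs[:, 0, axis]
    rs[flip] = rs[flip, ::-1]

    centroid = rs.mean(axis=0)  # (N, 3)
    d = np.linalg.norm(rs - centroid[None], axis=2)  # (S, N)
    sigma = d.std(axis=0, ddof=0)
    sigma[sigma == 0] = 1.0
    w = np.exp(-0.5 * (d / sigma[None]) ** 2)

    vox = np.asarray(voxel_size_mm, dtype=float)
    pts_vox = rs / vox[None, None, :]
    shape = np.asarray(scalar_map.shape)
    # half-voxel margin: points within the voxel extent count as inside
    inside = np.all(
        (pts_vox >= -0.5) & (pts_vox <= shape[None, None] - 0.5), axis=2
    )
    vals = ndimage.map_coordinates(
        np.asarray(scalar_map, dtype=float),
        pts_vox.reshape(-1, 3).T,
        order=1,
        mode="nearest",
    ).reshape(d.shape)
    w = w * inside
    wsum = w.sum(axis=0)
    node_values = np.full(n_nodes, np.nan)
    ok = wsum > 0
    node_values[ok] = (w * np.where(inside, vals, 0.0)).sum(axis=0)[ok] / wsum[ok]
    w_norm = np.divide(w, wsum[None], out=np.zeros_like(w), where=wsum[None] > 0)
    return TractProfile(
        node_values=node_values, node_weights=w_norm, name=name or bundle.name
    )


def profile_reliability(
    profiles_s1: dict[int, TractProfile],
    profiles_s2: dict[int, TractProfile],
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Across-subject scan-rescan reliability of one tract's profiles.

    Tract-mean reliability is the Pearson r of per-subject profile means
    (middle 80 nodes) between sessions, with a 68% bootstrap percentile
    CI over subjects; per-node reliability is the across-subject r at
    each analyzed node.
    """
    subjects = sorted(set(profiles_s1) & set(profiles_s2))
    if len(subjects) < 3:
        raise ValueError("profile reliability requires at least 3 matched subjects")
    m1 = np.array([profiles_s1[s].mean() for s in subjects])
    m2 = np.array([profiles_s2[s].mean() for s in subjects])
    v1 = np.stack([profiles_s1[s].node_values[ANALYZED_NODES] for s in subjects])
    v2 = np.stack([profiles_s2[s].node_values[ANALYZED_NODES] for s in subjects])

    def _r(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
    n = len(subjects)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots.append(_r(m1[idx], m2[idx]))
    boots = np.asarray([b for b in boots if np.isfinite(b)])
    ci = (np.percentile(boots, 16), np.percentile(boots, 84)) if boots.size else (np.nan, np.nan)
    return {
        "tract_mean_r": _r(m1, m2),
        "tract_mean_r_ci68": (float(ci[0]), float(ci[1])),
        "per_node_r": np.array([_r(v1[:, j], v2[:, j]) for j in range(v1.shape[1])]),
        "n_subjects": n,
    }


def age_correlation(
    tract_r1_means: dict[str, np.ndarray],
    ages: np.ndarray,
    fdr_q: float = 0.05,
):
    """Pearson correlation of tract-mean R1 with age, BH-FDR corrected.

    Returns a DataFrame with one row per tract: r, p, FDR-adjusted p and
    a significance flag at ``fdr_q``.
    """
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    ages = np.asarray(ages, dtype=float)
    if ages.size < 10:
        raise ValueError("age correlation requires at least 10 subjects")
    if np.std(ages) == 0:
        raise ValueError("ages are constant")
    rows = []
    for name, vals in tract_r1_means.items():
        vals = np.asarray(vals, dtype=float)
        f = np.isfinite(vals)
        r, p = stats.pearsonr(ages[f], vals[f])
        rows.append({"tract": name, "r": float(r), "p": float(p), "n": int(f.sum())})
    df = pd.DataFrame(rows)
    rej, p_adj, _, _ = multipletests(df["p"], alpha=fdr_q, method="fdr_bh")
    df["p_fdr"] = p_adj
    df["significant"] = rej
    return df


def default_tract_cores(
    shape: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float],
    n_points: int = 40,
) -> dict[str, np.ndarray]:
    """Core curves of the synthetic tract set, in mm.

    Seven callosal-analog arcs spanning left-right at increasing
    anterior-posterior positions, plus seven hemispheric-analog curves
    running anterior-posterior at alternating lateral offsets — a
    reduced-count analog of a standard whole-brain tract inventory.
    """
    nx, ny, nz = shape
    vox = np.asarray(voxel_size_mm)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    z = (nz - 1) / 2.0
    cores = {}
    u = np.linspace(-1.0, 1.0, n_points)
    for i in range(7):
        ypos = cy + (i - 3) * 0.09 * ny
        x = cx + 0.28 * nx * u
        y = ypos - 0.04 * ny * (1 - u**2)  # gentle arc
        pts = np.stack([x, y, np.full(n_points, z)], axis=1) * vox[None]
        cores[f"callosal_{i + 1}"] = pts
    for i in range(7):
        side = -1 if i % 2 == 0 else 1
        xpos = cx + side * (0.12 + 0.045 * (i // 2)) * nx
        y = cy + 0.28 * ny * u
        x = xpos + 0.02 * nx * np.sin(np.pi * u)
        pts = np.stack([x, y, np.full(n_points, z)], axis=1) * vox[None]
        cores[f"assoc_{i + 1}"] = pts
    return cores
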