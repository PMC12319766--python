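"""Scan-rescan reliability statistics.

Three complementary views of test-retest agreement are provided:
voxelwise Pearson correlation plus an R^2 computed about the identity
line y = x (sensitive to additive bias, unlike Pearson's r); per-ROI
across-subject correlation and the two-measurement coefficient of
variation CV = sd(a, b) / mean(a, b) * 100 with sd = |a - b| / sqrt(2);
and Bland-Altman difference summaries.  A linear mixed-effects model
(r ~ duration * B0 + age + random subject intercept) quantifies how scan
duration and off-resonance correction contribute to reliability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReliabilityResult",
    "voxelwise_reliability",
    "roi_reliability",
    "bland_altman",
    "fit_reliability_lmm",
    "two_point_cv",
]

log = logging.getLogger(__name__)


@dataclass
class ReliabilityResult:
    pearson_r: float
    r2_identity: float
    cv_percent: float
    n: int
    unit: str = "voxel-set"

    def __post_init__(self) -> None:
        if np.isfinite(self.pearson_r) and not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("pearson_r out of [-1, 1]")


def two_point_cv(a: float, b: float) -> float:
    """CV%% of two measurements: sd = |a - b|/sqrt(2), mean = (a + b)/2."""
    m = 0.5 * (a + b)
    if m == 0:
        return np.nan
    return abs(a - b) / np.sqrt(2.0) / m * 100.0


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _r2_identity(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 of session-2 values about the fixed line y = x (no fitting)."""
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return np.nan
    return 1.0 - float(np.sum((y - x) ** 2)) / ss_tot


def voxelwise_reliability(
    map1: np.ndarray,
    map2: np.ndarray,
    mask: np.ndarray | None = None,
) -> ReliabilityResult:
    """Pearson r, identity-line R^2 and mean two-point CV over voxels.

    Non-finite voxels in either map are excluded pairwise (intersection
    mask); a constant input yields NaN statistics rather than an error.
    """
    map1, map2 = np.asarray(map1, float), np.asarray(map2, float)
    if map1.shape != map2.shape:
        raise ValueError("maps must share one grid")
    m = np.isfinite(map1) & np.isfinite(map2)
    if mask is not None:
        m &= np.asarray(mask, bool)
    if not np.any(m):
        raise ValueError("mask selects no voxels")
    x, y = map1[m], map2[m]
    means = 0.5 * (x + y)
    ok = means != 0
    cv = float(np.mean(np.abs(x - y)[ok] / np.sqrt(2.0) / means[ok] * 100.0)) if np.any(ok) else np.nan
    return ReliabilityResult(
        pearson_r=_pearson(x, y),
        r2_identity=_r2_identity(x, y),
        cv_percent=cv,
        n=int(m.sum()),
        unit="voxel-set",
    )


def roi_reliability(
    t1_session1: dict[int, np.ndarray] | list[np.ndarray],
    t1_session2: dict[int, np.ndarray] | list[np.ndarray],
    label_maps: dict[int, np.ndarray] | list[np.ndarray],
    roi_ids: dict[str, int | list[int]],
) -> pd.DataFrame:
    """Across-subject ROI reliability table.

    For each ROI, the mean T1 inside the ROI labels is computed per
    subject and session; the table reports across-subject Pearson r and
    identity-line R^2 between sessions, plus the mean per-subject
    two-point CV.  Subjects with an empty ROI are dropped with a log
    entry.
    """
    if isinstance(t1_session1, dict):
        subjects = sorted(t1_session1)
    else:
        subjects = list(range(len(t1_session1)))
        t1_session1 = dict(enumerate(t1_session1))
        t1_session2 = dict(enumerate(t1_session2))
        label_maps = dict(enumerate(label_maps))
    rows = []
    for roi_name, labels in roi_ids.items():
        labels = [labels] if np.isscalar(labels) else list(labels)
        a, b = [], []
        for s in subjects:
            sel = np.isin(label_maps[s], labels)
            if not np.any(sel):
                log.info("roi_reliability: subject %s has empty ROI %s; dropped", s, roi_name)
                continue
            v1, v2 = t1_session1[s][sel], t1_session2[s][sel]
            f = np.isfinite(v1) & np.isfinite(v2)
            if not np.any(f):
                log.info("roi_reliability: subject %s ROI %s all-NaN; dropped", s, roi_name)
                continue
            a.append(float(v1[f].mean()))
            b.append(float(v2[f].mean()))
        a, b = np.asarray(a), np.asarray(b)
        cvs = [two_point_cv(x, y) for x, y in zip(a, b)]
        rows.append(
            {
                "roi": roi_name,
                "n_subjects": a.size,
                "pearson_r": _pearson(a, b) if a.size >= 3 else np.nan,
                "r2_identity": _r2_identity(a, b) if a.size >= 3 else np.nan,
                "cv_percent": float(np.nanmean(cvs)) if cvs else np.nan,
            }
        )
    return pd.DataFrame(rows)


def bland_altman(pairs: np.ndarray) -> dict:
    """Bland-Altman summary of paired measurements (n x 2 array).

    Returns the mean difference (bias), the +/-1.96 sd limits of
    agreement, and the per-pair means/differences for plotting.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("pairs must be an (n >= 2, 2) array")
    diff = pairs[:, 1] - pairs[:, 0]
    mean = pairs.mean(axis=1)
    sd = float(diff.std(ddof=1))
    md = float(diff.mean())
    return {
        "mean_difference": md,
        "loa_low": md - 1.96 * sd,
        "loa_high": md + 1.96 * sd,
        "sd_difference": sd,
        "means": mean,
        "differences": diff,
    }


def fit_reliability_lmm(table: pd.DataFrame) -> dict:
    """Mixed model r ~ duration * b0 + age + (1 | participant), REML.

    ``table`` needs columns participant, duration (minutes, 2 or 4), b0
    (0/1), age, r; the factorial must be complete per participant.
    Returns fixed-effect estimates with standard errors and t statistics,
    the random-intercept variance, and a convergence/singularity flag.
    """
    import statsmodels.formula.api as smf

    required = {"participant", "duration", "b0", "age", "r"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must contain columns {sorted(required)}")
    counts = table.groupby("participant").size()
    if counts.nunique() != 1 or counts.iloc[0] != 4:
        raise ValueError("table must contain the complete 2x2 factorial per participant")

    df = table.copy()
    df["duration4"] = (df["duration"] == 4).astype(float)
    df["b0"] = df["b0"].astype(float)
    if float(np.var(df["r"])) == 0.0:
        # degenerate: identical responses; all effects and variances are 0
        zeros = {k: {"estimate": 0.0, "se": np.nan, "t": np.nan}
                 for k in ("Intercept", "duration4", "b0", "duration4:b0", "age")}
        zeros["Intercept"]["estimate"] = float(df["r"].iloc[0])
        return {"fixed_effects": zeros, "random_intercept_var": 0.0,
                "residual_var": 0.0, "singular": True}

    model = smf.mixedlm("r ~ duration4 * b0 + age", df, groups=df["participant"])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    fe = {
        name: {
            "estimate": float(fit.params[name]),
            "se": float(fit.bse[name]),
            "t": float(fit.tvalues[name]),
        }
        for name in fit.fe_params.index
    }
    singular = bool(getattr(fit, "converged", True) is False or np.any(~np.isfinite(fit.bse[fit.fe_params.index])))
    return {
        "fixed_effects": fe,
        "random_intercept_var": float(fit.cov_re.iloc[0, 0]),
        "residual_var": float(fit.scale),
        "singular": singular,
    }
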