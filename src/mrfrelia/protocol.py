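"""Acquisition protocol and dictionary grid definitions.

The fingerprinting sequence modelled here is an inversion-prepared,
gradient-spoiled echo train: each acquisition *group* starts with an
adiabatic inversion pulse (inversion time 15 ms), followed by a train of
excitations with a smoothly varying flip-angle schedule, one readout per
TR.  A rest period (1.2 s by default) separates groups so longitudinal
magnetization can recover.  A full scan concatenates ``n_groups`` such
groups; two scans with complementary k-space sampling can be combined
into a double-duration acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionProtocol", "DictionaryGrid", "default_flip_schedule"]


def default_flip_schedule(n_trs: int, min_deg: float = 5.0, max_deg: float = 35.0) -> np.ndarray:
    """Smooth pseudo-sinusoidal flip-angle ramp used within each group.

    Rises from ``min_deg`` to ``max_deg`` mid-train and back, giving the
    varying T1/T2 weighting that makes fingerprints distinguishable.  The
    moderate peak flip keeps the fingerprint family compact enough that a
    five-component temporal basis captures it almost completely, which is
    what makes the subspace reconstruction well posed.
    """
    if n_trs < 1:
        raise ValueError("n_trs must be >= 1")
    if n_trs == 1:
        return np.array([max_deg])
    i = np.arange(n_trs)
    return min_deg + (max_deg - min_deg) * np.sin(np.pi * i / (n_trs - 1))


@dataclass
class AcquisitionProtocol:
    """Timing and flip-angle description of one fingerprinting scan.

    Parameters
    ----------
    inversion_time_ms
        Delay between the inversion pulse and the first excitation of a group.
    n_groups
        Number of inversion-prepared acquisition groups (16 for a single
        scan; a combined two-scan acquisition has 32).
    trs_per_group
        Excitations (and readouts) per group.
    rest_s
        Free-recovery time after each group.
    tr_ms, te_ms
        Repetition and echo time of each excitation.
    flip_schedule_deg
        Flip angles, one per TR within a group; the same schedule repeats
        in every group.
    group_trajectory_ids
        Which sampling pattern each group uses (defaults to one pattern
        per group).
    """

    inversion_time_ms: float = 15.0
    n_groups: int = 16
    trs_per_group: int = 500
    rest_s: float = 1.2
    tr_ms: float = 12.0
    te_ms: float = 1.8
    flip_schedule_deg: np.ndarray | None = None
    group_trajectory_ids: np.ndarray | None = None
    inversion_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.flip_schedule_deg is None:
            self.flip_schedule_deg = default_flip_schedule(self.trs_per_group)
        self.flip_schedule_deg = np.asarray(self.flip_schedule_deg, dtype=float)
        if self.group_trajectory_ids is None:
            self.group_trajectory_ids = np.arange(self.n_groups)
        self.group_trajectory_ids = np.asarray(self.group_trajectory_ids)
        for name in ("inversion_time_ms", "rest_s", "tr_ms", "te_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_groups < 1 or self.trs_per_group < 1:
            raise ValueError("n_groups and trs_per_group must be >= 1")
        if self.flip_schedule_deg.shape != (self.trs_per_group,):
            raise ValueError(
                "flip_schedule_deg must have length trs_per_group "
                f"({self.flip_schedule_deg.shape[0]} != {self.trs_per_group})"
            )
        if np.any(self.flip_schedule_deg < 0) or np.any(self.flip_schedule_deg > 90):
            raise ValueError("flip angles must lie in [0, 90] degrees")
        if self.te_ms >= self.tr_ms:
            raise ValueError("te_ms must be smaller than tr_ms")
        if not (0.0 <= self.inversion_efficiency <= 1.0):
            raise ValueError("inversion_efficiency must lie in [0, 1]")

    @property
    def n_timepoints(self) -> int:
        return self.n_groups * self.trs_per_group

    @classmethod
    def desk_scale(cls, n_groups: int = 16, trs_per_group: int = 60, **kw) -> "AcquisitionProtocol":
        """Reduced-size protocol for fast simulation; same structure."""
        return cls(n_groups=n_groups, trs_per_group=trs_per_group, **kw)

    def to_dict(self) -> dict:
        return {
            "inversion_time_ms": self.inversion_time_ms,
            "n_groups": int(self.n_groups),
            "trs_per_group": int(self.trs_per_group),
            "rest_s": self.rest_s,
            "tr_ms": self.tr_ms,
            "te_ms": self.te_ms,
            "flip_schedule_deg": self.flip_schedule_deg.tolist(),
            "inversion_efficiency": self.inversion_efficiency,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        d = dict(d)
        if "flip_schedule_deg" in d and d["flip_schedule_deg"] is not None:
            d["flip_schedule_deg"] = np.asarray(d["flip_schedule_deg"], dtype=float)
        return cls(**d)


def _grid(start: float, stop: float, step: float) -> np.ndarray:
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass
class DictionaryGrid:
    """T1 x T2 grid over which fingerprint atoms are simulated.

    Default T1 values: 20..3000 ms in 20 ms steps, then 3200..5000 ms in
    coarse 200 ms steps (long-T1 CSF range).  Only physically valid pairs
    with T2 <= T1 are simulated.
    """

    t1_values_ms: np.ndarray = field(default_factory=lambda: np.concatenate(
        [_grid(20, 3000, 20), _grid(3200, 5000, 200)]))
    t2_values_ms: np.ndarray = field(default_factory=lambda: np.concatenate(
        [_grid(10, 300, 10), _grid(500, 2000, 100)]))

    def __post_init__(self) -> None:
        self.t1_values_ms = np.asarray(self.t1_values_ms, dtype=float)
        self.t2_values_ms = np.asarray(self.t2_values_ms, dtype=float)
        for name, v in (("t1_values_ms", self.t1_values_ms), ("t2_values_ms", self.t2_values_ms)):
            if v.size == 0:
                raise ValueError(f"{name} is empty")
            if np.any(v <= 0):
                raise ValueError(f"{name} must be positive")
            if np.any(np.diff(v) <= 0):
                raise ValueError(f"{name} must be strictly increasing")

    def pairs(self) -> np.ndarray:
        """All (T1, T2) pairs with T2 <= T1, as an (n, 2) array."""
        t1, t2 = np.meshgrid(self.t1_values_ms, self.t2_values_ms, indexing="ij")
        mask = t2 <= t1
        return np.stack([t1[mask], t2[mask]], axis=1)

    @classmethod
    def desk_scale(cls) -> "DictionaryGrid":
        """Coarser grid for quick tests (same span, fewer atoms)."""
        return cls(
            t1_values_ms=np.concatenate([_grid(20, 3000, 20), _grid(3200, 5000, 200)]),
            t2_values_ms=np.array([20.0, 60.0, 100.0, 300.0, 1000.0, 2000.0]),
        )
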