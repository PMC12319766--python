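"""Desk-scale k-space sampling schemes.

A pseudo-random Cartesian mask per acquisition group stands in for the
3D spiral-projection trajectories of the scanner sequence: the subspace
reconstruction model (mask x Fourier x coils x basis) is
trajectory-agnostic.  Samples within a group are distributed round-robin
over the group's TRs, and each sample carries an acquisition time along a
0-5 ms readout ramp (quantised to a small set of distinct times so the
exact off-resonance operator is computable).  A scan pair can be made
*complementary*: the second scan samples k-space locations disjoint from
the first wherever the undersampling factor permits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SamplingScheme", "make_sampling_scheme", "make_scheme_pair"]


@dataclass
class SamplingScheme:
    """Per-group k-space sample coordinates, TR assignment, and times.

    coords
        (n_groups, n_samples, 3) frequency coordinates in cycles/FOV;
        integer-valued coordinates lie on the FFT grid.
    tr_index
        (n_groups, n_samples) TR within the group acquiring each sample.
    time_ms
        (n_groups, n_samples) time from excitation to sample acquisition.
    """

    shape: tuple[int, int, int]
    coords: np.ndarray
    tr_index: np.ndarray
    time_ms: np.ndarray
    trs_per_group: int
    readout_times_ms: np.ndarray
    complementary: bool = False

    def __post_init__(self) -> None:
        nyq = np.asarray(self.shape) / 2.0
        if np.any(np.abs(self.coords) > nyq[None, None, :] + 1e-9):
            raise ValueError("sample coordinates exceed the grid Nyquist limit")
        if np.any(self.time_ms < 0):
            raise ValueError("sample times must be nonnegative")
        if self.tr_index.min() < 0 or self.tr_index.max() >= self.trs_per_group:
            raise ValueError("tr_index out of range")

    @property
    def n_groups(self) -> int:
        return self.coords.shape[0]

    @property
    def n_samples_per_group(self) -> int:
        return self.coords.shape[1]

    def group_on_grid(self, g: int) -> bool:
        c = self.coords[g]
        return bool(np.allclose(c, np.round(c), atol=1e-9))


def _assign_times(
    n_samples: int, trs_per_group: int, readout_ms: float, n_readout_times: int
):
    """Round-robin TR assignment and quantised readout-time ramp."""
    j = np.arange(n_samples)
    tr = j % trs_per_group
    pos_in_tr = j // trs_per_group
    times = np.linspace(0.0, readout_ms, n_readout_times)
    t = times[pos_in_tr % n_readout_times]
    return tr, t, times


def make_sampling_scheme(
    shape: tuple[int, int, int],
    n_groups: int,
    trs_per_group: int,
    undersampling: float = 1.0,
    seed: int = 0,
    readout_ms: float = 5.0,
    n_readout_times: int = 16,
    full_kt: bool = False,
) -> SamplingScheme:
    """One scan's sampling scheme.

    ``undersampling`` = 1 distributes one full k-space coverage per group
    over the group's TRs.  ``full_kt`` instead samples the *entire* grid at
    *every* TR (no undersampling in k-t at all); with unit-RSS coils this
    makes the encoding operator's normal matrix the identity, so an
    unregularized reconstruction recovers the temporal projection of the
    true signals exactly.
    """
    if full_kt:
        nx, ny, nz = shape
        grid = np.stack(
            np.meshgrid(
                np.arange(nx) - nx // 2,
                np.arange(ny) - ny // 2,
                np.arange(nz) - nz // 2,
                indexing="ij",
            ),
            axis=-1,
        ).reshape(-1, 3)
        nvox = grid.shape[0]
        coords = np.tile(grid, (trs_per_group, 1))  # TR-major blocks
        tr = np.repeat(np.arange(trs_per_group), nvox)
        times_nodes = np.linspace(0.0, readout_ms, n_readout_times)
        t = times_nodes[np.tile(np.arange(nvox) % n_readout_times, trs_per_group)]
        return SamplingScheme(
            shape=tuple(shape),
            coords=np.broadcast_to(coords, (n_groups,) + coords.shape).copy(),
            tr_index=np.broadcast_to(tr, (n_groups, tr.size)).copy(),
            time_ms=np.broadcast_to(t, (n_groups, t.size)).copy(),
            trs_per_group=trs_per_group,
            readout_times_ms=times_nodes,
            complementary=False,
        )
    s1, _ = make_scheme_pair(
        shape, n_groups, trs_per_group, undersampling, seed, readout_ms, n_readout_times
    )
    s1.complementary = False
    return s1


def make_scheme_pair(
    shape: tuple[int, int, int],
    n_groups: int,
    trs_per_group: int,
    undersampling: float = 2.0,
    seed: int = 0,
    readout_ms: float = 5.0,
    n_readout_times: int = 16,
) -> tuple[SamplingScheme, SamplingScheme]:
    """Two complementary schemes (scan 2 interleaves scan 1's coverage)."""
    if undersampling < 1.0:
        raise ValueError("undersampling factor must be >= 1")
    nx, ny, nz = shape
    n_total = nx * ny * nz
    n_samp = max(1, int(round(n_total / undersampling)))
    grid = np.stack(
        np.meshgrid(
            np.arange(nx) - nx // 2,
            np.arange(ny) - ny // 2,
            np.arange(nz) - nz // 2,
            indexing="ij",
        ),
        axis=-1,
    ).reshape(-1, 3)

    # variable density: centre-weighted inclusion probability so the heavy
    # low-frequency content is always covered (uniform masks occasionally
    # leave the centre under-sampled, which destabilises the fit)
    kr2 = (
        (grid[:, 0] / nx) ** 2 + (grid[:, 1] / ny) ** 2 + (grid[:, 2] / max(nz, 1)) ** 2
    )
    weights = np.exp(-kr2 / (2 * 0.15**2)) + 0.05

    coords = np.empty((2, n_groups, n_samp, 3))
    for g in range(n_groups):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5A, g]))
        # exponential-key trick = weighted sampling without replacement
        keys = rng.exponential(size=n_total) / weights
        perm = np.argsort(keys)
        idx1 = perm[:n_samp]
        # complementary coverage: take the next block (wraps when R < 2)
        idx2 = perm[np.arange(n_samp, 2 * n_samp) % n_total]
        coords[0, g] = grid[idx1]
        coords[1, g] = grid[idx2]

    tr, t, times = _assign_times(n_samp, trs_per_group, readout_ms, n_readout_times)
    tr = np.broadcast_to(tr, (n_groups, n_samp)).copy()
    t = np.broadcast_to(t, (n_groups, n_samp)).copy()
    mk = lambda c: SamplingScheme(
        shape=tuple(shape),
        coords=c,
        tr_index=tr,
        time_ms=t,
        trs_per_group=trs_per_group,
        readout_times_ms=times,
        complementary=True,
    )
    return mk(coords[0]), mk(coords[1])
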