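"""Fingerprint dictionary, temporal subspace basis, and synthetic T1w images.

The dictionary holds one unit-norm complex signal evolution ("atom") per
(T1, T2) pair on a physically valid grid.  A singular value decomposition
of the atom matrix yields a low-dimensional temporal basis: the first
K = 5 right singular vectors capture essentially all dictionary energy,
so time-resolved images can be represented by K coefficient maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .epg import epg_simulate_batch
from .protocol import AcquisitionProtocol, DictionaryGrid

__all__ = [
    "Dictionary",
    "SubspaceBasis",
    "build_dictionary",
    "compute_subspace",
    "synthesize_t1w",
]


@dataclass
class Dictionary:
    """Simulated fingerprint atoms with their tissue parameters.

    ``atoms`` has shape (n_atoms, n_timepoints); every row has unit
    Euclidean norm.  ``params`` has shape (n_atoms, 2) holding (T1, T2)
    in ms.
    """

    atoms: np.ndarray
    params: np.ndarray
    protocol: AcquisitionProtocol

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.atoms.shape[1]

    def save(self, path: str | Path) -> None:
        """Persist atoms + parameters + protocol in an npz container."""
        import json

        np.savez_compressed(
            path,
            atoms=self.atoms,
            params=self.params,
            protocol_json=np.array(json.dumps(self.protocol.to_dict())),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Dictionary":
        import json

        with np.load(path, allow_pickle=False) as f:
            protocol = AcquisitionProtocol.from_dict(json.loads(str(f["protocol_json"])))
            return cls(atoms=f["atoms"], params=f["params"], protocol=protocol)


@dataclass
class SubspaceBasis:
    """Temporal subspace basis Phi (n_timepoints x K), columns orthonormal."""

    phi: np.ndarray
    singular_values: np.ndarray

    @property
    def k(self) -> int:
        return self.phi.shape[1]

    @property
    def captured_energy(self) -> float:
        """Fraction of total squared singular-value energy in the basis."""
        s2 = self.singular_values**2
        return float(s2[: self.k].sum() / s2.sum())

    def save(self, path: str | Path) -> None:
        np.savez_compressed(path, phi=self.phi, singular_values=self.singular_values)

    @classmethod
    def load(cls, path: str | Path) -> "SubspaceBasis":
        with np.load(path, allow_pickle=False) as f:
            return cls(phi=f["phi"], singular_values=f["singular_values"])


def build_dictionary(
    grid: DictionaryGrid,
    protocol: AcquisitionProtocol,
    n_states: int = 30,
) -> Dictionary:
    """Simulate and normalise one atom per valid (T1, T2) grid pair."""
    pairs = grid.pairs()
    if pairs.shape[0] == 0:
        raise ValueError("dictionary grid produced no valid (T1, T2) pairs")
    atoms = epg_simulate_batch(pairs[:, 0], pairs[:, 1], protocol, n_states=n_states)
    norms = np.linalg.norm(atoms, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-signal atom encountered; check the protocol")
    return Dictionary(atoms=atoms / norms, params=pairs, protocol=protocol)


def compute_subspace(dictionary: Dictionary, k: int = 5) -> SubspaceBasis:
    """SVD of the atom matrix; keep the first k temporal singular vectors."""
    n_t = dictionary.n_timepoints
    if not 1 <= k <= n_t:
        raise ValueError(f"k must lie in [1, {n_t}]")
    # temporal side: right singular vectors of (n_atoms x n_timepoints)
    _, s, vh = np.linalg.svd(dictionary.atoms, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(dictionary.atoms.shape) * np.finfo(float).eps))
    if k > rank:
        raise ValueError(f"k={k} exceeds numerical rank {rank}")
    return SubspaceBasis(phi=vh[:k].conj().T.copy(), singular_values=s)


def synthesize_t1w(
    t1_map: np.ndarray,
    t2_map: np.ndarray,
    pd_map: np.ndarray,
    ti_ms: float = 1100.0,
    tr_ms: float = 2500.0,
    flip_deg: float = 8.0,
    te_ms: float = 3.0,
) -> np.ndarray:
    """Synthetic T1-weighted (MPRAGE-like) image from quantitative maps.

    Uses the steady-state signal of an inversion-prepared spoiled gradient
    echo,

        S = PD * sin(a) * (1 - 2 e^{-TI/T1} + e^{-TR/T1})
            / (1 - cos(a) e^{-TR/T1}) * e^{-TE/T2},

    evaluated voxelwise.  With the default timing the signal decreases
    monotonically with T1, so white matter appears bright and CSF dark.
    """
    t1_map = np.asarray(t1_map, dtype=float)
    t2_map = np.asarray(t2_map, dtype=float)
    pd_map = np.asarray(pd_map, dtype=float)
    if not (t1_map.shape == t2_map.shape == pd_map.shape):
        raise ValueError("t1, t2 and pd maps must share one shape")
    out = np.zeros_like(t1_map)
    ok = (t1_map > 0) & (t2_map > 0)
    a = np.deg2rad(flip_deg)
    e1i = np.exp(-ti_ms / t1_map[ok])
    e1r = np.exp(-tr_ms / t1_map[ok])
    e2 = np.exp(-te_ms / t2_map[ok])
    out[ok] = pd_map[ok] * np.sin(a) * (1 - 2 * e1i + e1r) / (1 - np.cos(a) * e1r) * e2
    return out
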