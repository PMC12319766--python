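"""Cross-correlation template matching in the compressed subspace.

The dictionary is projected onto the temporal basis (K numbers per atom,
re-normalised), and each voxel's coefficient vector is matched to the
atom with the largest magnitude normalised inner product.  The winning
atom's (T1, T2) are the voxel's quantitative values; the matched
amplitude serves as a proton-density estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .recon import CoefficientMaps
from .signal_model import Dictionary, SubspaceBasis

__all__ = [
    "CompressedDictionary",
    "QuantitativeMapSet",
    "compress_dictionary",
    "template_match",
    "r1_map",
]

log = logging.getLogger(__name__)


@dataclass
class CompressedDictionary:
    """Subspace-compressed atoms (n_atoms x K, unit row norm)."""

    atoms_k: np.ndarray
    params: np.ndarray  # (n_atoms, 2): T1, T2 in ms
    projection_residual: np.ndarray  # per-atom energy fraction lost by compression

    @property
    def n_atoms(self) -> int:
        return self.atoms_k.shape[0]

    @property
    def k(self) -> int:
        return self.atoms_k.shape[1]

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            atoms_k=self.atoms_k,
            params=self.params,
            projection_residual=self.projection_residual,
        )

    @classmethod
    def load(cls, path) -> "CompressedDictionary":
        with np.load(path, allow_pickle=False) as f:
            return cls(
                atoms_k=f["atoms_k"],
                params=f["params"],
                projection_residual=f["projection_residual"],
            )


@dataclass
class QuantitativeMapSet:
    """Matched quantitative maps; T1/T2 values lie on the dictionary grid."""

    t1_map: np.ndarray
    t2_map: np.ndarray
    pd_map: np.ndarray
    match_corr_map: np.ndarray


def compress_dictionary(dictionary: Dictionary, basis: SubspaceBasis) -> CompressedDictionary:
    """Project atoms onto the basis and re-normalise the K-vectors."""
    if basis.phi.shape[0] != dictionary.n_timepoints:
        raise ValueError(
            "basis and dictionary disagree on the number of timepoints "
            f"({basis.phi.shape[0]} != {dictionary.n_timepoints})"
        )
    proj = dictionary.atoms @ basis.phi.conj()  # (n_atoms, K)
    norms = np.linalg.norm(proj, axis=1)
    # atoms have unit norm, so residual energy fraction = 1 - |proj|^2
    residual = np.clip(1.0 - norms**2, 0.0, 1.0)
    if np.any(norms == 0):
        raise ValueError("an atom is orthogonal to the subspace; increase K")
    return CompressedDictionary(
        atoms_k=proj / norms[:, None],
        params=dictionary.params.copy(),
        projection_residual=residual,
    )


def template_match(
    coeff_maps: CoefficientMaps | np.ndarray,
    compressed: CompressedDictionary,
    mask: np.ndarray | None = None,
    chunk: int = 8192,
) -> QuantitativeMapSet:
    """Voxelwise argmax of |<c_voxel, atom_k>| / ||c_voxel||.

    Matching is invariant to a global complex scaling of the coefficients
    and to atom ordering; ties break toward the lowest T1 (deterministic).
    Voxels with zero coefficients (or outside ``mask``) get the flag
    value T1 = 0 with match correlation 0.
    """
    c = coeff_maps.c if isinstance(coeff_maps, CoefficientMaps) else np.asarray(coeff_maps)
    if c.shape[0] != compressed.k:
        raise ValueError("coefficient K does not match compressed dictionary K")
    shape = c.shape[1:]
    cv = c.reshape(compressed.k, -1).T  # (n_vox, K)
    norms = np.linalg.norm(cv, axis=1)
    valid = norms > 0
    if mask is not None:
        valid &= np.asarray(mask, bool).ravel()

    # stable tie-break toward the lowest T1: order atoms by (T1, T2) and
    # rely on argmax returning the first maximal entry
    order = np.lexsort((compressed.params[:, 1], compressed.params[:, 0]))
    atoms = compressed.atoms_k[order]
    params = compressed.params[order]

    n_vox = cv.shape[0]
    t1 = np.zeros(n_vox)
    t2 = np.zeros(n_vox)
    pd = np.zeros(n_vox)
    corr = np.zeros(n_vox)
    idx_valid = np.nonzero(valid)[0]
    for start in range(0, idx_valid.size, chunk):
        sel = idx_valid[start : start + chunk]
        inner = np.abs(atoms.conj() @ cv[sel].T)  # (n_atoms, n_sel)
        best = np.argmax(inner, axis=0)
        amp = inner[best, np.arange(sel.size)]
        t1[sel] = params[best, 0]
        t2[sel] = params[best, 1]
        pd[sel] = amp
        corr[sel] = np.clip(amp / norms[sel], 0.0, 1.0)
    return QuantitativeMapSet(
        t1_map=t1.reshape(shape),
        t2_map=t2.reshape(shape),
        pd_map=pd.reshape(shape),
        match_corr_map=corr.reshape(shape),
    )


def r1_map(t1_map_ms: np.ndarray) -> np.ndarray:
    """R1 = 1000 / T1[ms] in 1/s; non-positive T1 propagates as NaN."""
    t1 = np.asarray(t1_map_ms, dtype=float)
    out = np.full(t1.shape, np.nan)
    ok = t1 > 0
    out[ok] = 1000.0 / t1[ok]
    n_bad = int(t1.size - ok.sum())
    if n_bad:
        log.info("r1_map: %d voxels with non-positive T1 set to NaN", n_bad)
    return out
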