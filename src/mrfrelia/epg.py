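"""Extended phase graph (EPG) simulation of the fingerprinting sequence.

The EPG formalism tracks magnetization as configuration states
``(F+_k, F-_k, Z_k)`` indexed by the integer dephasing order ``k``.  An RF
pulse mixes the three states at each order, a fully-spoiled TR shifts the
transverse ladders by one order, and relaxation scales the states while
``Z_0`` recovers toward equilibrium.  The recorded signal is the ``F+_0``
state at the echo time of each excitation.

All routines are vectorised over an arbitrary batch of (T1, T2) pairs so
an entire dictionary is simulated in one pass.
"""

from __future__ import annotations

import numpy as np

from .protocol import AcquisitionProtocol

__all__ = ["epg_simulate", "epg_simulate_batch"]


def _rf_matrix(alpha_rad: float, phase_rad: float = 0.0) -> np.ndarray:
    """3x3 mixing matrix of an RF pulse acting on (F+_k, F-_k, Z_k)."""
    a, p = alpha_rad, phase_rad
    co2, si2 = np.cos(a / 2) ** 2, np.sin(a / 2) ** 2
    sa, ca = np.sin(a), np.cos(a)
    ep = np.exp(1j * p)
    return np.array(
        [
            [co2, ep * ep * si2, -1j * ep * sa],
            [np.conj(ep * ep) * si2, co2, 1j * np.conj(ep) * sa],
            [-0.5j * np.conj(ep) * sa, 0.5j * ep * sa, ca],
        ],
        dtype=complex,
    )


class _EPGBatch:
    """Configuration-state ladders for a batch of tissues."""

    def __init__(self, t1_ms: np.ndarray, t2_ms: np.ndarray, n_states: int):
        self.t1 = np.asarray(t1_ms, dtype=float)
        self.t2 = np.asarray(t2_ms, dtype=float)
        n = self.t1.shape[0]
        self.fp = np.zeros((n, n_states), dtype=complex)
        self.fm = np.zeros((n, n_states), dtype=complex)
        self.z = np.zeros((n, n_states), dtype=complex)
        self.z[:, 0] = 1.0

    def invert(self, efficiency: float) -> None:
        # adiabatic inversion with crushers: transverse states destroyed
        self.fp[:] = 0.0
        self.fm[:] = 0.0
        self.z *= -efficiency

    def relax(self, tau_ms: float) -> None:
        e1 = np.exp(-tau_ms / self.t1)[:, None]
        e2 = np.exp(-tau_ms / self.t2)[:, None]
        self.fp *= e2
        self.fm *= e2
        self.z *= e1
        self.z[:, 0] += 1.0 - e1[:, 0]

    def rf(self, alpha_rad: float) -> None:
        m = _rf_matrix(alpha_rad)
        fp = m[0, 0] * self.fp + m[0, 1] * self.fm + m[0, 2] * self.z
        fm = m[1, 0] * self.fp + m[1, 1] * self.fm + m[1, 2] * self.z
        z = m[2, 0] * self.fp + m[2, 1] * self.fm + m[2, 2] * self.z
        self.fp, self.fm, self.z = fp, fm, z

    def shift(self) -> None:
        # unit gradient dephasing per TR: F+ ladder up, F- ladder down
        self.fp[:, 1:] = self.fp[:, :-1]
        self.fp[:, 0] = np.conj(self.fm[:, 1])
        self.fm[:, :-1] = self.fm[:, 1:]
        self.fm[:, -1] = 0.0


def epg_simulate_batch(
    t1_ms: np.ndarray,
    t2_ms: np.ndarray,
    protocol: AcquisitionProtocol,
    n_states: int = 30,
    return_mz: bool = False,
):
    """Simulate fingerprints for a batch of (T1, T2) pairs.

    Returns a complex array of shape ``(n_pairs, n_timepoints)`` holding the
    transverse signal at the echo time of every TR.  With ``return_mz`` the
    longitudinal ``Z_0`` state sampled at the same instants is returned too.
    """
    t1 = np.atleast_1d(np.asarray(t1_ms, dtype=float))
    t2 = np.atleast_1d(np.asarray(t2_ms, dtype=float))
    if t1.shape != t2.shape:
        raise ValueError("t1_ms and t2_ms must have the same shape")
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("relaxation times must be positive")
    if np.any(t2 > t1):
        raise ValueError("physically valid tissues require T2 <= T1")

    state = _EPGBatch(t1, t2, n_states)
    flips = np.deg2rad(protocol.flip_schedule_deg)
    te, tr = protocol.te_ms, protocol.tr_ms
    signal = np.empty((t1.shape[0], protocol.n_timepoints), dtype=complex)
    mz = np.empty_like(signal) if return_mz else None

    idx = 0
    for _ in range(protocol.n_groups):
        state.invert(protocol.inversion_efficiency)
        state.relax(protocol.inversion_time_ms)
        for alpha in flips:
            state.rf(alpha)
            state.relax(te)
            signal[:, idx] = state.fp[:, 0]
            if mz is not None:
                mz[:, idx] = state.z[:, 0]
            state.relax(tr - te)
            state.shift()
            idx += 1
        state.relax(protocol.rest_s * 1000.0)

    if return_mz:
        return signal, mz
    return signal


def epg_simulate(
    t1_ms: float,
    t2_ms: float,
    protocol: AcquisitionProtocol,
    n_states: int = 30,
    return_mz: bool = False,
):
    """Simulate a single fingerprint; see :func:`epg_simulate_batch`."""
    out = epg_simulate_batch([t1_ms], [t2_ms], protocol, n_states=n_states, return_mz=return_mz)
    if return_mz:
        return out[0][0], out[1][0]
    return out[0]
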