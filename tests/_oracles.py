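"""Independent oracles used by the test suite.

These deliberately avoid the package's EPG implementation: the isochromat
simulator integrates the Bloch equations for an ensemble of spins with
ideal gradient spoiling (uniform intra-voxel dephasing accrued once per
TR, gradient moment nulled at the echo), and serves as the ground truth
the configuration-state simulation must reproduce.
"""

from __future__ import annotations

import numpy as np


def bloch_isochromat(t1_ms, t2_ms, protocol, n_isochromats=200):
    """Brute-force multi-isochromat Bloch simulation of the sequence.

    Returns the ensemble-average complex transverse magnetization at the
    echo time of every TR.
    """
    psi = 2 * np.pi * (np.arange(n_isochromats) + 0.5) / n_isochromats
    m = np.zeros((n_isochromats, 3))
    m[:, 2] = 1.0
    flips = np.deg2rad(protocol.flip_schedule_deg)
    te, tr = protocol.te_ms, protocol.tr_ms
    out = []

    def relax(tau, dephase=None):
        e1, e2 = np.exp(-tau / t1_ms), np.exp(-tau / t2_ms)
        mxy = (m[:, 0] + 1j * m[:, 1]) * e2
        if dephase is not None:
            mxy = mxy * np.exp(1j * dephase)
        m[:, 0], m[:, 1] = mxy.real, mxy.imag
        m[:, 2] = m[:, 2] * e1 + (1 - e1)

    for _ in range(protocol.n_groups):
        # adiabatic inversion with crushers
        m[:, 0] = 0.0
        m[:, 1] = 0.0
        m[:, 2] = -protocol.inversion_efficiency * m[:, 2]
        relax(protocol.inversion_time_ms)
        for a in flips:
            c, s = np.cos(a), np.sin(a)
            my = c * m[:, 1] - s * m[:, 2]
            mz = s * m[:, 1] + c * m[:, 2]
            m[:, 1], m[:, 2] = my, mz
            relax(te)
            out.append(np.mean(m[:, 0] + 1j * m[:, 1]))
            relax(tr - te, dephase=psi)
        relax(protocol.rest_s * 1000.0)
    return np.asarray(out)
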