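"""Shared fixtures: small protocol/dictionary/phantom objects reused
across test modules (session-scoped where construction is expensive)."""

from __future__ import annotations

import numpy as np
import pytest

import mrfrelia as m


@pytest.fixture(scope="session")
def toy_protocol():
    """Tiny 4-group protocol: fast, same structure as the full sequence."""
    return m.AcquisitionProtocol.desk_scale(n_groups=4, trs_per_group=20)


@pytest.fixture(scope="session")
def desk_grid():
    return m.DictionaryGrid.desk_scale()


@pytest.fixture(scope="session")
def toy_dictionary(desk_grid, toy_protocol):
    return m.build_dictionary(desk_grid, toy_protocol)


@pytest.fixture(scope="session")
def toy_basis(toy_dictionary):
    return m.compute_subspace(toy_dictionary, k=5)


@pytest.fixture(scope="session")
def toy_compressed(toy_dictionary, toy_basis):
    return m.compress_dictionary(toy_dictionary, toy_basis)


@pytest.fixture(scope="session")
def toy_phantom():
    return m.make_phantom((32, 32, 2), (3.0, 3.0, 3.0), seed=7)


@pytest.fixture(scope="session")
def toy_coils(toy_phantom):
    return m.make_coil_sensitivities(toy_phantom.shape, n_coils=3, seed=11)


@pytest.fixture(scope="session")
def toy_scheme(toy_phantom, toy_protocol):
    return m.make_sampling_scheme(
        toy_phantom.shape, toy_protocol.n_groups, toy_protocol.trs_per_group,
        undersampling=2.0, seed=13,
    )


@pytest.fixture(scope="session")
def toy_truth(toy_phantom, toy_protocol, toy_basis):
    """Exact voxel signals and their subspace projection (true c maps)."""
    from mrfrelia.encoding import phantom_signals

    sig = phantom_signals(toy_phantom, toy_protocol)
    c = np.zeros((toy_basis.k,) + toy_phantom.shape, dtype=complex)
    c[:, toy_phantom.foreground] = (sig @ toy_basis.phi.conj()).T
    return {"signals": sig, "c_true": c}
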