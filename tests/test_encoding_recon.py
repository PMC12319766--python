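"""Encoding operator contracts, subspace reconstruction, B0 correction,
and k-space motion-compensated combination."""

import numpy as np
import pytest

import mrfrelia as m
from mrfrelia.encoding import SubspaceEncodingOperator, phantom_signals
from mrfrelia.recon import ReconDivergence
from mrfrelia.transforms import RigidTransform


def _rand_cy(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


class TestOperatorContracts:
    @pytest.mark.parametrize("variant", ["plain", "b0_seg", "b0_exact", "offgrid"])
    def test_adjointness(self, variant, toy_basis, toy_coils, toy_scheme, toy_phantom):
        """<A x, y> == <x, A^H y> to 1e-6 relative for every encoding variant."""
        scheme = toy_scheme
        b0, nseg = None, 0
        if variant == "b0_seg":
            b0, nseg = toy_phantom.b0_map, 4
        elif variant == "b0_exact":
            b0, nseg = toy_phantom.b0_map, "exact"
        elif variant == "offgrid":
            # rotate one group's coordinates off the Cartesian grid
            coords = scheme.coords.copy()
            th = np.deg2rad(3.0)
            rot = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
            coords[1] = np.clip(coords[1] @ rot.T, -15.9, 15.9)
            scheme = m.SamplingScheme(
                shape=scheme.shape, coords=coords, tr_index=scheme.tr_index,
                time_ms=scheme.time_ms, trs_per_group=scheme.trs_per_group,
                readout_times_ms=scheme.readout_times_ms,
            )
        op = SubspaceEncodingOperator(toy_basis, toy_coils, scheme, b0, nseg)
        rng = np.random.default_rng(42)
        x = _rand_cy(rng, (toy_basis.k,) + toy_phantom.shape)
        y = _rand_cy(rng, (3, scheme.n_groups, scheme.n_samples_per_group))
        lhs = np.vdot(y, op.forward(x))
        rhs = np.vdot(op.adjoint(y), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_point_source_constant_kspace_magnitude(self, toy_basis):
        """Fourier transform of a centred delta has flat magnitude."""
        shape = (32, 32, 2)
        coils = np.ones((1,) + shape, dtype=complex)
        scheme = m.make_sampling_scheme(shape, 4, 20, undersampling=2, seed=1)
        op = SubspaceEncodingOperator(toy_basis, coils, scheme)
        c = np.zeros((toy_basis.k,) + shape, dtype=complex)
        c[:, 16, 16, 1] = 1.0  # delta at the FFT origin convention? use any voxel
        y = op.forward(c)
        trs = scheme.trs_per_group
        for g in range(scheme.n_groups):
            phi_g = toy_basis.phi[g * trs : (g + 1) * trs]
            expect = np.abs(phi_g.sum(axis=1))[scheme.tr_index[g]]
            assert np.allclose(np.abs(y[0, g]) * np.sqrt(np.prod(shape)), expect, atol=1e-9)

    def test_zero_b0_equals_plain_path_bitwise(self, toy_basis, toy_coils, toy_scheme, toy_phantom):
        rng = np.random.default_rng(3)
        x = _rand_cy(rng, (toy_basis.k,) + toy_phantom.shape)
        plain = SubspaceEncodingOperator(toy_basis, toy_coils, toy_scheme)
        zb0 = SubspaceEncodingOperator(
            toy_basis, toy_coils, toy_scheme, np.zeros(toy_phantom.shape), 4
        )
        assert np.array_equal(plain.forward(x), zb0.forward(x))

    def test_segmented_equals_exact_at_full_segment_count(
        self, toy_basis, toy_coils, toy_scheme, toy_phantom
    ):
        """L = number of distinct sample times reproduces the exact
        per-sample off-resonance phase operator."""
        rng = np.random.default_rng(4)
        x = _rand_cy(rng, (toy_basis.k,) + toy_phantom.shape)
        exact = SubspaceEncodingOperator(
            toy_basis, toy_coils, toy_scheme, toy_phantom.b0_map, "exact"
        )
        full_l = SubspaceEncodingOperator(
            toy_basis, toy_coils, toy_scheme, toy_phantom.b0_map,
            len(toy_scheme.readout_times_ms),
        )
        ya, yb = exact.forward(x), full_l.forward(x)
        assert np.max(np.abs(ya - yb)) <= 1e-10 * np.max(np.abs(ya))

    def test_nyquist_violation_rejected(self, toy_scheme):
        coords = toy_scheme.coords.copy()
        coords[0, 0] = [40, 0, 0]
        with pytest.raises(ValueError):
            m.SamplingScheme(
                shape=toy_scheme.shape, coords=coords, tr_index=toy_scheme.tr_index,
                time_ms=toy_scheme.time_ms, trs_per_group=toy_scheme.trs_per_group,
                readout_times_ms=toy_scheme.readout_times_ms,
            )


class TestReconstruction:
    def test_full_kt_noiseless_recovers_projection(
        self, toy_phantom, toy_protocol, toy_basis, toy_coils, toy_truth
    ):
        """Fully sampled (k-t), noiseless, lambda=0: the fit equals the
        projection of the true signals onto the basis."""
        scheme = m.make_sampling_scheme(
            toy_phantom.shape, toy_protocol.n_groups, toy_protocol.trs_per_group,
            full_kt=True,
        )
        y = m.forward_model(toy_phantom, None, toy_coils, scheme, protocol=toy_protocol)
        cm = m.reconstruct_subspace(
            y, toy_basis, toy_coils, config=m.ReconConfig(lam_rel=0, n_iters=5)
        )
        rel = np.linalg.norm(cm.c - toy_truth["c_true"]) / np.linalg.norm(toy_truth["c_true"])
        assert rel < 1e-3

    def test_huge_lambda_shrinks_to_zero(self, toy_basis, toy_coils, toy_scheme, toy_truth):
        y = m.forward_model(toy_truth["c_true"], toy_basis, toy_coils, toy_scheme)
        cm = m.reconstruct_subspace(
            y, toy_basis, toy_coils,
            config=m.ReconConfig(lam_rel=50.0, n_iters=10),
        )
        assert np.max(np.abs(cm.c)) < 1e-10 * np.max(np.abs(toy_truth["c_true"]))

    def test_llr_beats_unregularized_under_noise(
        self, toy_phantom, toy_protocol, toy_basis, toy_coils, toy_scheme, toy_truth
    ):
        """2x undersampling + noise: a tuned lambda > 0 lowers coefficient
        error versus lambda = 0."""
        y = m.forward_model(
            toy_phantom, None, toy_coils, toy_scheme, protocol=toy_protocol,
            noise_rel=0.05, seed=21,
        )
        c_true = toy_truth["c_true"]

        def err(lam):
            cm = m.reconstruct_subspace(
                y, toy_basis, toy_coils,
                config=m.ReconConfig(lam_rel=lam, n_iters=25, seed=5),
            )
            return np.linalg.norm(cm.c - c_true) / np.linalg.norm(c_true)

        e0 = err(0.0)
        e_reg = min(err(lam) for lam in (0.01, 0.03))
        assert e_reg < e0

    def test_objective_nonincreasing(self, toy_basis, toy_coils, toy_scheme, toy_truth):
        y = m.forward_model(toy_truth["c_true"], toy_basis, toy_coils, toy_scheme,
                            noise_rel=0.03, seed=2)
        cm = m.reconstruct_subspace(
            y, toy_basis, toy_coils, config=m.ReconConfig(lam_rel=0.02, n_iters=15)
        )
        assert np.all(np.diff(cm.objectives) <= 1e-9 * cm.objectives[0])

    def test_divergent_step_raises(self, toy_basis, toy_coils, toy_scheme, toy_truth):
        y = m.forward_model(toy_truth["c_true"], toy_basis, toy_coils, toy_scheme)
        with pytest.raises(ReconDivergence):
            m.reconstruct_subspace(
                y, toy_basis, toy_coils,
                config=m.ReconConfig(lam_rel=0.02, n_iters=40, step=500.0),
            )

    def test_b0_zero_matches_plain_recon_bitwise(
        self, toy_basis, toy_coils, toy_scheme, toy_truth
    ):
        y = m.forward_model(toy_truth["c_true"], toy_basis, toy_coils, toy_scheme,
                            noise_rel=0.02, seed=3)
        a = m.reconstruct_subspace(
            y, toy_basis, toy_coils, config=m.ReconConfig(lam_rel=0.02, n_iters=8, seed=1)
        )
        b = m.reconstruct_subspace_b0(
            y, toy_basis, toy_coils, b0_map_hz=np.zeros(toy_coils.shape[1:]),
            config=m.ReconConfig(lam_rel=0.02, n_iters=8, b0_segments=4, seed=1),
        )
        assert np.array_equal(a.c, b.c)

    def test_denser_sampling_does_not_increase_error(
        self, toy_phantom, toy_protocol, toy_basis, toy_coils, toy_truth
    ):
        """More k-space samples per group (paired noise seed, same noise
        level) gives non-increasing coefficient reconstruction error."""
        errs = []
        for r in (2.5, 1.25):
            scheme = m.make_sampling_scheme(
                toy_phantom.shape, toy_protocol.n_groups, toy_protocol.trs_per_group,
                undersampling=r, seed=13,
            )
            y = m.forward_model(
                toy_phantom, None, toy_coils, scheme, protocol=toy_protocol,
                noise_rel=0.02, seed=5,
            )
            cm = m.reconstruct_subspace(
                y, toy_basis, toy_coils, config=m.ReconConfig(lam_rel=0, n_iters=30)
            )
            errs.append(
                np.linalg.norm(cm.c - toy_truth["c_true"])
                / np.linalg.norm(toy_truth["c_true"])
            )
        assert errs[1] <= errs[0] + 1e-6


class TestB0Correction:
    def test_correction_reduces_pocket_t1_error(self):
        """With the sinus-analog pocket, matched T1 RMSE inside the pocket is
        lower with time-segmented correction than without; outside the
        pocket the two reconstructions differ by <1%."""
        shape = (48, 48, 1)
        prot = m.AcquisitionProtocol.desk_scale(n_groups=6, trs_per_group=24)
        d = m.build_dictionary(m.DictionaryGrid.desk_scale(), prot)
        basis = m.compute_subspace(d, 5)
        compressed = m.compress_dictionary(d, basis)
        ph = m.make_phantom(shape, (3.0, 3.0, 3.0), seed=31, b0_pocket_amplitude_hz=80.0)
        coils = m.make_coil_sensitivities(shape, 3, seed=5)
        # full k-t sampling isolates the off-resonance effect from
        # undersampling aliasing
        scheme = m.make_sampling_scheme(shape, 6, 24, full_kt=True)
        y = m.forward_model(ph, None, coils, scheme, b0_map_hz=ph.b0_map, protocol=prot)

        cm_plain = m.reconstruct_subspace(
            y, basis, coils, config=m.ReconConfig(lam_rel=0, n_iters=25)
        )
        cm_corr = m.reconstruct_subspace_b0(
            y, basis, coils, b0_map_hz=ph.b0_map,
            config=m.ReconConfig(lam_rel=0, n_iters=25, b0_segments=8),
        )
        fg = ph.foreground
        t1_plain = m.template_match(cm_plain, compressed, mask=fg).t1_map
        t1_corr = m.template_match(cm_corr, compressed, mask=fg).t1_map

        from scipy import ndimage

        pocket = ndimage.binary_dilation(ph.b0_pocket_mask, iterations=2) & fg
        outside = fg & ~ndimage.binary_dilation(ph.b0_pocket_mask, iterations=4)

        def rmse(t1, mask):
            return float(np.sqrt(np.mean((t1[mask] - ph.t1_map[mask]) ** 2)))

        assert rmse(t1_corr, pocket) < rmse(t1_plain, pocket)
        diff = np.abs(t1_corr[outside] - t1_plain[outside])
        assert np.mean(diff) / np.mean(ph.t1_map[outside]) < 0.01


class TestCombination:
    def _pair_data(self, toy_phantom, toy_protocol, toy_coils, noise=0.0):
        sa, sb = m.make_scheme_pair(
            toy_phantom.shape, toy_protocol.n_groups, toy_protocol.trs_per_group,
            undersampling=2.0, seed=23,
        )
        sig = phantom_signals(toy_phantom, toy_protocol)
        ya = m.encode_phantom(toy_phantom, toy_protocol, toy_coils, sa,
                              use_b0=False, noise_rel=noise, seed=1, signals=sig)
        yb = m.encode_phantom(toy_phantom, toy_protocol, toy_coils, sb,
                              use_b0=False, noise_rel=noise, seed=2, signals=sig)
        return ya, yb

    def test_identity_transform_is_concatenation(self, toy_phantom, toy_protocol, toy_coils):
        ya, yb = self._pair_data(toy_phantom, toy_protocol, toy_coils)
        comb = m.combine_acquisitions(ya, yb, RigidTransform.identity())
        ns = ya.scheme.n_samples_per_group
        assert np.array_equal(comb.samples[:, :, :ns], ya.samples)
        assert np.array_equal(comb.samples[:, :, ns:], yb.samples)
        assert np.array_equal(comb.scheme.coords[:, ns:], yb.scheme.coords)

    def test_nonrigid_transform_rejected(self, toy_phantom, toy_protocol, toy_coils):
        ya, yb = self._pair_data(toy_phantom, toy_protocol, toy_coils)
        with pytest.raises(TypeError):
            m.combine_acquisitions(ya, yb, np.eye(4))

    def test_translation_compensation_matches_fourier_shift(
        self, toy_basis, toy_phantom, toy_protocol, toy_truth
    ):
        """Scan 2 of a translated object, phase-compensated in k-space,
        equals the unmoved scan (Fourier shift theorem).  A uniform coil is
        used: the head moves inside static coils, so coil weighting is the
        one (small, smooth) effect k-space compensation cannot undo."""
        sa, sb = m.make_scheme_pair(
            toy_phantom.shape, toy_protocol.n_groups, toy_protocol.trs_per_group,
            undersampling=2.0, seed=23,
        )
        coils = np.ones((1,) + toy_phantom.shape, dtype=complex)
        c_true = toy_truth["c_true"]
        shift_vox = np.array([3.0, -2.0, 0.0])
        # exact (circular) Fourier shift: c_moved(r) = c_true(r + s)
        kx = np.fft.fftfreq(32)[:, None, None]
        ky = np.fft.fftfreq(32)[None, :, None]
        ramp = np.exp(2j * np.pi * (kx * shift_vox[0] + ky * shift_vox[1]))
        c_moved = np.fft.ifftn(np.fft.fftn(c_true, axes=(1, 2)) * ramp[None], axes=(1, 2))

        y_unmoved = m.forward_model(c_true, toy_basis, coils, sb)
        y_moved = m.forward_model(c_moved, toy_basis, coils, sb)
        # pull-back map scan-1 coords -> scan-2 coords: moved(r) = true(r + s)
        t = RigidTransform(0.0, translation_mm=3.0 * shift_vox)  # voxel size 3 mm
        comb = m.combine_acquisitions(
            m.forward_model(c_true, toy_basis, coils, sa), y_moved, t,
            voxel_size_mm=(3.0, 3.0, 3.0),
        )
        ns = sa.n_samples_per_group
        compensated = comb.samples[:, :, ns:]
        rel = np.linalg.norm(compensated - y_unmoved.samples) / np.linalg.norm(
            y_unmoved.samples
        )
        assert rel < 1e-3

    def test_combined_t1_error_not_worse_than_single(
        self, toy_phantom, toy_protocol, toy_coils, toy_dictionary, toy_basis, toy_compressed
    ):
        """Paired-seed run: the combined double-duration reconstruction has
        voxelwise T1 RMSE <= the single-scan RMSE."""
        ya, yb = self._pair_data(toy_phantom, toy_protocol, toy_coils, noise=0.03)
        comb = m.combine_acquisitions(ya, yb, None)
        cfg = m.ReconConfig(lam_rel=0.02, n_iters=20, seed=3)
        fg = toy_phantom.foreground
        wm = toy_phantom.wm_mask()

        def t1_rmse(y):
            cm = m.reconstruct_subspace(y, toy_basis, toy_coils, config=cfg)
            t1 = m.template_match(cm, toy_compressed, mask=fg).t1_map
            return float(np.sqrt(np.mean((t1[wm] - toy_phantom.t1_map[wm]) ** 2)))

        assert t1_rmse(comb) <= t1_rmse(ya)
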