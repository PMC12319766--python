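"""Streamline bundles, cleaning, along-tract profiles, and tract statistics."""

import numpy as np
import pytest

import mrfrelia as m
from mrfrelia.tracts import default_tract_cores


def straight_core(n=40, length=90.0):
    u = np.linspace(0, 1, n)
    return np.stack([np.full(n, 60.0), 20 + length * u, np.full(n, 3.0)], axis=1)


class TestGenerate:
    def test_zero_spread_zero_outliers_reproduces_core(self):
        core = straight_core()
        b = m.generate_bundle(core, n_streamlines=12, spread_mm=0.0, outlier_frac=0.0, seed=1)
        for s in b.streamlines:
            assert np.allclose(s, core)

    def test_seed_determinism(self):
        core = straight_core()
        a = m.generate_bundle(core, 20, 2.0, 0.1, seed=5)
        b = m.generate_bundle(core, 20, 2.0, 0.1, seed=5)
        for x, y in zip(a.streamlines, b.streamlines):
            assert np.array_equal(x, y)

    def test_outliers_exceed_cleaning_threshold(self):
        core = straight_core()
        b = m.generate_bundle(core, 40, spread_mm=2.0, outlier_frac=0.1, seed=3)
        from mrfrelia.tracts import _resample

        rs = np.stack([_resample(s, 100) for s in b.streamlines])
        inlier = rs[4:]  # first 10% are the planted outliers
        core_mean = inlier.mean(axis=0)
        d = np.linalg.norm(rs - core_mean[None], axis=2).mean(axis=1)
        d_in = d[4:]
        assert np.all(d[:4] > d_in.mean() + 3 * d_in.std())

    def test_short_core_rejected(self):
        with pytest.raises(ValueError):
            m.generate_bundle(straight_core(n=10), 10, 1.0, 0.0, seed=0)


class TestClean:
    def test_clean_bundle_without_outliers_keeps_most(self):
        """False-positive rate of the 3 sd rule stays below 5%."""
        kept = []
        for seed in range(5):
            b = m.generate_bundle(straight_core(), 60, 2.0, 0.0, seed=seed)
            c = m.clean_bundle(b)
            kept.append(c.n_streamlines / b.n_streamlines)
        assert np.mean(kept) >= 0.95

    def test_removes_all_planted_gross_outliers(self):
        core = straight_core()
        for seed in range(3):
            b = m.generate_bundle(core, 50, 2.0, outlier_frac=0.1, seed=seed)
            outlier_ids = {id(s) for s in b.streamlines[:5]}
            c = m.clean_bundle(b)
            assert all(id(s) not in outlier_ids for s in c.streamlines)

    def test_zero_iterations_is_identity(self):
        b = m.generate_bundle(straight_core(), 30, 2.0, 0.2, seed=2)
        c = m.clean_bundle(b, iterations=0)
        assert c.n_streamlines == b.n_streamlines

    def test_cleaning_is_idempotent(self):
        b = m.generate_bundle(straight_core(), 50, 2.0, 0.1, seed=4)
        once = m.clean_bundle(b)
        twice = m.clean_bundle(once)
        assert twice.n_streamlines == once.n_streamlines

    def test_too_few_streamlines_rejected(self):
        b = m.generate_bundle(straight_core(), 5, 1.0, 0.0, seed=0)
        with pytest.raises(ValueError):
            m.clean_bundle(b)


class TestProfile:
    def test_constant_map_gives_flat_profile(self):
        b = m.generate_bundle(straight_core(), 30, 1.5, 0.0, seed=6)
        scalar = np.full((40, 40, 3), 850.0)
        prof = m.tract_profile(b, scalar, voxel_size_mm=(3.0, 3.0, 3.0))
        assert prof.node_values.shape == (100,)
        assert np.allclose(prof.node_values, 850.0)

    def test_linear_gradient_gives_linear_profile(self):
        """A scalar ramp along the core maps onto a linear 100-node profile."""
        b = m.generate_bundle(straight_core(length=90.0), 30, 1.0, 0.0, seed=7)
        y_mm = np.arange(40) * 3.0
        scalar = np.broadcast_to(y_mm[None, :, None], (40, 40, 3)).copy()
        prof = m.tract_profile(b, scalar, voxel_size_mm=(3.0, 3.0, 3.0))
        nodes = np.arange(100)
        fit = np.polyfit(nodes, prof.node_values, 1)
        resid = prof.node_values - np.polyval(fit, nodes)
        value_range = prof.node_values.max() - prof.node_values.min()
        assert np.max(np.abs(resid)) < 0.01 * value_range

    def test_weights_sum_to_one(self):
        b = m.generate_bundle(straight_core(), 25, 2.0, 0.0, seed=8)
        prof = m.tract_profile(b, np.full((40, 40, 3), 1.0), voxel_size_mm=(3.0, 3.0, 3.0))
        assert np.allclose(prof.node_weights.sum(axis=0), 1.0, atol=1e-12)

    def test_orientation_enforced_under_reversal(self):
        """Reversing streamline point order leaves the profile unchanged."""
        b = m.generate_bundle(straight_core(), 20, 1.5, 0.0, seed=9)
        rev = m.StreamlineBundle(
            streamlines=[s[::-1].copy() for s in b.streamlines],
            name=b.name, orientation=b.orientation,
        )
        y_mm = np.arange(40) * 3.0
        scalar = np.broadcast_to(y_mm[None, :, None], (40, 40, 3)).copy()
        pa = m.tract_profile(b, scalar, voxel_size_mm=(3.0, 3.0, 3.0))
        pb = m.tract_profile(rev, scalar, voxel_size_mm=(3.0, 3.0, 3.0))
        assert np.allclose(pa.node_values, pb.node_values)

    def test_analysis_restricted_to_middle_80(self):
        b = m.generate_bundle(straight_core(), 20, 1.0, 0.0, seed=10)
        prof = m.tract_profile(b, np.full((40, 40, 3), 850.0), voxel_size_mm=(3.0, 3.0, 3.0))
        assert prof.analyzed_slice == slice(10, 90)


class TestProfileReliability:
    def _profiles(self, tau, sigma, n=20, seed=0):
        rng = np.random.default_rng(seed)
        truth = 850 + tau * rng.standard_normal(n)
        out = []
        for noise_seed in (1, 2):
            nrng = np.random.default_rng([seed, noise_seed])
            profs = {}
            for i in range(n):
                vals = truth[i] + sigma * nrng.standard_normal(100)
                profs[i] = m.TractProfile(node_values=vals, node_weights=np.ones((1, 100)))
            out.append(profs)
        return out

    def test_identical_sessions_unit_reliability(self):
        p1, _ = self._profiles(30, 5)
        rel = m.profile_reliability(p1, p1)
        assert rel["tract_mean_r"] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(rel["per_node_r"], 1.0)

    def test_shuffled_subjects_near_zero(self):
        p1, p2 = self._profiles(30, 5, n=20, seed=3)
        shuffled = {i: p2[(i + 7) % 20] for i in range(20)}
        rel = m.profile_reliability(p1, shuffled, seed=3)
        lo, hi = rel["tract_mean_r_ci68"]
        assert lo < 0.3 and rel["tract_mean_r"] < 0.5

    def test_recovers_reliability_closed_form(self):
        """tract-mean r ~ tau^2/(tau^2+sigma_mean^2) over 30 replicates."""
        tau, sigma_node = 30.0, 30.0
        sigma_mean2 = sigma_node**2 / 80  # 80 analyzed nodes average down
        expected = tau**2 / (tau**2 + sigma_mean2)
        rs = []
        for rep in range(30):
            p1, p2 = self._profiles(tau, sigma_node, n=25, seed=100 + rep)
            rs.append(m.profile_reliability(p1, p2)["tract_mean_r"])
        assert abs(np.mean(rs) - expected) < 0.05

    def test_too_few_subjects_rejected(self):
        p1, p2 = self._profiles(30, 5, n=2)
        with pytest.raises(ValueError):
            m.profile_reliability(p1, p2)


class TestAgeCorrelation:
    def test_positive_slope_detected_fdr(self):
        """Cohort of 40 subjects with the default R1-age slope: tract-mean
        R1 (both scans pooled, age at scan) correlates positively with age,
        FDR-significant."""
        spec = m.CohortSpec(n_subjects=40, shape=(40, 40, 2), seed=5)
        subs = m.simulate_cohort(spec)
        ages = np.array([sess.age_y for s in subs for sess in s.sessions])
        cores = default_tract_cores(spec.shape, spec.voxel_size_mm)
        means = {}
        for t_name, core in cores.items():
            vals = []
            for s in subs:
                b = m.generate_bundle(core, 20, 1.5, 0.0, seed=s.subject_id)
                for sess in s.sessions:
                    ph = sess.phantom
                    prof = m.tract_profile(
                        b, m.r1_map(np.where(ph.t1_map > 0, ph.t1_map, np.nan)),
                        voxel_size_mm=spec.voxel_size_mm,
                    )
                    vals.append(prof.mean())
            means[t_name] = np.asarray(vals)
        tab = m.age_correlation(means, ages)
        # as in the study: positive correlations throughout, significant in
        # most (not necessarily all) tracts
        assert np.all(tab["r"] > 0)
        assert tab["significant"].mean() >= 0.7

    def test_null_slope_controls_false_positives(self):
        """slope = 0: fraction of FDR-significant tracts <= 5% over 50 reps."""
        rng = np.random.default_rng(17)
        n_sig = 0
        n_tot = 0
        for rep in range(50):
            ages = rng.uniform(8, 13, size=40)
            means = {f"t{i}": 1.2 + 0.02 * rng.standard_normal(40) for i in range(8)}
            tab = m.age_correlation(means, ages)
            n_sig += int(tab["significant"].sum())
            n_tot += len(tab)
        assert n_sig / n_tot <= 0.05

    def test_single_tract_reduces_to_raw_p(self):
        rng = np.random.default_rng(19)
        ages = rng.uniform(8, 13, 20)
        vals = {"only": 1.2 + 0.01 * ages + 0.02 * rng.standard_normal(20)}
        tab = m.age_correlation(vals, ages)
        assert tab.loc[0, "p_fdr"] == pytest.approx(tab.loc[0, "p"], rel=1e-12)

    def test_constant_ages_rejected(self):
        with pytest.raises(ValueError):
            m.age_correlation({"t": np.ones(12)}, np.full(12, 10.0))

    def test_r1_t1_rank_consistency(self):
        """Tract-mean rank correlations flip sign between T1 and R1."""
        from scipy import stats

        rng = np.random.default_rng(21)
        t1_means = 850 + 40 * rng.standard_normal(15)
        ages = np.linspace(8, 13, 15)
        r_t1 = stats.spearmanr(ages, t1_means).statistic
        r_r1 = stats.spearmanr(ages, 1000.0 / t1_means).statistic
        assert r_t1 == pytest.approx(-r_r1, abs=1e-12)
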