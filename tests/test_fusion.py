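"""Commonality index: oracles, degeneracy, permutation inference, metrics."""

import numpy as np
import pytest
import scipy.stats

import fusionrsa as f
from fusionrsa.fusion import CommonalityTrace, partial_spearman, spearman, storey_fdr


def rank_oracle(x):
    """Brute-force average ranks (midrank for ties)."""
    x = np.asarray(x, dtype=float)
    out = np.empty(len(x))
    for i, v in enumerate(x):
        less = np.sum(x < v)
        eq = np.sum(x == v)
        out[i] = less + (eq + 1) / 2.0
    return out


def spearman_oracle(x, y):
    rx, ry = rank_oracle(x), rank_oracle(y)
    return np.corrcoef(rx, ry)[0, 1]


def partial_oracle(x, y, z):
    """Pearson correlation of rank-regression residuals."""
    rx, ry, rz = rank_oracle(x), rank_oracle(y), rank_oracle(z)
    Z = np.column_stack([np.ones_like(rz), rz])
    res_x = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
    res_y = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    return np.corrcoef(res_x, res_y)[0, 1]


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        assert spearman(x, x**2) == pytest.approx(1.0)

    def test_reversal(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        assert spearman(x, x[::-1]) == pytest.approx(-1.0)

    def test_ties_match_brute_force_oracle(self):
        x = np.array([1.0, 1, 2, 3])
        y = np.array([2.0, 3, 1, 4])
        assert spearman(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_matches_scipy_on_random_vectors(self, rng):
        """Independent library cross-check, including tied data."""
        for _ in range(50):
            x = rng.integers(0, 4, size=8).astype(float)
            y = rng.normal(size=8)
            if np.unique(x).size < 2:
                continue
            expected = scipy.stats.spearmanr(x, y).statistic
            assert spearman(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_undefined(self):
        assert np.isnan(spearman(np.ones(6), np.arange(6.0)))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spearman(np.arange(5.0), np.arange(6.0))


class TestPartialSpearman:
    def test_orthogonal_z_collapses_to_spearman(self):
        """If z is rank-orthogonal to x and y the partialling does nothing.

        Exact rank-orthogonality at length 6 needs tied z values, as the
        binary model RDVs have."""
        x = np.array([1.0, 2, 3, 4, 5, 6])
        z = np.array([1.0, 3, 2, 2, 3, 1])
        for y in ([1.0, 2, 3, 6, 4, 5], [1.0, 2, 4, 3, 5, 6]):
            y = np.asarray(y)
            assert abs(spearman(x, z)) < 1e-12 and abs(spearman(y, z)) < 1e-12
            assert partial_spearman(x, y, z) == pytest.approx(spearman(x, y), abs=1e-12)

    def test_self_correlation(self, rng):
        x = rng.normal(size=6)
        z = rng.normal(size=6)
        val = partial_spearman(x, x, z)
        if not np.isnan(val):
            assert val == pytest.approx(1.0)

    def test_matches_residual_oracle(self, rng):
        for _ in range(300):
            x, y, z = rng.normal(size=(3, 6))
            val = partial_spearman(x, y, z)
            if np.isnan(val):
                continue
            assert val == pytest.approx(partial_oracle(x, y, z), abs=1e-10)

    def test_degenerate_returns_nan_not_inf(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        val = partial_spearman(x, y, x)  # rho_xz = 1
        assert np.isnan(val) and not np.isinf(val)


class TestCommonalityIndex:
    def test_oracle_equivalence_1000_triplets(self, rng):
        """commonality == raw - residual-partial oracle, to 1e-12."""
        checked = 0
        while checked < 1000:
            x, y, z = rng.normal(size=(3, 6))
            val = f.commonality_index(x, y, z)
            if np.isnan(val):
                continue
            oracle = spearman_oracle(x, y) - partial_oracle(x, y, z)
            assert val == pytest.approx(oracle, abs=1e-12)
            checked += 1

    def test_symmetry_in_neural_rdvs(self, rng):
        for _ in range(100):
            x, y, z = rng.normal(size=(3, 6))
            a, b = f.commonality_index(x, y, z), f.commonality_index(y, x, z)
            if np.isnan(a):
                assert np.isnan(b)
            else:
                assert a == pytest.approx(b, abs=1e-12)

    def test_rank_invariance(self, rng):
        """A strictly monotone transform of one RDV changes nothing."""
        for _ in range(100):
            x, y, z = rng.normal(size=(3, 6))
            a = f.commonality_index(x, y, z)
            b = f.commonality_index(np.exp(3 * x), y, z)
            if np.isnan(a):
                assert np.isnan(b)
            else:
                assert a == pytest.approx(b, abs=1e-12)

    def test_dissimilarity_convention_invariance(self, rng):
        """Flipping both neural RDVs (1-x) leaves the index unchanged."""
        for _ in range(100):
            x, y, z = rng.uniform(size=(3, 6))
            a = f.commonality_index(x, y, z)
            b = f.commonality_index(1 - x, 1 - y, z)
            if np.isnan(a):
                assert np.isnan(b)
            else:
                assert a == pytest.approx(b, abs=1e-12)

    def test_zero_for_rank_orthogonal_model(self):
        """A model rank-orthogonal to both neural RDVs yields commonality 0.

        Exact rank-orthogonality at length 6 requires tied model values
        (with distinct ranks the rank cross-product cannot hit the required
        non-integer), which the binary 0.5/1 model RDMs naturally have.
        """
        x = np.array([1.0, 2, 3, 4, 5, 6])
        z = np.array([1.0, 3, 2, 2, 3, 1])  # tied, rank-orthogonal to x
        assert abs(spearman(x, z)) < 1e-12
        for y in ([1.0, 2, 3, 6, 4, 5], [1.0, 2, 4, 3, 5, 6], [1.0, 2, 5, 6, 3, 4]):
            y = np.asarray(y)
            assert abs(spearman(y, z)) < 1e-12
            assert f.commonality_index(x, y, z) == pytest.approx(0.0, abs=1e-12)

    def test_meg_equals_model_degenerate(self, rng):
        x = rng.normal(size=6)
        z = rng.normal(size=6)
        assert np.isnan(f.commonality_index(x, z.copy(), z))


class TestStoreyFDR:
    def test_all_ones(self):
        np.testing.assert_array_equal(storey_fdr(np.ones(20)), np.ones(20))

    def test_hand_computed_example(self):
        """One small p among 99 large ones, pi0 from the lambda=0.5 tail."""
        p = np.concatenate([[0.001], np.full(99, 0.9)])
        q = storey_fdr(p, lambda_=0.5)
        pi0 = min(1.0, 99 / (0.5 * 100))  # all 99 large ps exceed lambda
        assert q[0] == pytest.approx(pi0 * 100 * 0.001 / 1)
        assert q[0] == pytest.approx(0.1)

    def test_monotone_in_sorted_p(self, rng):
        p = rng.uniform(size=50)
        q = storey_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_small_family_falls_back_to_bh(self):
        p = np.array([0.01, 0.2, 0.5, 0.9])
        with pytest.warns(RuntimeWarning, match="Benjamini"):
            q = storey_fdr(p)
        m = len(p)
        expected = np.minimum.accumulate((np.sort(p) * m / np.arange(1, m + 1))[::-1])[::-1]
        np.testing.assert_allclose(np.sort(q), np.clip(expected, 0, 1))

    def test_bounds(self, rng):
        q = storey_fdr(rng.uniform(size=100))
        assert np.all((q >= 0) & (q <= 1))


def _make_trace(times, com, sig, alignment="stimulus"):
    n = len(times)
    return CommonalityTrace(
        roi="r", info_type="across", alignment=alignment,
        times_ms=np.asarray(times, dtype=float),
        commonality=np.asarray(com, dtype=float),
        rho_fmri_meg=np.zeros(n), rho_meg_model=np.zeros(n), rho_fmri_model=0.0,
        p_values=np.zeros(n), q_values=np.zeros(n),
        sig_mask=np.asarray(sig, dtype=bool),
    )


class TestTemporalMetrics:
    def test_constructed_single_peak(self):
        times = np.arange(0, 1000, 100.0)
        com = np.exp(-((times - 400) ** 2) / (2 * 100.0**2))
        sig = times >= 300
        tm = f.temporal_metrics(_make_trace(times, com, sig), response_ref_ms=1692.0)
        assert tm.time_to_first_sig_ms == 300
        assert tm.time_to_max_ms == 400
        assert tm.time_from_max_to_response_ms == 1692.0 - 400
        assert tm.reliable

    def test_never_significant(self):
        times = np.arange(0, 500, 100.0)
        com = np.linspace(0, 0.1, times.size)
        tm = f.temporal_metrics(_make_trace(times, com, np.zeros(times.size)))
        assert np.isnan(tm.time_to_first_sig_ms)
        assert tm.time_to_max_ms == times[-1]  # argmax still reported
        assert not tm.reliable

    def test_response_aligned_reference(self):
        times = np.arange(-500, 100, 100.0)
        com = -np.abs(times + 300) / 1000.0  # peak at -300
        sig = np.ones(times.size)
        tm = f.temporal_metrics(_make_trace(times, com, sig, alignment="response"))
        assert tm.time_to_max_ms == -300
        assert tm.time_from_max_to_response_ms == 300  # max precedes response

    def test_requires_inference(self):
        tr = _make_trace([0.0, 100.0, 200.0], [0, 1, 0], [0, 1, 0])
        tr.sig_mask = None
        with pytest.raises(ValueError, match="permutation"):
            f.temporal_metrics(tr)


class TestPermutationPipeline:
    @pytest.fixture(scope="class")
    def planted_world(self, small_trials):
        """fMRI ROI and a 300-700 ms MEG window share 'across' structure."""
        from fusionrsa.rdm import build_model_rdm, build_neural_rdm, rdm_to_rdv
        from fusionrsa.schemes import assign_conditions, scheme_conditions

        ut = f.usable_trials(small_trials)
        betas = f.simulate_fmri_betas(
            small_trials, [{"roi": "IPS", "n_voxels": 30}],
            [f.EffectSpec("across", 2.0, target="IPS")], scheme="across", seed=2,
        )["IPS"]
        ep = f.simulate_meg_epochs(
            ut, n_sensors=16,
            effect_specs=[f.EffectSpec("across", 2.0, target=(300.0, 700.0))],
            alignment="stimulus", sampling_rate_hz=25.0, span_ms=(-80.0, 920.0), seed=3,
        )
        cond = assign_conditions(ut, "across").astype(str).to_numpy()
        acc = f.pairwise_condition_decoding(
            ep, condition_labels=cond, conditions=scheme_conditions("across"),
            k=5, seed=4,
        )
        meg_rdvs = np.stack(
            [rdm_to_rdv(build_neural_rdm(acc[i], "across").matrix) for i in range(acc.shape[0])]
        )
        return betas, meg_rdvs, build_model_rdm("across").rdv, ep.times_ms

    def test_planted_window_detected(self, planted_world):
        betas, meg_rdvs, model, times = planted_world
        tr = f.permutation_test_commonality(
            betas, meg_rdvs, model, times, info_type="across", n_perm=150, seed=5
        )
        inside = (times >= 300) & (times <= 700)
        outside = (times < 250) | (times > 750)
        assert np.nanmean(tr.commonality[inside]) > 0.3
        assert tr.sig_mask[inside].any()
        # single-dataset false-positive check is loose; the 50-replicate
        # calibration lives in the acceptance suite
        assert tr.sig_mask[outside].mean() <= 0.3
        assert np.nanmean(tr.commonality[outside]) < np.nanmean(tr.commonality[inside]) / 2

    def test_p_value_bounds_and_determinism(self, planted_world):
        betas, meg_rdvs, model, times = planted_world
        a = f.permutation_test_commonality(
            betas, meg_rdvs, model, times, n_perm=120, seed=9
        )
        b = f.permutation_test_commonality(
            betas, meg_rdvs, model, times, n_perm=120, seed=9
        )
        np.testing.assert_array_equal(a.p_values, b.p_values)
        ok = ~np.isnan(a.p_values)
        assert np.all(a.p_values[ok] >= 1 / 121)
        assert np.all(a.p_values[ok] <= 1.0)

    def test_negative_commonality_never_significant(self, planted_world):
        betas, meg_rdvs, model, times = planted_world
        tr = f.permutation_test_commonality(
            betas, meg_rdvs, model, times, n_perm=120, seed=10
        )
        assert not np.any(tr.sig_mask & (tr.commonality <= 0))

    def test_trace_length_matches_grid(self, planted_world):
        betas, meg_rdvs, model, times = planted_world
        tr = f.commonality_timecourse(np.arange(6.0), meg_rdvs, model, times)
        assert tr.commonality.size == times.size
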