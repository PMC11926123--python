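"""Sparse copying-HMM correctness: limits, conservation, dense oracle."""

import numpy as np
import pytest

from sparsepaint.hmm import (HMMParams, _min_cover, estimate_lambda,
                             expected_chunk_counts, expected_chunk_lengths,
                             posterior, run_forward_backward)
from sparsepaint.painter import dosage_tracks, paint_targets
from sparsepaint.panel import GeneticMap
from sparsepaint.pbwt import (MatchSet, build_pbwt, impute_empty_positions,
                              report_q_longest_matches)
from sparsepaint.simulate import (SimConfig, accuracy_bestguess, accuracy_r2,
                                  simulate)

from _oracles import (dense_li_stephens, mosaic_target,
                      sparse_posterior_to_dense)
from conftest import make_panel, uniform_map


def _full_match_ms(K, n_ref, donors):
    """MatchSet where each listed donor matches across the whole chromosome."""
    ms = MatchSet(n_snp=K, n_ref=n_ref, n_target=1)
    for d in donors:
        ms.add(0, [d], [0], [K - 1])
    return ms


class TestForwardBackward:
    def test_single_donor_everywhere(self):
        K = 20
        ms = _full_match_ms(K, 4, [2])
        gmap = uniform_map(K)
        params = HMMParams.from_map(gmap, 10.0, 4)
        fb = run_forward_backward(ms, gmap, params)
        assert np.allclose(fb.fvals, 1.0)
        post = posterior(fb)
        assert np.allclose(post, 1.0)

    def test_two_donors_zero_gaps_stay_half(self):
        K = 10
        ms = _full_match_ms(K, 6, [1, 4])
        gmap = GeneticMap(cm=np.zeros(K))  # rho = 1 everywhere
        params = HMMParams.from_map(gmap, 10.0, 6)
        fb = run_forward_backward(ms, gmap, params)
        assert np.allclose(fb.fvals, 0.5)
        assert np.allclose(posterior(fb), 0.5)

    def test_backward_boundary_uniform(self):
        K = 8
        ms = _full_match_ms(K, 5, [0, 3])
        gmap = uniform_map(K)
        params = HMMParams.from_map(gmap, 5.0, 5)
        fb = run_forward_backward(ms, gmap, params)
        last = slice(fb.indptr[K - 1], fb.indptr[K])
        assert np.allclose(fb.bvals[last], 1.0 / 5)
        assert fb.bdefault[K - 1] == pytest.approx(1.0 / 5)

    def test_infinite_gap_removes_linkage(self):
        # a huge gap makes rho ~ 0: backward values equalise across donors
        K = 4
        ms = MatchSet(n_snp=K, n_ref=4, n_target=1)
        ms.add(0, [0, 1], [0, 0], [3, 1])  # donor 1 only matches SNPs 0-1
        ms.add(0, [2], [2], [3])
        gmap = GeneticMap(cm=np.array([0.0, 0.1, 5000.0, 5000.1]))
        params = HMMParams.from_map(gmap, 10.0, 4)
        fb = run_forward_backward(ms, gmap, params)
        sl = slice(fb.indptr[1], fb.indptr[2])  # SNP 1, before the huge gap
        assert np.allclose(fb.bvals[sl], fb.bvals[sl][0])


@pytest.fixture(scope="module")
def oracle_fixtures():
    """Panels with mosaic targets: a match exists at every SNP."""
    rng = np.random.default_rng(99)
    out = []
    for _ in range(5):
        N, K = 16, 200
        base = rng.integers(0, 2, size=(4, K)).astype(np.uint8)
        X = base[rng.integers(0, 4, size=N)]
        X = X ^ (rng.random(X.shape) < 0.05)
        y = mosaic_target(rng, X, 5)
        gaps = rng.uniform(0.0002, 0.004, size=K - 1)
        cm = np.concatenate([[0.0], np.cumsum(gaps) * 100])
        out.append((X, y, gaps, GeneticMap(cm=cm)))
    return out


def _sparse_run(X, y, gmap, lam, Q=None, L_min=1):
    N, K = X.shape
    panel = make_panel(X)
    tgt = make_panel(np.vstack([y, y]))
    ms = report_q_longest_matches(build_pbwt(panel), tgt, gmap,
                                  Q=Q or 2 * N, L_min=L_min, L_0=2 * K)
    ms = impute_empty_positions(ms, gmap)
    params = HMMParams.from_map(gmap, lam, N)
    fb = run_forward_backward(ms, gmap, params, t=0)
    post = posterior(fb)
    l_hat = expected_chunk_lengths(fb, gmap, N, post=post)
    c_hat = expected_chunk_counts(fb, N, post=post)
    return fb, post, l_hat, c_hat


class TestDenseOracle:
    def test_posterior_lengths_counts_match_dense(self, oracle_fixtures):
        for X, y, gaps, gmap in oracle_fixtures:
            fb, post, l_hat, c_hat = _sparse_run(X, y, gmap, lam=50.0)
            post_d, l_d, c_d = dense_li_stephens(X, y, gaps, 50.0, mu=1e-9)
            P = sparse_posterior_to_dense(fb, post, X.shape[0])
            assert np.abs(P - post_d).max() < 1e-5
            assert np.abs(l_hat - l_d).max() < 1e-5
            assert np.abs(c_hat - c_d).max() < 1e-5

    def test_conservation(self, oracle_fixtures):
        for X, y, gaps, gmap in oracle_fixtures:
            fb, post, l_hat, _ = _sparse_run(X, y, gmap, lam=100.0)
            assert l_hat.sum() == pytest.approx(gmap.total_morgans, rel=1e-6)
            for j in range(fb.n_snp):
                sl = slice(fb.indptr[j], fb.indptr[j + 1])
                assert post[sl].sum() == pytest.approx(1.0, abs=1e-8)


class TestChunkSummaries:
    def test_single_donor_length_is_G(self):
        K = 30
        ms = _full_match_ms(K, 1, [0])
        gmap = uniform_map(K, total_cm=37.0)
        params = HMMParams.from_map(gmap, 5.0, 1)
        fb = run_forward_backward(ms, gmap, params)
        l_hat = expected_chunk_lengths(fb, gmap, 1)
        assert l_hat[0] == pytest.approx(gmap.total_morgans, rel=1e-9)

    def test_counts_approach_one_as_lambda_vanishes(self):
        K = 30
        ms = _full_match_ms(K, 3, [0])
        gmap = uniform_map(K)
        c_prev = None
        for lam in (10.0, 1.0, 1e-3, 1e-6):
            params = HMMParams.from_map(gmap, lam, 3)
            fb = run_forward_backward(ms, gmap, params)
            c = expected_chunk_counts(fb, 3).sum()
            assert c >= 1.0 - 1e-9
            if c_prev is not None:
                assert c <= c_prev + 1e-12
            c_prev = c
        assert c_prev == pytest.approx(1.0, abs=1e-6)

    def test_monotone_locality_in_lambda(self):
        # two donors: one long match, one short; more recombination spreads
        # posterior away from the long-match donor's competitor
        K = 40
        ms = MatchSet(n_snp=K, n_ref=2, n_target=1)
        ms.add(0, [0], [0], [K - 1])     # long-match donor
        ms.add(0, [1], [10], [14])       # short competitor
        gmap = uniform_map(K)
        ms = impute_empty_positions(ms, gmap)
        prev = None
        for lam in (1.0, 10.0, 100.0):
            params = HMMParams.from_map(gmap, lam, 2)
            fb = run_forward_backward(ms, gmap, params)
            post = posterior(fb)
            comp = 0.0
            for j in range(K):
                sl = slice(fb.indptr[j], fb.indptr[j + 1])
                d = fb.donors[sl]
                comp += post[sl][d == 1].sum()
            comp /= K
            if prev is not None:
                assert comp >= prev - 1e-12
            prev = comp


class TestLambda:
    def test_single_full_match_floors(self):
        ms = _full_match_ms(10, 2, [0])
        assert estimate_lambda(ms, uniform_map(10)) == pytest.approx(1e-6)

    def test_two_abutting_matches(self):
        K = 10
        ms = MatchSet(n_snp=K, n_ref=2, n_target=1)
        ms.add(0, [0, 1], [0, 5], [4, 9])
        gmap = GeneticMap(cm=np.linspace(0, 50.0, K))  # G = 0.5 Morgans
        assert estimate_lambda(ms, gmap) == pytest.approx(1 / 0.5)

    @pytest.mark.parametrize("trial", range(5))
    def test_min_cover_equals_dp_oracle(self, trial):
        from _oracles import min_cover_dp

        rng = np.random.default_rng(500 + trial)
        K = 40
        n_int = 15
        s = rng.integers(0, K, size=n_int)
        e = np.minimum(s + rng.integers(1, 15, size=n_int), K - 1)
        got = _min_cover(s.astype(np.int64), e.astype(np.int64), K)
        exp = min_cover_dp(list(zip(s.tolist(), e.tolist())), K)
        assert got == exp

    def test_lambda_grows_with_admixture_age(self):
        lams = []
        for g in (5, 20, 80):
            cfg = SimConfig(n_pop=2, n_ref_per_pop=30, n_target=10,
                            n_snp=1000, generations=g, seed=17)
            ref, tgt, gmap, _ = simulate(cfg)
            res = paint_targets(ref, tgt, gmap, store_pop_probs=False)
            lams.append(res.lam)
        assert lams[0] < lams[1] < lams[2]


class TestPaintTargets:
    def test_verbatim_population_member(self, sim_small):
        cfg, (ref, tgt, gmap, truth) = sim_small
        # target copied verbatim from a pop1 reference haplotype
        h = 2 * cfg.n_ref_per_pop * 1 + 4  # a pop1 haplotype
        alleles = np.vstack([ref.alleles[h], ref.alleles[h]])
        one = make_panel(alleles)
        res = paint_targets(ref, one, gmap, mode="tvr", Q=10, L_min=20)
        a = res.pops.index("pop1")
        assert res.pop_probs[0, a].mean() > 0.95

    def test_exchangeability_reference_vs_target(self, sim_small):
        cfg, (ref, tgt, gmap, truth) = sim_small
        res_ref = paint_targets(ref, None, gmap, mode="rvr", Q=10, L_min=20,
                                lam=150.0)
        # the designated (lowest-index) individual of pop0 gets, as a target
        # under leave-one-out, exactly the rvr donor pool
        alleles = ref.alleles[0:2]
        one = make_panel(alleles)
        res_tgt = paint_targets(ref, one, gmap, mode="tvr", Q=10, L_min=20,
                                lam=150.0, leave_one_out=True)
        assert np.allclose(res_tgt.pop_probs[0], res_ref.pop_probs[0],
                           atol=1e-6)
        assert np.allclose(res_tgt.pop_probs[1], res_ref.pop_probs[1],
                           atol=1e-6)

    def test_lambda_misspecification_hurts(self, sim_small):
        cfg, (ref, tgt, gmap, truth) = sim_small
        good = paint_targets(ref, tgt, gmap, mode="tvr", Q=10, L_min=20)
        bad = paint_targets(ref, tgt, gmap, mode="tvr", Q=10, L_min=20,
                            lam=good.lam * 100)
        acc_good = accuracy_bestguess(good.pop_probs, truth.labels)
        acc_bad = accuracy_bestguess(bad.pop_probs, truth.labels)
        r2_good = accuracy_r2(dosage_tracks(good), truth.dosage)
        r2_bad = accuracy_r2(dosage_tracks(bad), truth.dosage)
        assert acc_good > acc_bad
        assert r2_good > r2_bad

    def test_leave_one_out_empty_population_errors(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(4, 50)).astype(np.uint8)
        panel = make_panel(X, pops=["A", "B"])
        with pytest.raises(ValueError, match="single individual"):
            paint_targets(panel, None, uniform_map(50), mode="rvr",
                          Q=2, L_min=1)
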