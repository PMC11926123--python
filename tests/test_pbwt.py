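"""PBWT construction and match queries against exhaustive oracles."""

import time

import numpy as np
import pytest

from sparsepaint.panel import GeneticMap
from sparsepaint.pbwt import (MatchSet, _build_arrays, build_pbwt,
                              impute_empty_positions, long_matches,
                              report_q_longest_matches, set_maximal_matches)
from sparsepaint.simulate import SimConfig, simulate

from _oracles import (enumerate_maximal_matches, greedy_q_longest_oracle,
                      set_maximal_oracle)
from conftest import make_panel, uniform_map


def _matchset_triples(ms):
    out = set()
    for t, m in ms.matches.items():
        for r, s, e in zip(m["ref"], m["s"], m["e"]):
            out.add((t, r, s, e))
    return out


class TestBuild:
    def test_identical_haplotypes_zero_divergence(self):
        panel = make_panel(np.tile([0, 1, 1, 0, 1], (6, 1)))
        idx = build_pbwt(panel)
        # all neighbours match from the start; only the first sorted row
        # carries the no-previous sentinel
        assert np.all(idx.divergence[1:, 1:] == 0)

    def test_prefix_arrays_match_reversed_prefix_sort(self, rng):
        M, K = 8, 32
        X = rng.integers(0, 2, size=(M, K)).astype(np.uint8)
        idx = build_pbwt(make_panel(X))
        for k in range(K + 1):
            # sort by reversed prefix y[k-1], ..., y[0], ties by index
            keys = [np.arange(M)] + [X[:, j] for j in range(k)]
            expected = np.lexsort(tuple(keys))
            assert np.array_equal(idx.prefix[k], expected), k

    def test_single_haplotype_prefix(self):
        a, d = _build_arrays(np.array([[0, 1, 1, 0]], dtype=np.uint8))
        assert np.all(a == 0)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            build_pbwt(make_panel(np.empty((0, 0))))


class TestSetMaximal:
    def test_target_copy_of_reference(self, rng):
        X = rng.integers(0, 2, size=(4, 20)).astype(np.uint8)
        ref = make_panel(X)
        tgt = make_panel(np.vstack([X[2], X[2]]))
        ms = set_maximal_matches(build_pbwt(ref), tgt)
        m = ms.get(0)
        assert set(zip(m["ref"], m["s"], m["e"])) == {(2, 0, 19)}

    @pytest.mark.parametrize("trial", range(8))
    def test_all_vs_all_equals_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        M, K = 10, 50
        X = rng.integers(0, 2, size=(M, K)).astype(np.uint8)
        ms = set_maximal_matches(build_pbwt(make_panel(X)),
                                 exclude_same_individual=False)
        assert _matchset_triples(ms) == set_maximal_oracle(X)

    @pytest.mark.parametrize("trial", range(4))
    def test_target_vs_reference_equals_oracle(self, trial):
        rng = np.random.default_rng(200 + trial)
        X = rng.integers(0, 2, size=(8, 40)).astype(np.uint8)
        Y = rng.integers(0, 2, size=(4, 40)).astype(np.uint8)
        # mix in a near-copy so long matches exist
        Y[0] = X[3]
        Y[0, 17] ^= 1
        ms = set_maximal_matches(build_pbwt(make_panel(X)), make_panel(Y))
        got = _matchset_triples(ms)
        allm = enumerate_maximal_matches(Y, X)
        exp = set()
        for t in range(Y.shape[0]):
            mine = [(r, s, e) for (tt, r, s, e) in allm if tt == t]
            for (r, s, e) in mine:
                contained = any(s2 <= s and e2 >= e and (s2 < s or e2 > e)
                                for (_r2, s2, e2) in mine)
                if not contained:
                    exp.add((t, r, s, e))
        assert got == exp

    def test_no_shared_alleles_empty(self):
        ref = make_panel(np.zeros((4, 10)))
        tgt = make_panel(np.tile([1, 1], (2, 5)).reshape(2, 10) * 0 + 1)
        ms = set_maximal_matches(build_pbwt(ref), tgt)
        assert ms.total_matches() == 0


class TestLongMatches:
    @pytest.mark.parametrize("trial", range(6))
    def test_L1_equals_brute_force(self, trial):
        rng = np.random.default_rng(300 + trial)
        X = rng.integers(0, 2, size=(6, 24)).astype(np.uint8)
        ms = long_matches(build_pbwt(make_panel(X)), None, 1)
        got = {(min(t, r), max(t, r), s, e)
               for (t, r, s, e) in _matchset_triples(ms)}
        assert got == enumerate_maximal_matches(X)

    def test_full_length_copy(self, rng):
        X = rng.integers(0, 2, size=(4, 16)).astype(np.uint8)
        tgt = make_panel(np.vstack([X[1], 1 - X[1]]))
        ms = long_matches(build_pbwt(make_panel(X)), tgt, 16)
        m = ms.get(0)
        assert set(zip(m["ref"], m["s"], m["e"])) == {(1, 0, 15)}

    def test_monotone_in_L(self, rng):
        X = rng.integers(0, 2, size=(10, 60)).astype(np.uint8)
        idx = build_pbwt(make_panel(X))
        prev = None
        for L in (2, 4, 8, 16):
            cur = _matchset_triples(long_matches(idx, None, L))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_L_beyond_K_warns_empty(self, rng):
        X = rng.integers(0, 2, size=(4, 10)).astype(np.uint8)
        with pytest.warns(UserWarning):
            ms = long_matches(build_pbwt(make_panel(X)), None, 11)
        assert ms.total_matches() == 0


class TestReportQLongest:
    def test_full_copy_single_match(self, rng):
        X = rng.integers(0, 2, size=(6, 30)).astype(np.uint8)
        tgt = make_panel(np.vstack([X[4], X[4]]))
        gmap = uniform_map(30)
        ms = report_q_longest_matches(build_pbwt(make_panel(X)), tgt, gmap,
                                      Q=1, L_min=30, L_0=32)
        m = ms.get(0)
        assert (m["ref"][0], m["s"][0], m["e"][0]) == (4, 0, 29)
        assert len(m["ref"]) == 1

    def test_equals_greedy_oracle_on_simulated_fixture(self):
        cfg = SimConfig(n_pop=3, n_ref_per_pop=8, n_target=3, n_snp=300,
                        seed=42)
        ref, tgt, gmap, _ = simulate(cfg)
        Q, L_min = 5, 10
        ms = report_q_longest_matches(build_pbwt(ref), tgt, gmap, Q=Q,
                                      L_min=L_min, L_0=256)
        allm = enumerate_maximal_matches(tgt.alleles, ref.alleles)
        for t in range(tgt.n_hap):
            mine = [(r, s, e) for (tt, r, s, e) in allm
                    if tt == t and e - s + 1 >= L_min]
            exp = greedy_q_longest_oracle(mine, gmap.cm, Q, ref.n_snp)
            m = ms.get(t)
            got = set(zip(m["ref"], m["s"], m["e"]))
            assert got == exp, t

    def test_coverage_property(self):
        cfg = SimConfig(n_pop=2, n_ref_per_pop=10, n_target=2, n_snp=200,
                        seed=7)
        ref, tgt, gmap, _ = simulate(cfg)
        Q, L_min = 4, 8
        ms = report_q_longest_matches(build_pbwt(ref), tgt, gmap, Q=Q,
                                      L_min=L_min)
        allm = enumerate_maximal_matches(tgt.alleles, ref.alleles)
        for t in range(tgt.n_hap):
            cov = ms.coverage(t)
            full = np.zeros(ref.n_snp, dtype=int)
            for (tt, r, s, e) in allm:
                if tt == t and e - s + 1 >= L_min:
                    full[s:e + 1] += 1
            assert np.array_equal(np.minimum(cov, Q), np.minimum(full, Q))

    def test_runtime_roughly_linear_in_K(self):
        rng = np.random.default_rng(5)

        def run(K):
            cfg = SimConfig(n_pop=2, n_ref_per_pop=20, n_target=5, n_snp=K,
                            seed=3)
            ref, tgt, gmap, _ = simulate(cfg)
            idx = build_pbwt(ref)
            t0 = time.time()
            report_q_longest_matches(idx, tgt, gmap, Q=5, L_min=10)
            return time.time() - t0

        run(500)  # warm JIT
        t1, t2 = run(1000), run(2000)
        assert t2 < 3 * t1 + 0.5  # loose: doubling K less than triples time


class TestImpute:
    def _ms(self, K, entries):
        ms = MatchSet(n_snp=K, n_ref=4, n_target=1)
        for (r, s, e) in entries:
            ms.add(0, [r], [s], [e])
        return ms

    def test_identity_when_no_gaps(self):
        ms = self._ms(10, [(0, 0, 9)])
        gmap = uniform_map(10)
        out = impute_empty_positions(ms, gmap)
        m = out.get(0)
        assert list(zip(m["ref"], m["s"], m["e"])) == [(0, 0, 9)]

    def test_tie_goes_left(self):
        # SNP 2 empty, equidistant in cM between covered 1 and 3
        ms = self._ms(5, [(0, 0, 1), (1, 3, 4)])
        gmap = uniform_map(5)
        out = impute_empty_positions(ms, gmap)
        m = out.get(0)
        imputed = [(r, s, e) for r, s, e, i in
                   zip(m["ref"], m["s"], m["e"], m["imputed"]) if i]
        assert imputed == [(0, 2, 2)]  # donors copied from SNP 1 (left)

    def test_masked_region_matches_linear_scan(self, rng):
        K = 60
        cm = np.sort(rng.uniform(0, 20, K))
        gmap = GeneticMap(cm=cm)
        ms = self._ms(K, [(0, 0, 14), (1, 10, 19), (2, 40, 59)])
        out = impute_empty_positions(ms, gmap)
        cov_after = out.coverage(0)
        assert np.all(cov_after > 0)
        covered = sorted(set(range(0, 20)) | set(range(40, 60)))
        for k in range(20, 40):
            dists = [abs(cm[k] - cm[c]) for c in covered]
            src = covered[int(np.argmin(dists))]
            m = out.get(0)
            at_k = {r for r, s, e in zip(m["ref"], m["s"], m["e"])
                    if s <= k <= e}
            exp = {r for r, s, e in zip([0, 1, 2], [0, 10, 40], [14, 19, 59])
                   if s <= src <= e}
            assert at_k == exp, k

    def test_matchless_haplotype_raises(self):
        ms = MatchSet(n_snp=5, n_ref=2, n_target=1)
        ms.matches[0] = MatchSet._empty()
        with pytest.raises(ValueError, match="haplotype 0"):
            impute_empty_positions(ms, uniform_map(5))
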