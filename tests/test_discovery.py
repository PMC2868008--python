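"""The three-phase discovery engine: starts, EM, scoring, erasing."""

import math

import numpy as np
import pytest

import memepsp as mp
from memepsp.discovery import ColumnPvalueCalculator, EMResult


def zero_order(p):
    return mp.BackgroundModel.zero_order(np.asarray(p, dtype=float))


class TestSubsequenceToPSPM:
    def test_definition(self):
        theta = mp.subsequence_to_pspm("A", beta=0.55)
        assert np.allclose(theta.matrix[0], [0.55, 0.15, 0.15, 0.15])

    def test_columns_stochastic(self):
        theta = mp.subsequence_to_pspm("GATTACA", beta=0.7)
        assert np.allclose(theta.matrix.sum(axis=1), 1.0)

    def test_beta_one_is_point_mass(self):
        theta = mp.subsequence_to_pspm("CG", beta=1.0)
        assert theta.matrix[0, 1] == 1.0 and theta.matrix[1, 2] == 1.0


class TestPhase1:
    def test_planted_word_wins(self):
        """With the same word planted in every sequence the winning
        starting point is that word."""
        rng = np.random.default_rng(0)
        word = "GGATCCGG"
        seqs = []
        for _ in range(10):
            s = list(rng.choice(list("ACGT"), size=50))
            j = int(rng.integers(0, 43))
            s[j:j + 8] = list(word)
            seqs.append("".join(s))
        sset = mp.SequenceSet.from_strings(seqs)
        starts = mp.phase1_search(sset, None, None, 8, model="oops",
                                  strand_mode="single")
        (t, cand), = starts.items()
        assert t == 10
        assert cand.word == word

    def test_uniform_prior_matches_likelihood_only_oracle(self):
        """With a uniform PSP the Phase I ranking reduces to plain
        likelihood ranking (the prior is constant per sequence)."""
        rng = np.random.default_rng(3)
        sset = mp.SequenceSet.from_strings(
            ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(3)])
        w, beta = 4, 0.55
        bg = mp.BackgroundModel.uniform()
        starts = mp.phase1_search(sset, None, bg, w, model="oops",
                                  strand_mode="single", beta=beta)
        # oracle: exhaustive scoring, likelihood-only site choice
        best_score, best_word = -np.inf, None
        enc = sset.encoded()
        for x in enc:
            for a in range(len(x) - w + 1):
                theta = mp.subsequence_to_pspm(x[a:a + w], beta)
                sites = []
                for y in enc:
                    liks = [mp.site_likelihood(theta, y, j)
                            for j in range(len(y) - w + 1)]
                    sites.append(y[int(np.argmax(liks)):][:w])
                score = mp.weighted_llr(sites, np.ones(len(sites)), bg)
                if score > best_score:
                    best_score, best_word = score, sites and theta
        got = starts[3]
        assert got.score == pytest.approx(best_score, rel=1e-9)

    def test_zoops_schedule_keys(self, planted_easy):
        seqs, _, _ = planted_easy  # n = 15
        starts = mp.phase1_search(seqs, None, None, 8, model="zoops")
        assert sorted(starts) == [2, 4, 8, 15]

    def test_all_zero_prior_errors(self, toy_seqs):
        psp = mp.make_uniform_psp(toy_seqs, 6)
        for v in psp.positional:
            v[:] = 0.0
        psp.p0[:] = 1.0
        with pytest.raises(ValueError, match="no legal sites"):
            mp.phase1_search(toy_seqs, psp, None, 6, model="zoops")


def brute_force_estep(seqs, theta, gamma, psp, bg, strand_mode="single"):
    """Enumerate every outcome (site at each (j, strand) / no site)."""
    alph = seqs.alphabet
    p = bg.marginals
    w = theta.width
    n_str = 2 if strand_mode == "double" else 1
    out_z, out_z0 = [], []
    for i, x in enumerate(seqs.encoded()):
        L = len(x)
        m = L - w + 1
        qs = psp.positional[i][:m] / psp.positional[i][:m].sum()
        bg_all = np.prod(p[x])
        weights = np.zeros((n_str, m))
        for j in range(m):
            for s in range(n_str):
                win = x[j:j + w] if s == 0 else alph.revcomp(x[j:j + w])
                lik = np.prod(theta.matrix[np.arange(w), win])
                site_seq_lik = bg_all / np.prod(p[x[j:j + w]]) * lik
                weights[s, j] = gamma * (qs[j] / n_str) * site_seq_lik
        no_site = (1 - gamma) * bg_all
        total = weights.sum() + no_site
        out_z.append(weights / total)
        out_z0.append(no_site / total)
    return out_z, np.array(out_z0)


class TestEStep:
    def test_oops_uniform_everything_gives_uniform_z(self, toy_seqs):
        theta = mp.PSPM.uniform(4)
        params = mp.ModelParams(theta, 1.0, None, "oops", "single")
        Z = mp.e_step(toy_seqs, params, mp.BackgroundModel.uniform())
        for zi, L in zip(Z.z, toy_seqs.lengths):
            m = L - 4 + 1
            assert np.allclose(zi[0], 1.0 / m)
        assert np.allclose(Z.z0, 0.0)

    def test_prior_point_mass_pins_z(self, toy_seqs):
        psp = mp.make_uniform_psp(toy_seqs, 4, strand_mode="single")
        for v in psp.positional:
            v[:] = 0.0
            v[2] = 1.0
        theta = mp.PSPM(np.random.default_rng(1).dirichlet(np.ones(4), 4))
        params = mp.ModelParams(theta, 1.0, psp, "oops", "single")
        Z = mp.e_step(toy_seqs, params)
        for zi in Z.z:
            assert zi[0, 2] == pytest.approx(1.0)

    @pytest.mark.parametrize("strand_mode", ["single", "double"])
    def test_zoops_matches_bruteforce_enumeration(self, strand_mode):
        seqs = mp.SequenceSet.from_strings(["ACGTT", "TGCAA"])
        rng = np.random.default_rng(7)
        theta = mp.PSPM(rng.dirichlet(np.ones(4), size=3))
        bg = zero_order([0.3, 0.2, 0.2, 0.3])
        psp = mp.make_uniform_psp(seqs, 3, strand_mode=strand_mode)
        for v in psp.positional:
            v[:3] = rng.dirichlet(np.ones(3))
        gamma = 0.5
        params = mp.ModelParams(theta, gamma, psp, "zoops", strand_mode)
        Z = mp.e_step(seqs, params, bg)
        ez, ez0 = brute_force_estep(seqs, theta, gamma, psp, bg, strand_mode)
        for i in range(2):
            got = Z.z[i]
            want = ez[i]
            if strand_mode == "double":
                # oracle indexes minus strand by window start == forward
                # leftmost coordinate, same convention as ZMatrix
                assert np.allclose(got, want, atol=1e-12)
            else:
                assert np.allclose(got, want, atol=1e-12)
        assert np.allclose(Z.z0, ez0, atol=1e-12)

    def test_rows_normalize(self, planted_easy):
        seqs, truth, motif = planted_easy
        psp = mp.generate_psp(truth, seqs, 8, 0.6, "zoops")
        params = mp.ModelParams(motif, 0.7, psp, "zoops", "double")
        Z = mp.e_step(seqs, params)
        for i, zi in enumerate(Z.z):
            assert abs(Z.z0[i] + zi.sum() - 1.0) <= 1e-9

    def test_all_zero_mass_errors(self):
        seqs = mp.SequenceSet.from_strings(["ACGTT"])
        psp = mp.make_uniform_psp(seqs, 3, strand_mode="single")
        psp.positional[0][:] = 0.0
        psp.p0[0] = 1.0
        theta = mp.PSPM.uniform(3)
        params = mp.ModelParams(theta, 1.0, psp, "oops", "single")
        with pytest.raises(ValueError, match="posterior mass"):
            mp.e_step(seqs, params)


class TestMStep:
    def test_point_mass_recovers_word(self):
        seqs = mp.SequenceSet.from_strings(["ACGTA", "TACGT"])
        Z = mp.ZMatrix(np.zeros(2),
                       [np.array([[1.0, 0, 0]]), np.array([[0, 1.0, 0]])])
        params = mp.m_step(seqs, Z, "oops", zero_order([0.25] * 4),
                           pseudo_frac=1e-12, strand_mode="single")
        # both selected windows are "ACG"
        assert np.allclose(params.theta.matrix[0], [1, 0, 0, 0], atol=1e-9)
        assert np.allclose(params.theta.matrix[1], [0, 1, 0, 0], atol=1e-9)
        assert np.allclose(params.theta.matrix[2], [0, 0, 1, 0], atol=1e-9)

    def test_gamma_clamps_at_floor(self):
        seqs = mp.SequenceSet.from_strings(["ACGTA", "TACGT"])
        Z = mp.ZMatrix(np.ones(2), [np.zeros((1, 3)), np.zeros((1, 3))])
        params = mp.m_step(seqs, Z, "zoops", strand_mode="single")
        assert params.gamma == pytest.approx(0.5)  # floor 1/n with n = 2

    def test_matches_direct_count_arithmetic(self):
        rng = np.random.default_rng(5)
        seqs = mp.SequenceSet.from_strings(["ACGTAC", "GGTACC"])
        w = 3
        z = [rng.dirichlet(np.ones(4)) * 0.8 for _ in range(2)]
        Z = mp.ZMatrix(np.array([0.2, 0.2]),
                       [z[0].reshape(1, 4), z[1].reshape(1, 4)])
        bg = zero_order([0.4, 0.1, 0.1, 0.4])
        pf = 0.01
        params = mp.m_step(seqs, Z, "zoops", bg, pseudo_frac=pf,
                           strand_mode="single")
        counts = np.zeros((w, 4))
        for i, x in enumerate(seqs.encoded()):
            for j in range(4):
                for k in range(w):
                    counts[k, x[j + k]] += z[i][j]
        delta = pf * bg.marginals
        expect = (counts + delta) / (sum(zz.sum() for zz in z) + delta.sum())
        assert np.allclose(params.theta.matrix, expect, atol=1e-12)
        assert params.gamma == pytest.approx(0.8)


class TestRunEM:
    def _start(self, word, w, t):
        return mp.CandidateStart(word, w, t, 0.0,
                                 mp.subsequence_to_pspm(word, 0.55))

    def test_fixed_point_on_noiseless_data(self):
        word = "GATTACAT"
        seqs = mp.SequenceSet.from_strings(
            ["ACGTGCAT" + word + "CCGGAATT" for _ in range(6)])
        start = mp.CandidateStart(word, 8, 6, 0.0,
                                  mp.subsequence_to_pspm(word, 1.0))
        res = mp.run_em(start, seqs, None, None, "oops",
                        strand_mode="single")
        assert res.converged and res.n_iter <= 2
        assert np.abs(res.params.theta.matrix.max(axis=1) - 1).max() < 0.01

    def test_monotone_objective_many_starts(self, planted_easy):
        seqs, truth, _ = planted_easy
        enc = seqs.encoded()
        for s in range(20):
            i, j = s % len(seqs), (7 * s) % (len(enc[0]) - 8)
            word = enc[i][j:j + 8]
            if (word < 0).any():
                continue
            start = mp.CandidateStart("x", 8, len(seqs), 0.0,
                                      mp.subsequence_to_pspm(word))
            res = mp.run_em(start, seqs, None, None, "zoops")
            tr = np.asarray(res.objective_trace)
            assert (np.diff(tr) >= -1e-8 * np.abs(tr[:-1])).all()

    def test_infinite_tol_single_iteration(self, planted_easy):
        seqs, _, _ = planted_easy
        res = mp.run_em(self._start("GATTACCA", 8, len(seqs)), seqs, None,
                        None, "oops", tol=float("inf"))
        assert res.n_iter == 1 and len(res.objective_trace) == 1


class TestColumnPvalue:
    def test_single_draw_degenerate(self, uniform_bg):
        assert mp.column_pvalue([1, 0, 0, 0], 1, uniform_bg) == \
            pytest.approx(1.0, abs=1e-12)

    def test_two_draw_pure_column(self, uniform_bg):
        # brute force over 4^2 ordered columns: only (2,0,0,0)-type beats it
        assert mp.column_pvalue([2, 0, 0, 0], 2, uniform_bg) == \
            pytest.approx(4 / 16, abs=1e-12)

    def test_minimum_llr_gives_one(self, uniform_bg):
        assert mp.column_pvalue([1, 1, 1, 1], 4, uniform_bg) == \
            pytest.approx(1.0, abs=1e-12)

    def test_zero_sites(self, uniform_bg):
        assert mp.column_pvalue([0, 0, 0, 0], 0, uniform_bg) == 1.0

    def test_lattice_approximates_exact(self, skewed_bg):
        calc = ColumnPvalueCalculator(skewed_bg)
        t = 30
        exact = calc._exact_table(t)
        lattice = calc._lattice_table(t)
        for counts in ([30, 0, 0, 0], [10, 10, 5, 5], [15, 5, 5, 5]):
            obs = calc._llr_of_counts(np.array(counts, dtype=float), t)
            def look(tbl):
                llr, cum = tbl
                idx = np.searchsorted(-llr, -(obs - 1e-9), side="right")
                return cum[idx - 1] if idx else 0.0
            assert look(lattice) == pytest.approx(look(exact), abs=0.02)


class TestProductPvalue:
    def test_single_identity(self):
        assert mp.product_pvalue([0.37]) == pytest.approx(0.37, rel=1e-12)

    def test_closed_form_two(self):
        got = mp.product_pvalue([0.01, 0.01])
        expect = 1e-4 * (1 + math.log(1e4))
        assert got == pytest.approx(expect, rel=1e-12)
        assert got == pytest.approx(1.0210e-3, abs=5e-7)

    def test_all_ones(self):
        assert mp.product_pvalue([1.0, 1.0, 1.0]) == 1.0

    def test_empty(self):
        assert mp.product_pvalue([]) == 1.0


class TestMotifEvalue:
    def test_single_site_equals_product_pvalue(self, skewed_bg):
        seqs = mp.SequenceSet.from_strings(["ACG"])
        theta = mp.PSPM.uniform(3)
        log10_e = mp.motif_evalue([(0, 0, "+")], theta, seqs, skewed_bg,
                                  model="oops", strand_mode="single")
        chain = mp.product_pvalue(
            [mp.column_pvalue(c, 1, skewed_bg)
             for c in ([1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0])])
        assert log10_e == pytest.approx(math.log10(chain), abs=1e-9)

    def test_doubling_positions_adds_t_log2(self, uniform_bg):
        theta = mp.PSPM.uniform(2)
        seqs1 = mp.SequenceSet.from_strings(["ACGT", "ACGT"])      # m = 3
        seqs2 = mp.SequenceSet.from_strings(["ACGTCAT", "ACGTCAT"])  # m = 6
        sites = [(0, 0, "+"), (1, 0, "+")]
        e1 = mp.motif_evalue(sites, theta, seqs1, uniform_bg,
                             model="zoops", strand_mode="single")
        e2 = mp.motif_evalue(sites, theta, seqs2, uniform_bg,
                             model="zoops", strand_mode="single")
        assert e2 - e1 == pytest.approx(2 * math.log10(2), abs=1e-9)

    def test_hand_chained_three_identical_sites(self, uniform_bg):
        seqs = mp.SequenceSet.from_strings(["GGAAT", "TGGCA", "AGGTC"])
        theta = mp.PSPM.uniform(2)
        sites = [(0, 0, "+"), (1, 1, "+"), (2, 1, "+")]  # all "GG"
        got = mp.motif_evalue(sites, theta, seqs, uniform_bg,
                              model="zoops", strand_mode="single")
        pcol = mp.column_pvalue([0, 0, 3, 0], 3, uniform_bg)
        prod = mp.product_pvalue([pcol, pcol])
        nways = math.comb(3, 3) * 4 ** 3   # C(n,t) * prod strands*m_i
        assert got == pytest.approx(math.log10(prod * nways), abs=1e-9)


class TestSelectSites:
    def test_oops_point_masses(self):
        Z = mp.ZMatrix(np.zeros(2), [
            np.array([[0.0, 1.0, 0.0]]),
            np.array([[0.0, 0.0, 1.0]]),
        ])
        sel = mp.select_sites(Z, "oops")
        assert sel.ranked == [(0, 1, "+"), (1, 2, "+")]
        assert sel.prefixes() == [[(0, 1, "+"), (1, 2, "+")]]

    def test_zoops_prefixes(self):
        Z = mp.ZMatrix(np.array([0.1, 0.2, 0.9]), [
            np.array([[0.9, 0.0]]),
            np.array([[0.0, 0.8]]),
            np.array([[0.1, 0.0]]),
        ])
        sel = mp.select_sites(Z, "zoops")
        assert sel.ranked == [(0, 0, "+"), (1, 1, "+"), (2, 0, "+")]
        assert [len(p) for p in sel.prefixes()] == [2, 3]

    def test_tie_breaking_deterministic(self):
        Z = mp.ZMatrix(np.zeros(2), [
            np.array([[0.5, 0.5]]),
            np.array([[0.5, 0.5]]),
        ])
        sel = mp.select_sites(Z, "zoops")
        assert sel.ranked == [(0, 0, "+"), (1, 0, "+")]


class TestErase:
    def _seqs(self):
        return mp.SequenceSet.from_strings(["ACGTACGTA"])

    def test_hard_erasure(self):
        seqs = self._seqs()
        er = mp.ErasureWeights.ones(seqs)
        w = 3
        zi = np.zeros((1, 7))
        zi[0, 2] = 1.0
        out = mp.erase(er, mp.ZMatrix(np.zeros(1), [zi]), w)
        assert np.allclose(out.u[0][2:5], 0.0)
        assert np.allclose(out.u[0][:2], 1.0)
        assert np.allclose(out.u[0][5:], 1.0)

    def test_zero_z_is_identity(self):
        seqs = self._seqs()
        er = mp.ErasureWeights.ones(seqs)
        out = mp.erase(er, mp.ZMatrix(np.zeros(1), [np.zeros((1, 7))]), 3)
        assert np.array_equal(out.u[0], er.u[0])

    def test_partial_erasure_scales(self):
        seqs = self._seqs()
        er = mp.ErasureWeights.ones(seqs)
        zi = np.zeros((1, 7))
        zi[0, 2] = 0.5
        out = mp.erase(er, mp.ZMatrix(np.zeros(1), [zi]), 3)
        assert np.allclose(out.u[0][2:5], 0.5)

    def test_non_increasing(self, planted_easy):
        seqs, _, _ = planted_easy
        res = mp.discover_motifs(seqs, minw=8, maxw=8, model="oops")[0]
        er = mp.erase(mp.ErasureWeights.ones(seqs), res.zmatrix, 8)
        for u in er.u:
            assert (u <= 1.0 + 1e-12).all() and (u >= -1e-12).all()


class TestDiscover:
    def test_recovers_strong_planted_motif(self, planted_easy):
        seqs, _, motif = planted_easy
        res = mp.discover_motifs(seqs, minw=8, maxw=8, model="oops")[0]
        d = mp.aligned_distance(res.pspm, motif, ic_filter=True)
        assert d.distance < 0.25

    def test_prior_point_mass_pins_sites(self, planted_easy):
        seqs, truth, _ = planted_easy
        psp = mp.make_uniform_psp(seqs, 8)
        for i, j, _ in truth:
            psp.positional[i][:] = 0.0
            psp.positional[i][j] = 1.0
        res = mp.discover_motifs(seqs, psp=psp, minw=8, maxw=8,
                                 model="oops")[0]
        got = {(sid, s, e) for sid, s, e, _ in res.sites}
        want = {(seqs.ids[i], j, j + 8) for i, j, _ in truth}
        assert got == want

    def test_two_disjoint_motifs(self):
        rng = np.random.default_rng(21)
        wa, wb = "GGGGCGCC", "TTATAATA"
        rows = []
        for _ in range(12):
            s = list(rng.choice(list("ACGT"), size=70))
            s[5:13] = list(wa)
            s[40:48] = list(wb)
            rows.append("".join(s))
        seqs = mp.SequenceSet.from_strings(rows)
        res = mp.discover_motifs(seqs, minw=8, maxw=8, model="oops",
                                 nmotifs=2, strand_mode="single")
        assert len(res) == 2
        targets = [mp.subsequence_to_pspm(wa, 1.0),
                   mp.subsequence_to_pspm(wb, 1.0)]
        dists = np.array([[mp.aligned_distance(r.pspm, t).distance
                           for t in targets] for r in res])
        assert dists.min(axis=0).max() < 0.25   # each target matched
        assert dists.argmin(axis=1).tolist() in ([0, 1], [1, 0])

    def test_empty_width_range_errors(self, toy_seqs):
        with pytest.raises(ValueError, match="empty width range"):
            mp.discover_motifs(toy_seqs, minw=8, maxw=7)

    def test_deterministic(self, planted_easy):
        seqs, _, _ = planted_easy
        a = mp.discover_motifs(seqs, minw=8, maxw=8, model="zoops")[0]
        b = mp.discover_motifs(seqs, minw=8, maxw=8, model="zoops")[0]
        assert np.array_equal(a.pspm.matrix, b.pspm.matrix)
        assert a.sites == b.sites and a.log10_evalue == b.log10_evalue


class TestEstimator:
    def test_sklearn_contract(self, planted_easy):
        seqs, _, motif = planted_easy
        est = mp.MotifDiscovery(model="oops", min_width=8, max_width=8)
        params = est.get_params()
        assert params["model"] == "oops"
        est.set_params(n_motifs=1)
        est.fit(seqs)
        assert est.best_motif_ is not None
        assert mp.success(est.best_motif_.pspm, motif)
        X = est.transform(seqs)
        assert X.shape == (len(seqs), 1)
        assert (X > 0).all()

    def test_fit_accepts_plain_strings(self):
        rows = ["ACGTGGGGCGCCAAT" * 2 for _ in range(4)]
        est = mp.MotifDiscovery(model="oops", min_width=6, max_width=6,
                                both_strands=False)
        est.fit(rows)
        assert est.n_sequences_ == 4
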