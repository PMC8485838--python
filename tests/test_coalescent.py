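"""The coalescent engine against analytic expectations and msprime."""

import numpy as np
import pytest

from cpphylo.coalescent import (
    Event,
    Genealogy,
    constant_size_tree,
    fixed_s_patterns,
    hky_rate_matrix,
    hky_site_matrix,
    pairwise_difference_matrix,
    poisson_branch_mutations,
    simulate_genealogy,
)


class TestGenealogy:
    def test_pair_tmrca_matches_haploid_convention(self):
        """E[TMRCA] of a pair in a haploid population of size N is N."""
        rng = np.random.default_rng(1)
        N, reps = 400.0, 4000
        t = np.array([constant_size_tree(2, N, rng).time[2] for _ in range(reps)])
        se = t.std() / np.sqrt(reps)
        assert abs(t.mean() - N) < 3 * se

    def test_total_tree_length_expectation(self):
        """E[total length] = 2 N sum_{i=1}^{n-1} 1/i."""
        rng = np.random.default_rng(2)
        n, N, reps = 12, 100.0, 3000
        a1 = sum(1.0 / i for i in range(1, n))
        tl = np.array([
            constant_size_tree(n, N, rng).total_branch_length() for _ in range(reps)
        ])
        se = tl.std() / np.sqrt(reps)
        assert abs(tl.mean() - 2 * N * a1) < 3 * se

    def test_matches_msprime_tmrca_distribution(self):
        """Mean sample TMRCA agrees with msprime under the same model."""
        import msprime

        rng = np.random.default_rng(3)
        n, N, reps = 8, 1000.0, 1500
        ours = np.array([constant_size_tree(n, N, rng).time.max() for _ in range(reps)])
        theirs = np.array([
            msprime.sim_ancestry(
                samples=n, population_size=N, ploidy=1, random_seed=s,
            ).max_root_time
            for s in range(1, reps + 1)
        ])
        se = np.sqrt(ours.var() / reps + theirs.var() / reps)
        assert abs(ours.mean() - theirs.mean()) < 3 * se

    def test_non_coalescing_configuration_raises(self):
        with pytest.raises(RuntimeError, match="non-coalescing"):
            simulate_genealogy({"a": 2, "b": 2}, {"a": 10.0, "b": 10.0}, [],
                               np.random.default_rng(0))

    def test_merge_event_brings_lineages_together(self):
        rng = np.random.default_rng(4)
        tree = simulate_genealogy(
            {"a": 3, "b": 3}, {"a": 1.0, "b": 1.0, "anc": 1.0},
            [Event("merge", 100.0, "anc", ("a", "b"))], rng,
        )
        assert tree.n_tips == 6
        assert (tree.parent >= 0).sum() == tree.n_nodes - 1
        # cross-population coalescences cannot predate the merge
        member = tree.membership()
        for v in range(tree.n_tips, tree.n_nodes):
            tips = np.flatnonzero(member[:, v])
            pops = {tree.tip_pops[t] for t in tips}
            if len(pops) > 1:
                assert tree.time[v] >= 100.0

    def test_size_event_changes_rate(self):
        # huge size until t=50, then size 1: pair TMRCA concentrates just after 50
        rng = np.random.default_rng(5)
        times = []
        for _ in range(500):
            tree = simulate_genealogy(
                {"a": 2}, {"a": 1e8}, [Event("size", 50.0, "a", size=1.0)], rng)
            times.append(tree.time[2])
        times = np.array(times)
        assert (times > 50).mean() > 0.99
        assert np.median(times) < 53


class TestMutationOverlays:
    def test_watterson_expectation(self):
        """E[S] = theta a1 for a constant-size sample (large L, so the
        finite-sites correction is negligible)."""
        rng = np.random.default_rng(6)
        n, N, L, mu, reps = 10, 500.0, 20000, 2e-7, 2000
        theta = 2 * N * mu * L
        a1 = sum(1.0 / i for i in range(1, n))
        S = np.empty(reps)
        for i in range(reps):
            tree = constant_size_tree(n, N, rng)
            _, codes = hky_site_matrix(tree, L, mu, rng)
            S[i] = (codes != codes[0]).any(axis=0).sum()
        se = S.std() / np.sqrt(reps)
        assert abs(S.mean() - theta * a1) < 3 * se

    def test_rate_matrix_mean_rate_is_mu(self):
        for freqs in ((0.25,) * 4, (0.4, 0.2, 0.1, 0.3)):
            q = hky_rate_matrix(1e-6, kappa=3.0, freqs=freqs)
            away = q.sum(axis=1)
            assert float(np.asarray(freqs) @ away) == pytest.approx(1e-6)

    def test_joint_tip_distribution_matches_matrix_exponential(self):
        """On a fixed two-tip tree the joint tip-base law is
        sum_a pi_a P(t)[a, b1] P(t)[a, b2] with P(t) = expm(Q t)."""
        from scipy.linalg import expm

        rng = np.random.default_rng(7)
        freqs = (0.4, 0.1, 0.2, 0.3)
        kappa = 3.0
        mu, T, L = 1e-3, 3500.0, 60000
        q = hky_rate_matrix(mu, kappa, freqs)
        rates = q.copy()
        np.fill_diagonal(rates, -q.sum(axis=1))
        P = expm(rates * T)
        expected = np.einsum("a,ab,ac->bc", np.asarray(freqs), P, P)

        tree = Genealogy(np.array([2, 2, -1]), np.array([0.0, 0.0, T]), 2, ["p", "p"])
        counts = np.zeros((4, 4))
        pos, codes = hky_site_matrix(tree, L, mu, rng, kappa, freqs,
                                     keep_monomorphic=True)
        for b1, b2 in zip(codes[0], codes[1]):
            counts[b1, b2] += 1
        # sites never hit by a candidate event are not returned; with
        # r_max*2T ~ 10 the loss is negligible
        obs = counts / counts.sum()
        assert np.allclose(obs, expected / expected.sum(), atol=0.01)

    def test_fixed_s_places_exactly_s_mutations(self):
        rng = np.random.default_rng(8)
        tree = constant_size_tree(6, 1.0, rng)
        patterns = fixed_s_patterns(tree, 9, rng)
        assert patterns.shape == (6, 9)
        counts = patterns.sum(axis=0)
        assert ((1 <= counts) & (counts <= 5)).all()  # no fixed or absent mutations

    def test_pairwise_difference_matrix_matches_brute_force(self):
        rng = np.random.default_rng(9)
        tree = constant_size_tree(7, 5.0, rng)
        muts = poisson_branch_mutations(tree, 0.8, rng)
        fast = pairwise_difference_matrix(tree, muts)
        member = tree.membership()
        slow = np.zeros_like(fast)
        for b in range(tree.n_nodes):
            for _ in range(muts[b]):
                inside = member[:, b]
                slow += np.logical_xor.outer(inside, inside)
        assert (fast == slow).all()


class TestDivergenceFst:
    def test_deep_divergence_drives_fst_to_one(self):
        """Two populations separated for >> N generations are fully fixed."""
        from cpphylo.abc_inference import summarize

        rng = np.random.default_rng(10)
        fsts = []
        for _ in range(40):
            tree = simulate_genealogy(
                {"a": 8, "b": 8, "c": 2},
                {"a": 100.0, "b": 100.0, "c": 100.0, "anc": 100.0},
                [Event("merge", 1e5, "anc", ("a", "b", "c"))], rng,
            )
            _, codes = hky_site_matrix(tree, 3000, 1e-6, rng)
            if codes.shape[1] == 0:
                continue
            gidx = np.array([0] * 8 + [1] * 8 + [2] * 2)
            stats = summarize(codes, gidx)
            fsts.append(stats[9 + 1])  # fst_12
        assert np.mean(fsts) > 0.9
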