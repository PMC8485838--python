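"""ABC machinery: priors, summary statistics, model choice, estimation."""

import numpy as np
import pandas as pd
import pytest

from cpphylo.abc_inference import (
    PARAM_NAMES,
    STAT_NAMES,
    PriorSpec,
    build_reference_table,
    draw_priors,
    estimate_parameters,
    model_check_pca,
    model_choice,
    pod_error_rates,
    prior_midpoints,
    scenario_events,
    simulate_dataset,
    summarize,
    summarize_alignment,
)
from cpphylo.alignment import Alignment


class TestPriors:
    def test_draws_within_bounds_and_ordered(self):
        spec = PriorSpec()
        rng = np.random.default_rng(0)
        draws = [draw_priors(spec, 5, rng) for _ in range(2000)]
        for name in ("Na", "N1", "N2", "N3"):
            vals = np.array([d[name] for d in draws])
            assert vals.min() >= spec.size_bounds[0]
            assert vals.max() <= spec.size_bounds[1]
            # empirical extremes approach the bounds
            assert vals.min() < spec.size_bounds[0] + 0.05 * spec.size_bounds[1]
            assert vals.max() > 0.95 * spec.size_bounds[1]
        assert all(d["t2"] >= d["t1"] for d in draws)
        r = np.array([d["r"] for d in draws])
        assert (r >= 0.1).all() and (r <= 0.9).all()

    def test_t1_marginal_matches_brute_force_rejection(self):
        """Under the t2 >= t1 condition the t1 marginal is triangular;
        compare our sampler against an independent rejection sampler."""
        spec = PriorSpec(time_bounds=(0.0, 1.0) if False else (100.0, 100_000.0))
        rng = np.random.default_rng(1)
        ours = np.array([draw_priors(spec, 1, rng)["t1"] for _ in range(4000)])
        brute = np.random.default_rng(2)
        ref = []
        while len(ref) < 4000:
            t1, t2 = brute.uniform(*spec.time_bounds, size=2)
            if t2 >= t1:
                ref.append(t1)
        ref = np.array(ref)
        se = np.sqrt(ours.var() / ours.size + ref.var() / len(ref))
        assert abs(ours.mean() - ref.mean()) < 3 * se
        lo, hi = spec.time_bounds
        analytic_mean = lo + (hi - lo) / 3.0
        assert abs(ours.mean() - analytic_mean) < 4 * ours.std() / np.sqrt(ours.size)

    def test_midpoints_satisfy_ordering(self):
        spec = PriorSpec()
        for sc in range(1, 6):
            m = prior_midpoints(spec, sc)
            assert m["t2"] > m["t1"]

    def test_scenario_validation(self):
        params = dict(Na=100, N1=100, N2=100, N3=100, t1=500.0, t2=400.0, r=0.5)
        with pytest.raises(ValueError, match="t2 >= t1"):
            scenario_events(2, params)
        params.update(t2=600.0, r=1.5)
        with pytest.raises(ValueError, match="admixture"):
            scenario_events(5, params)


class TestSummaries:
    def test_monomorphic_gives_all_zero(self):
        codes = np.empty((10, 0), dtype=np.int8)
        gidx = np.array([0] * 3 + [1] * 5 + [2] * 2)
        assert summarize(codes, gidx).tolist() == [0.0] * len(STAT_NAMES)

    def test_fixed_difference_gives_fst_one(self):
        # groups fixed for different bases at every variable site
        codes = np.zeros((6, 4), dtype=np.int8)
        codes[2:4] = 1
        codes[4:] = 2
        gidx = np.array([0, 0, 1, 1, 2, 2])
        stats = dict(zip(STAT_NAMES, summarize(codes, gidx)))
        assert stats["fst_12"] == 1.0 and stats["fst_13"] == 1.0
        assert stats["S_1"] == 0.0 and stats["kbar_1"] == 0.0

    def test_rarest_base_frequency(self):
        # one group of 10, one site with 9 A : 1 T
        codes = np.zeros((12, 1), dtype=np.int8)
        codes[9] = 3
        gidx = np.array([0] * 10 + [1] * 2)
        stats = dict(zip(STAT_NAMES, summarize(codes, gidx)))
        assert stats["rare_1"] == pytest.approx(0.1)
        assert stats["S_1"] == 1.0

    def test_alignment_summary_agrees_with_code_summary(self):
        seqs = ["AACGT", "AACGT", "TACGT", "TACGA", "CACGA"]
        lineages = ["north", "north", "central", "central", "south"]
        aln = Alignment([f"s{i}" for i in range(5)], seqs)
        via_alignment = summarize_alignment(aln, lineages)
        codes = np.array([[0, 3], [0, 3], [3, 3], [3, 0], [1, 0]], dtype=np.int8)
        gidx = np.array([0, 0, 1, 1, 2])
        assert np.allclose(via_alignment, summarize(codes, gidx))


class TestReferenceTable:
    def test_reproducible_given_seed(self):
        a = build_reference_table(5, seed=11, scenarios=(1, 3))
        b = build_reference_table(5, seed=11, scenarios=(1, 3))
        pd.testing.assert_frame_equal(a, b)

    def test_scenario_column_and_chunk_reuse(self, tmp_path):
        out = tmp_path / "table.tsv"
        a = build_reference_table(4, seed=3, scenarios=(2, 5), out_path=out)
        assert sorted(a["scenario"].unique()) == [2, 5]
        assert (a["scenario"] == 2).sum() == 4
        # rerun reuses the per-scenario chunks byte-identically
        chunk = (tmp_path / "table.tsv.scenario2.tsv").read_bytes()
        b = build_reference_table(4, seed=3, scenarios=(2, 5), out_path=out)
        assert (tmp_path / "table.tsv.scenario2.tsv").read_bytes() == chunk
        pd.testing.assert_frame_equal(a, b)

    def test_scenario5_draws_admixture_rate(self, tiny_reference_table):
        t = tiny_reference_table
        assert t.loc[t.scenario == 5, "r"].notna().all()
        assert t.loc[t.scenario != 5, "r"].isna().all()


def _gaussian_table(rng, separation=6.0, n=300, scenarios=(1, 2, 3)):
    """Handmade table with well-separated per-scenario summary clouds."""
    frames = []
    for k, sc in enumerate(scenarios):
        stats = rng.normal(loc=k * separation, scale=1.0, size=(n, len(STAT_NAMES)))
        block = pd.DataFrame(stats, columns=list(STAT_NAMES))
        for p in PARAM_NAMES:
            block[p] = rng.uniform(1, 2, size=n)
        block.insert(0, "scenario", sc)
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


class TestModelChoice:
    def test_posterior_sums_to_one_and_picks_generating_scenario(self, rng):
        table = _gaussian_table(rng)
        observed = np.full(len(STAT_NAMES), 6.0)  # scenario 2's cloud centre
        res = model_choice(observed, table, tolerance=0.05, seed=0, n_boot_ci=20)
        assert res.posterior.sum() == pytest.approx(1.0, abs=1e-6)
        assert res.chosen == 2
        assert res.posterior[2] > 0.9
        assert (res.ci_low <= res.posterior + 1e-9).all()
        assert (res.posterior <= res.ci_high + 1e-9).all()

    def test_invariant_to_affine_rescaling_of_a_statistic(self, rng):
        table = _gaussian_table(rng)
        observed = np.full(len(STAT_NAMES), 6.0)
        base = model_choice(observed, table, tolerance=0.05, seed=0, n_boot_ci=0)
        scaled = table.copy()
        scaled[STAT_NAMES[4]] = scaled[STAT_NAMES[4]] * 37.0 - 11.0
        obs2 = observed.copy()
        obs2[4] = obs2[4] * 37.0 - 11.0
        res = model_choice(obs2, scaled, tolerance=0.05, seed=0, n_boot_ci=0)
        assert np.allclose(res.posterior, base.posterior, atol=1e-6)

    def test_identical_scenarios_share_posterior_mass(self, rng):
        # two scenarios drawn from the same cloud are indistinguishable
        frames = []
        for sc in (1, 2):
            stats = rng.normal(size=(400, len(STAT_NAMES)))
            block = pd.DataFrame(stats, columns=list(STAT_NAMES))
            for p in PARAM_NAMES:
                block[p] = 1.0
            block.insert(0, "scenario", sc)
            frames.append(block)
        table = pd.concat(frames, ignore_index=True)
        res = model_choice(np.zeros(len(STAT_NAMES)), table, tolerance=0.1,
                           seed=1, n_boot_ci=40)
        assert abs(res.posterior[1] - res.posterior[2]) < 0.2
        assert abs(res.rejection[1] - res.rejection[2]) < 0.2


class TestPodErrors:
    def test_rates_are_valid_and_separable_case_is_learned(self, tiny_reference_table):
        rates = pod_error_rates(tiny_reference_table, n_pods=4, seed=5,
                                scenarios=(1, 2, 3, 4, 5))
        assert ((rates["type_I"] >= 0) & (rates["type_I"] <= 1)).all()
        assert ((rates["type_II"] >= 0) & (rates["type_II"] <= 1)).all()
        assigned = rates[[c for c in rates.columns if c.startswith("assigned_")]]
        assert np.allclose(assigned.sum(axis=1), 1.0)


class TestEstimateParameters:
    def test_constant_statistics_make_adjustment_an_identity(self, rng):
        n = 60
        block = pd.DataFrame(
            np.ones((n, len(STAT_NAMES))), columns=list(STAT_NAMES)
        )
        for p in PARAM_NAMES:
            block[p] = rng.uniform(200, 1000, size=n)  # inside the prior support
        block.insert(0, "scenario", 2)
        observed = np.ones(len(STAT_NAMES))
        res = estimate_parameters(observed, block, scenario=2, tolerance=0.5)
        kept = res.adjusted["t1"].to_numpy()
        assert np.isin(np.round(kept, 6), np.round(block["t1"].to_numpy(), 6)).all()

    def test_times_reported_in_generations_and_years(self, tiny_reference_table):
        obs = tiny_reference_table[list(STAT_NAMES)].iloc[0].to_numpy()
        res = estimate_parameters(obs, tiny_reference_table, scenario=1)
        assert "t2_years" in res.summary.index
        assert res.summary.loc["t2_years", "median"] == pytest.approx(
            10.0 * res.summary.loc["t2", "median"]
        )
        assert (res.summary["q2.5"] <= res.summary["median"]).all()
        assert (res.summary["median"] <= res.summary["q97.5"]).all()

    def test_recovery_coverage_at_reduced_scale(self, tiny_reference_table):
        """True t2 falls inside its 95% credible interval for most
        pseudo-observed datasets (reduced-scale coverage check)."""
        from cpphylo.abc_inference import _substream

        spec = PriorSpec()
        hits = 0
        reps = 12
        for i in range(reps):
            rng = _substream(77, 2, i)
            params = draw_priors(spec, 2, rng)
            _, codes, gidx = simulate_dataset(2, params, rng)
            obs = summarize(codes, gidx)
            res = estimate_parameters(obs, tiny_reference_table, scenario=2,
                                      tolerance=0.1)
            lo, hi = res.summary.loc["t2", ["q2.5", "q97.5"]]
            hits += lo <= params["t2"] <= hi
        assert hits >= int(0.75 * reps)


class TestModelCheckPca:
    def test_observed_projects_into_simulation_cloud(self, tiny_reference_table):
        obs = tiny_reference_table[list(STAT_NAMES)].iloc[10].to_numpy()
        coords = model_check_pca(obs, tiny_reference_table, n_sample=200, seed=3)
        obs_row = coords[coords["scenario"] == "observed"]
        sims = coords[coords["scenario"] != "observed"]
        assert len(obs_row) == 1
        assert sims["pc1"].min() <= obs_row["pc1"].iloc[0] <= sims["pc1"].max()
        again = model_check_pca(obs, tiny_reference_table, n_sample=200, seed=3)
        pd.testing.assert_frame_equal(coords, again)
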