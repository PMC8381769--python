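"""ABC machinery: summary vectors, rejection, model choice, adjustment."""

import numpy as np
import pandas as pd
import pytest

from vineflow.coalescent import simulate_dataset
from vineflow.inference import (
    ReferenceTable,
    adjust_parameters,
    build_reference_table,
    confusion_analysis,
    model_check,
    model_choice,
    reject,
    select_best_scenario,
    stat_names,
    summary_vector,
)
from vineflow.scenarios import (
    DivergenceEvent,
    Prior,
    PriorSpec,
    Scenario,
    point_priors,
    separated_point_values,
    study_scenarios,
)

from conftest import make_matrix


def h1():
    return study_scenarios()["hypothesis_1"]


def small_table(n_per=150, n_loci=60, n_dip=8, seed=0, scens=None):
    scens = scens or h1()
    priors = {s.id: point_priors(s, separated_point_values(s)) for s in scens}
    pops = scens[0].populations
    return build_reference_table(
        scens, priors, {p: n_dip for p in pops}, n_loci, n_per, seed
    )


# ---------------------------------------------------------------------------
# summary vector
# ---------------------------------------------------------------------------


class TestSummaryVector:
    def test_three_populations_give_nine_statistics(self):
        s = h1()[0]
        g = simulate_dataset(s, separated_point_values(s),
                             {p: 6 for p in s.populations}, 40, 1)
        vec = summary_vector(g, s.populations)
        assert len(vec) == 9
        assert len(stat_names(s.populations)) == 9

    def test_four_populations_give_sixteen(self):
        assert len(stat_names(["A", "B", "C", "D"])) == 16

    def test_identical_populations_have_zero_distances(self):
        rng = np.random.default_rng(2)
        block = rng.integers(0, 3, size=(6, 50)).astype(np.int8)
        g = make_matrix(
            np.vstack([block, block, block]),
            pops=["A"] * 6 + ["B"] * 6 + ["C"] * 6,
        )
        vec = summary_vector(g, ["A", "B", "C"])
        he, fst, nei = vec[:3], vec[3:6], vec[6:9]
        assert np.allclose(he, he[0])
        # WC84 on literally duplicated samples is slightly negative, not 0
        assert np.all((fst > -0.2) & (fst <= 0.0))
        assert np.allclose(nei, 0.0, atol=1e-12)

    def test_matches_standalone_statistics(self):
        # the vector's fast single-pass path must equal the per-statistic
        # reference functions
        from vineflow.popgen import gene_diversity, nei_distance, pairwise_fst

        s = h1()[0]
        g = simulate_dataset(s, separated_point_values(s),
                             {p: 7 for p in s.populations}, 80, 5)
        pops = s.populations
        vec = summary_vector(g, pops)
        pairs = [(pops[i], pops[j]) for i in range(3) for j in range(i + 1, 3)]
        expect = [gene_diversity(g, p) for p in pops]
        expect += [pairwise_fst(g, a, b) for a, b in pairs]
        expect += [nei_distance(g, a, b) for a, b in pairs]
        assert np.allclose(vec, expect)

    def test_order_follows_population_list(self):
        names = stat_names(["X", "Y", "Z"])
        assert names[:3] == ["He_X", "He_Y", "He_Z"]
        assert names[3:6] == ["Fst_X|Y", "Fst_X|Z", "Fst_Y|Z"]
        assert names[6:] == ["NeiD_X|Y", "NeiD_X|Z", "NeiD_Y|Z"]


# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------


class TestReferenceTable:
    def test_row_counts_per_scenario(self):
        ref = small_table(n_per=30, n_loci=30, n_dip=5)
        assert ref.n_rows == 90
        for sid in ("S1", "S2", "S3"):
            assert (ref.scenario_ids == sid).sum() == 30

    def test_reproducible_by_seed(self):
        a = small_table(n_per=10, n_loci=20, n_dip=5, seed=5)
        b = small_table(n_per=10, n_loci=20, n_dip=5, seed=5)
        assert np.array_equal(a.stats, b.stats)
        assert a.params.equals(b.params)

    def test_statistic_spread_shrinks_with_loci(self):
        # point priors: spread is Monte-Carlo noise, variance ~ 1/n_loci
        s = h1()[0]
        priors = {s.id: point_priors(s, separated_point_values(s))}
        pops = s.populations
        v = {}
        for n_loci in (100, 400):
            ref = build_reference_table(
                [s], priors, {p: 8 for p in pops}, n_loci, 120, seed=3
            )
            v[n_loci] = ref.stats.var(axis=0).mean()
        assert v[100] / v[400] == pytest.approx(4.0, rel=0.5)


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------


class TestRejection:
    def test_exact_row_retained_at_distance_zero(self):
        ref = small_table(n_per=40, n_loci=30, n_dip=5)
        observed = ref.stats[17].copy()
        idx, dist = reject(ref, observed, tolerance=0.05)
        assert 17 in idx
        assert dist[17] == pytest.approx(0.0)

    def test_retained_count(self):
        ref = small_table(n_per=100, n_loci=20, n_dip=5)
        idx, _ = reject(ref, ref.stats.mean(axis=0), tolerance=0.01)
        assert len(idx) == int(np.ceil(0.01 * 300))

    def test_matches_brute_force_sort(self):
        ref = small_table(n_per=60, n_loci=25, n_dip=5)
        observed = ref.stats[3] * 1.05
        idx, dist = reject(ref, observed, tolerance=0.1)
        # brute force: standardize, full stable sort, take head
        z = (ref.stats - ref.stats.mean(0)) / ref.stats.std(0)
        zo = (observed - ref.stats.mean(0)) / ref.stats.std(0)
        brute = np.sqrt(((z - zo) ** 2).sum(axis=1))
        expect = np.argsort(brute, kind="stable")[: len(idx)]
        assert np.array_equal(idx, expect)

    def test_invalid_tolerance(self):
        ref = small_table(n_per=10, n_loci=20, n_dip=5)
        with pytest.raises(ValueError):
            reject(ref, ref.stats[0], tolerance=0.0)


# ---------------------------------------------------------------------------
# model choice
# ---------------------------------------------------------------------------


class TestModelChoice:
    def test_probabilities_sum_to_hundred_and_ci_contains_point(self):
        ref = small_table(n_per=120, n_loci=40, n_dip=6)
        observed = ref.stats[10]
        res = model_choice(ref, observed, tolerance=0.05, bootstrap_B=40, seed=1)
        assert sum(res.pp.values()) == pytest.approx(100.0, abs=0.1)
        for sid in res.scenario_ids:
            lo, hi = res.ci[sid]
            assert 0.0 <= lo <= res.pp[sid] <= hi <= 100.0

    def test_single_scenario_retained_dominates(self):
        # observed far in the direction of S3's signature
        ref = small_table(n_per=150, n_loci=50, n_dip=6)
        mask = ref.scenario_ids == "S3"
        observed = ref.stats[mask].mean(axis=0)
        res = model_choice(ref, observed, tolerance=0.01, bootstrap_B=0)
        if set(ref.scenario_ids[res.retained_indices]) == {"S3"}:
            assert res.pp["S3"] > 99.0
        assert res.best == "S3"

    def test_indistinguishable_scenarios_near_fifty_fifty(self):
        # two scenario ids over the *same* generative model: Pp ~ 50/50
        base = h1()[0]
        twin = Scenario(
            id="S1b", populations=base.populations,
            events=base.events, ne_params=base.ne_params,
        )
        scens = [base, twin]
        vals = separated_point_values(base)
        priors = {s.id: point_priors(s, vals) for s in scens}
        pops = base.populations
        ref = build_reference_table(
            scens, priors, {p: 6 for p in pops}, 50, 700, seed=55
        )
        devs = []
        for rep in range(12):
            pod = simulate_dataset(base, vals, {p: 6 for p in pops}, 50,
                                   9000 + rep)
            res = model_choice(ref, summary_vector(pod, pops),
                               tolerance=0.5, bootstrap_B=0)
            devs.append(abs(res.pp["S1"] - 50.0))
        assert np.mean(devs) < 10.0

    def test_affine_rescaling_of_statistics_changes_nothing(self):
        ref = small_table(n_per=100, n_loci=30, n_dip=5)
        observed = ref.stats[42]
        res1 = model_choice(ref, observed, tolerance=0.05, bootstrap_B=0)
        scaled = ReferenceTable(
            scenario_ids=ref.scenario_ids,
            params=ref.params,
            stats=ref.stats * 37.0 + 5.0,
            stat_names=ref.stat_names,
            populations=ref.populations,
        )
        res2 = model_choice(scaled, observed * 37.0 + 5.0,
                            tolerance=0.05, bootstrap_B=0)
        for sid in res1.scenario_ids:
            assert res1.pp[sid] == pytest.approx(res2.pp[sid], abs=1e-6)


# ---------------------------------------------------------------------------
# selection rule
# ---------------------------------------------------------------------------


class TestSelectBestScenario:
    def test_highest_pp_wins(self):
        res = select_best_scenario(
            {
                "S1": {"pp": 74.0, "n_outlying": 3},
                "S2": {"pp": 51.0, "n_outlying": 6},
                "S3": {"pp": 43.0, "n_outlying": 5},
            }
        )
        assert res.selected == "S1"
        assert res.selected_pp == 74.0
        assert res.winner_minimizes_outliers is True

    def test_pp_tie_broken_by_outliers(self):
        res = select_best_scenario(
            {"A": {"pp": 60.0, "n_outlying": 5}, "B": {"pp": 60.0, "n_outlying": 2}}
        )
        assert res.selected == "B"

    def test_ci_overlap_flagged(self):
        res = select_best_scenario(
            {
                "A": {"pp": 60.0, "ci": (50, 70), "n_outlying": 1},
                "B": {"pp": 55.0, "ci": (45, 65), "n_outlying": 2},
            }
        )
        assert res.ci_overlaps_runner_up is True
        res = select_best_scenario(
            {
                "A": {"pp": 80.0, "ci": (75, 85), "n_outlying": 1},
                "B": {"pp": 40.0, "ci": (35, 45), "n_outlying": 2},
            }
        )
        assert res.ci_overlaps_runner_up is False


# ---------------------------------------------------------------------------
# parameter adjustment
# ---------------------------------------------------------------------------


def _synthetic_table(n=200, seed=0):
    """Reference table whose parameter is an exact linear map of one stat."""
    rng = np.random.default_rng(seed)
    stats = rng.normal(size=(n, 3))
    t = 2.0 * stats[:, 0] - 1.0 * stats[:, 1]  # exact linear in stats
    a, b = 10.0, 500.0
    theta = a + (b - a) / (1.0 + np.exp(-t))
    params = pd.DataFrame({"t1": theta, "N_A": np.full(n, 1000.0)})
    return ReferenceTable(
        scenario_ids=np.array(["S"] * n),
        params=params,
        stats=stats,
        stat_names=["x", "y", "z"],
        populations=["A"],
    ), (a, b)


class TestAdjustParameters:
    scenario = Scenario(
        id="S", populations=["A", "B"],
        events=[DivergenceEvent("t1", derived="B", source="A")],
        ne_params={"A": "N_A", "B": "N_A"},
    )

    def priors(self, a=10.0, b=500.0):
        return PriorSpec(
            priors={"t1": Prior("uniform", a, b),
                    "N_A": Prior("uniform", 1000.0, 1000.0)},
        )

    def test_adjusted_values_inside_prior_bounds(self):
        ref, (a, b) = _synthetic_table(seed=1)
        observed = np.array([0.5, -0.3, 0.1])
        post = adjust_parameters(ref, observed, self.scenario, self.priors(),
                                 tolerance=0.5)
        assert ((post["t1"] > a) & (post["t1"] < b)).all()

    def test_exact_linear_relation_collapses_posterior(self):
        ref, (a, b) = _synthetic_table(seed=2)
        observed = np.array([0.5, -0.3, 0.1])
        post = adjust_parameters(ref, observed, self.scenario, self.priors(),
                                 tolerance=0.5)
        # the regression is exact in logit space, so all draws coincide with
        # the value implied at the observed statistics
        z = ref.standardize(observed)[0]
        zc = z * ref.scale[ref.active] + ref.center[ref.active]  # raw obs
        t_implied = 2.0 * observed[0] - 1.0 * observed[1]
        expect = a + (b - a) / (1.0 + np.exp(-t_implied))
        assert post["t1"].std() < 1e-6
        assert post["t1"].iloc[0] == pytest.approx(expect, rel=1e-6)

    def test_row_at_observed_point_unchanged(self):
        ref, _ = _synthetic_table(seed=3)
        observed = ref.stats[7].copy()
        post = adjust_parameters(ref, observed, self.scenario, self.priors(),
                                 tolerance=0.5)
        idx, _ = reject(ref, observed, tolerance=0.5)
        pos = int(np.flatnonzero(idx == 7)[0])
        assert post["t1"].iloc[pos] == pytest.approx(
            ref.params["t1"].iloc[7], rel=1e-6
        )

    def test_point_prior_passes_through(self):
        ref, _ = _synthetic_table(seed=4)
        post = adjust_parameters(ref, ref.stats[0], self.scenario,
                                 self.priors(), tolerance=0.5)
        assert (post["N_A"] == 1000.0).all()

    def test_too_few_rows_raises(self):
        ref, _ = _synthetic_table(n=30, seed=5)
        with pytest.raises(ValueError, match="retained rows"):
            adjust_parameters(ref, ref.stats[0], self.scenario, self.priors(),
                              tolerance=0.05)


# ---------------------------------------------------------------------------
# confusion analysis + model check
# ---------------------------------------------------------------------------


class TestConfusion:
    def test_accounting_identity_and_bounds(self):
        scens = h1()
        priors = {s.id: point_priors(s, separated_point_values(s)) for s in scens}
        pops = scens[0].populations
        rep = confusion_analysis(
            scens, priors, {p: 6 for p in pops}, 50, n_pods_per_scenario=4,
            seed=2, n_sims_per_scenario=100,
        )
        for s in rep.scenario_ids:
            assert 0 <= rep.type_i[s] <= 1
            assert 0 <= rep.type_ii[s] <= 1
        assert rep.performance == pytest.approx(
            1.0 - np.mean([rep.type_i[s] for s in rep.scenario_ids])
        )
        assert rep.confusion.to_numpy().sum() == 12


class TestModelCheck:
    def _setup(self, seed):
        s = h1()[0]
        vals = separated_point_values(s)
        pops = s.populations
        posterior = pd.DataFrame([vals] * 10)
        return s, vals, pops, posterior

    def test_calibrated_when_observed_from_same_model(self):
        s, vals, pops, posterior = self._setup(0)
        counts = []
        for rep in range(12):
            obs_g = simulate_dataset(s, vals, {p: 8 for p in pops}, 60,
                                     500 + rep)
            report = model_check(
                s, posterior, {p: 8 for p in pops}, 60, n_ppc=120,
                observed=summary_vector(obs_g, pops), seed=rep,
            )
            counts.append(report.n_outlying_05)
            assert 0 <= report.n_outlying_05 <= 9
            assert report.n_outlying_01 <= report.n_outlying_05 + 9
        assert np.mean(counts) < 1.5

    def test_gross_misfit_detected(self):
        s, vals, pops, posterior = self._setup(1)
        # observed generated under a very different model: 10x larger Ne
        far = {k: (10_000.0 if k.startswith("N_") else v)
               for k, v in vals.items()}
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            obs_g = simulate_dataset(s, far, {p: 8 for p in pops}, 60,
                                     900 + rep)
            report = model_check(
                s, posterior, {p: 8 for p in pops}, 60, n_ppc=120,
                observed=summary_vector(obs_g, pops), seed=rep,
            )
            if report.n_outlying_05 >= 4:
                hits += 1
        assert hits >= 0.8 * n_rep

    def test_pca_projection_shapes(self):
        s, vals, pops, posterior = self._setup(2)
        ref = small_table(n_per=40, n_loci=40, n_dip=8)
        obs_g = simulate_dataset(s, vals, {p: 8 for p in pops}, 40, 77)
        report = model_check(
            s, posterior, {p: 8 for p in pops}, 40, n_ppc=30,
            observed=summary_vector(obs_g, pops), seed=3, ref=ref,
        )
        assert report.pca_reference.shape == (ref.n_rows, 2)
        assert report.pca_predictive.shape == (30, 2)
        assert report.pca_observed.shape == (1, 2)
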