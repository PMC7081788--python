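"""Negative-binomial fitting, AICc selection, and permutation inference."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from plexrank.core_io import AttributeTable
from plexrank.inference import (
    FitResult,
    ModelSpec,
    aicc,
    aicc_candidate_set,
    build_model_frame,
    fit_nb_model,
    permutation_test,
    permute_attributes,
)
from tests.conftest import small_attribute_frame


def make_table(n, n_groups=1, seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    for g in range(n_groups):
        df = small_attribute_frame(n // n_groups, group=f"G{g}", seed=seed + g)
        df["node"] = [f"g{g}_n{i}" for i in range(len(df))]
        df["dominance_rank"] = rng.uniform(0, 1, len(df))
        frames.append(df)
    return AttributeTable(pd.concat(frames, ignore_index=True))


def nb_draw(rng, mu, alpha):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


class TestFitNbModel:
    def test_parameter_recovery(self):
        """Known coefficients at n=700, dispersion 1.5: estimates within 3 SE."""
        rng = np.random.default_rng(7)
        table = make_table(700, seed=7)
        df = table.df
        truth = {"Intercept": 2.0, "rank": 1.2, "sex[T.male]": -0.6}
        male = (df["sex"] == "male").astype(float).to_numpy()
        mu = np.exp(truth["Intercept"] + truth["rank"] * df["dominance_rank"].to_numpy()
                    + truth["sex[T.male]"] * male)
        y = nb_draw(rng, mu, alpha=1.5)
        outcome = dict(zip(df["node"], (int(v) for v in y)))
        fit = fit_nb_model(ModelSpec("rank + sex", group_effect="none"), outcome, table)
        for term, true_val in truth.items():
            assert abs(fit.params[term] - true_val) <= 3 * fit.se[term], term
        assert fit.alpha == pytest.approx(1.5, abs=0.5)

    def test_matches_statsmodels_oracle(self):
        """Dual route: plain fit agrees with statsmodels NegativeBinomial MLE."""
        rng = np.random.default_rng(3)
        table = make_table(400, seed=3)
        df = table.df
        mu = np.exp(1.5 + 0.8 * df["dominance_rank"].to_numpy())
        y = nb_draw(rng, mu, alpha=0.8)
        outcome = dict(zip(df["node"], (int(v) for v in y)))
        fit = fit_nb_model(ModelSpec("rank", group_effect="none"), outcome, table)

        x = np.column_stack([np.ones(len(df)), df["dominance_rank"].to_numpy()])
        oracle = sm.NegativeBinomial(y, x).fit(disp=0)
        assert fit.params["Intercept"] == pytest.approx(oracle.params[0], abs=2e-3)
        assert fit.params["rank"] == pytest.approx(oracle.params[1], abs=2e-3)
        assert fit.alpha == pytest.approx(oracle.params[2], abs=2e-2)
        assert fit.llf == pytest.approx(oracle.llf, abs=1e-2)

    def test_noise_covariate_ci_coverage(self):
        """Wald CI for a pure-noise covariate covers 0 in >= 90% of sims."""
        rng = np.random.default_rng(11)
        covered = 0
        n_sims = 100
        for s in range(n_sims):
            table = make_table(200, seed=1000 + s)
            df = table.df
            y = nb_draw(rng, np.full(len(df), np.exp(2.0)), alpha=1.0)
            outcome = dict(zip(df["node"], (int(v) for v in y)))
            fit = fit_nb_model(ModelSpec("rank", group_effect="none"), outcome, table)
            beta, se = fit.params["rank"], fit.se["rank"]
            if abs(beta) <= 1.96 * se:
                covered += 1
        assert covered >= 90

    def test_random_intercept_recovers_group_spread(self):
        rng = np.random.default_rng(5)
        table = make_table(600, n_groups=6, seed=5)
        df = table.df
        offsets = {g: o for g, o in zip(sorted(df["group"].unique()),
                                        rng.normal(0, 0.6, 6))}
        mu = np.exp(1.8 + 1.0 * df["dominance_rank"].to_numpy()
                    + df["group"].map(offsets).to_numpy())
        y = nb_draw(rng, mu, alpha=0.7)
        outcome = dict(zip(df["node"], (int(v) for v in y)))
        fit = fit_nb_model(ModelSpec("rank", group_effect="random"), outcome, table)
        assert fit.method == "random_intercept"
        assert fit.sigma_group == pytest.approx(np.std(list(offsets.values())), abs=0.45)
        assert fit.params["rank"] == pytest.approx(1.0, abs=3 * fit.se["rank"] + 0.15)

    def test_single_group_random_degrades_to_plain(self, attribute_table):
        rng = np.random.default_rng(0)
        y = nb_draw(rng, np.full(12, 5.0), alpha=0.5)
        outcome = dict(zip(attribute_table.nodes, (int(v) for v in y)))
        fit = fit_nb_model(ModelSpec("rank", group_effect="random"), outcome, attribute_table)
        assert fit.method == "plain"

    def test_negative_outcome_rejected(self, attribute_table):
        outcome = {n: -1 for n in attribute_table.nodes}
        with pytest.raises(Exception):
            fit_nb_model(ModelSpec("rank", group_effect="none"), outcome, attribute_table)


def fake_fit(name, llf, k, n=620):
    return FitResult(
        spec=ModelSpec("rank", name=name), params={}, se={}, alpha=1.0,
        sigma_group=None, llf=llf, k_params=k, n_obs=n,
        aicc=aicc(llf, k, n), converged=True, method="plain",
    )


def fit_with_aicc(name, target_aicc, k=5, n=620):
    # invert the AICc formula to hit the requested value exactly
    llf = (2 * k + 2 * k * (k + 1) / (n - k - 1) - target_aicc) / 2.0
    return fake_fit(name, llf, k, n)


class TestAiccSelection:
    def test_aicc_formula(self):
        # AICc = AIC + 2K(K+1)/(n-K-1)
        assert aicc(llf=-100.0, k=3, n=50) == pytest.approx(206.0 + 24 / 46)

    def test_correction_vanishes_for_large_n(self):
        k, n = 5, 10**6
        assert aicc(0.0, k, n) - (2 * k) < 1e-3

    def test_delta_2_7_weights(self):
        fits = [fit_with_aicc("m1", 3635.3), fit_with_aicc("m2", 3635.3 + 2.7)]
        candidates, weights = aicc_candidate_set(fits)
        assert len(candidates) == 2
        assert weights["m1"] == pytest.approx(0.795, abs=0.005)
        assert weights["m2"] == pytest.approx(0.205, abs=0.005)

    def test_single_model_weight_one(self):
        _, weights = aicc_candidate_set([fit_with_aicc("only", 100.0)])
        assert weights["only"] == pytest.approx(1.0)

    def test_delta_15_6_excluded(self):
        fits = [fit_with_aicc("best", 1670.6), fit_with_aicc("worse", 1670.6 + 15.6)]
        candidates, weights = aicc_candidate_set(fits)
        assert [f.spec.name for f in candidates] == ["best"]
        assert weights == {"best": pytest.approx(1.0)}

    def test_weights_sum_to_one(self, rng):
        fits = [fit_with_aicc(f"m{i}", 500 + float(d))
                for i, d in enumerate(rng.uniform(0, 10, 8))]
        _, weights = aicc_candidate_set(fits)
        assert sum(weights.values()) == pytest.approx(1.0)

    def test_differing_n_rejected(self):
        with pytest.raises(ValueError, match="differing n"):
            aicc_candidate_set([fake_fit("a", -10, 3, n=100), fake_fit("b", -10, 3, n=200)])


class TestPermuteAttributes:
    def test_multiset_conserved_per_group(self):
        table = make_table(40, n_groups=2, seed=1)
        permuted = permute_attributes(table, seed=42)
        for g in table.groups:
            orig = table.for_group(g).df
            perm = permuted.for_group(g).df
            cols = ["sex", "age", "dominance_rank", "dominance_certainty",
                    "matriline_size", "rearing"]
            orig_tuples = sorted(map(tuple, orig[cols].to_numpy().tolist()))
            perm_tuples = sorted(map(tuple, perm[cols].to_numpy().tolist()))
            assert orig_tuples == perm_tuples
            # nodes and groups stay put
            assert list(orig["node"]) == list(perm["node"])

    def test_rows_move_jointly(self):
        table = make_table(30, seed=2)
        permuted = permute_attributes(table, seed=7)
        cols = ["sex", "age", "dominance_rank", "dominance_certainty",
                "matriline_size", "rearing"]
        orig_rows = {tuple(r) for r in table.df[cols].to_numpy().tolist()}
        perm_rows = {tuple(r) for r in permuted.df[cols].to_numpy().tolist()}
        assert orig_rows == perm_rows  # no tuple was broken apart

    def test_deterministic_under_seed(self):
        table = make_table(25, seed=3)
        a = permute_attributes(table, seed=99).df
        b = permute_attributes(table, seed=99).df
        pd.testing.assert_frame_equal(a, b)

    def test_uniformity_chi2(self):
        """Each node receives each attribute bundle about uniformly."""
        from scipy import stats

        n = 8
        table = make_table(n, seed=4)
        # tag bundles by their (unique) age value
        ages = table.df["age"].to_numpy()
        assert len(set(ages)) == n
        age_index = {a: i for i, a in enumerate(ages)}
        counts = np.zeros((n, n))
        reps = 1000
        for s in range(reps):
            perm = permute_attributes(table, seed=s)
            for node_pos, a in enumerate(perm.df["age"]):
                counts[node_pos, age_index[a]] += 1
        expected = reps / n
        chi2 = ((counts - expected) ** 2 / expected).sum()
        dof = n * n - n  # rows sum to reps
        assert stats.chi2.sf(chi2, dof) > 0.01


class TestPermutationTest:
    def outcome_and_table(self, n=120, effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        table = make_table(n, seed=seed)
        df = table.df
        mu = np.exp(1.5 + effect * df["dominance_rank"].to_numpy())
        y = nb_draw(rng, mu, alpha=0.8)
        return dict(zip(df["node"], (int(v) for v in y))), table

    def test_null_coefficient_p_near_one(self):
        outcome, table = self.outcome_and_table(effect=0.0, seed=21)
        res = permutation_test(ModelSpec("rank", group_effect="none"), outcome, table,
                               replicates=199, seed=5)
        assert res.p_value["rank"] > 0.1
        assert not res.tail_significant["rank"]

    def test_planted_effect_detected(self):
        outcome, table = self.outcome_and_table(effect=2.5, seed=22)
        res = permutation_test(ModelSpec("rank", group_effect="none"), outcome, table,
                               replicates=199, seed=5)
        assert res.p_value["rank"] == pytest.approx(2 / 200)
        assert res.tail_significant["rank"]

    def test_p_values_in_unit_interval(self):
        outcome, table = self.outcome_and_table(effect=1.0, seed=23)
        res = permutation_test(ModelSpec("rank + sex", group_effect="none"),
                               outcome, table, replicates=99, seed=1)
        for term, p in res.p_value.items():
            assert 0 < p <= 1, term
        assert res.n_replicates == 99
        assert all(len(v) == 99 - res.n_failed for v in res.null.values())

    def test_deterministic_under_seed(self):
        outcome, table = self.outcome_and_table(effect=1.0, seed=24)
        spec = ModelSpec("rank", group_effect="none")
        a = permutation_test(spec, outcome, table, replicates=50, seed=9)
        b = permutation_test(spec, outcome, table, replicates=50, seed=9)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.null["rank"], b.null["rank"])

    def test_invariant_to_node_relabeling(self):
        outcome, table = self.outcome_and_table(effect=1.5, seed=25)
        spec = ModelSpec("rank", group_effect="none")
        res_orig = permutation_test(spec, outcome, table, replicates=60, seed=3)

        relabel = {n: f"zz_{n}" for n in table.nodes}  # monotone prefix map
        df = table.df.copy()
        df["node"] = df["node"].map(relabel)
        table2 = table.with_rows(df)
        outcome2 = {relabel[n]: v for n, v in outcome.items()}
        res_new = permutation_test(spec, outcome2, table2, replicates=60, seed=3)
        assert res_new.p_value["rank"] == res_orig.p_value["rank"]

    def test_observed_fit_reused(self):
        outcome, table = self.outcome_and_table(effect=1.0, seed=26)
        spec = ModelSpec("rank", group_effect="none")
        fit = fit_nb_model(spec, outcome, table)
        res = permutation_test(spec, outcome, table, replicates=30, seed=2,
                               observed_fit=fit)
        assert res.observed["rank"] == fit.params["rank"]


def test_build_model_frame_baselines(attribute_table):
    outcome = {n: 1 for n in attribute_table.nodes}
    frame = build_model_frame(outcome, attribute_table)
    assert frame["sex"].cat.categories[0] == "female"
    assert frame["rearing"].cat.categories[0] == "mother"
    assert list(frame["msc"].cat.categories) == ["1-5", "6-10", "11+"]
    assert (frame["y"] == 1).all()
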