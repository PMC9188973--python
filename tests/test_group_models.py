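"""Multilevel age models, imputation, outlier rules, anxiety models."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from specverse.cohort import CohortConfig
from specverse.group_models import (
    AgeModelSpec,
    exclude_outliers,
    fit_age_model,
    fit_brain_anxiety_model,
    fit_trial_dynamics_models,
    fit_within_between,
    impute_scared_items,
)
from specverse.simulate import GenerativeParams, simulate_scan_measures


class TestExcludeOutliers:
    def test_clear_outlier_dropped(self):
        vals = pd.Series([0.0] * 50 + [100.0])
        kept, excluded = exclude_outliers(vals)
        assert excluded == [50]
        assert len(kept) == 50

    def test_constant_values_keep_everything(self):
        vals = pd.Series([2.0] * 10)
        kept, excluded = exclude_outliers(vals)
        assert excluded == [] and len(kept) == 10

    def test_normal_tail_rate(self, rng):
        vals = pd.Series(rng.normal(size=10_000))
        _, excluded = exclude_outliers(vals)
        rate = len(excluded) / 10_000
        assert 0.0012 < rate < 0.0045  # ~0.27% with MC slack

    def test_none_rule_is_passthrough(self, rng):
        vals = pd.Series(rng.normal(size=100))
        kept, excluded = exclude_outliers(vals, "none")
        assert len(kept) == 100 and excluded == []


class TestFitAgeModel:
    def test_row_permutation_invariance_freq(self, measures, rng):
        a = fit_age_model(measures, "reactivity")[0]
        shuffled = measures.sample(frac=1.0, random_state=3).reset_index(drop=True)
        b = fit_age_model(shuffled, "reactivity")[0]
        assert np.isclose(a.estimate, b.estimate)
        assert np.isclose(a.lower, b.lower)

    def test_interval_and_flag_consistency(self, measures):
        for spec in (
            AgeModelSpec(),
            AgeModelSpec(age_form="quadratic"),
            AgeModelSpec(age_form="inverse"),
            AgeModelSpec(covariates="mean_fd+block+scanner"),
        ):
            for est in fit_age_model(measures, "reactivity", spec):
                assert est.lower <= est.estimate <= est.upper
                assert est.excludes_zero == (not est.lower <= 0 <= est.upper)

    def test_bayes_and_freq_agree_on_well_behaved_data(self, measures):
        freq = fit_age_model(measures, "reactivity")[0]
        bayes = fit_age_model(
            measures, "reactivity", AgeModelSpec(estimation="bayes_mcmc"),
            seed=4, bayes_kwargs={"n_steps": 500, "n_burn": 200},
        )[0]
        # agreement within 0.05 generative SD (age slope SD scale ~ 0.01)
        assert abs(freq.estimate - bayes.estimate) < 0.01

    def test_robust_fit_close_to_plain_on_clean_data(self, measures):
        plain = fit_age_model(measures, "reactivity")[0]
        robust = fit_age_model(
            measures, "reactivity", AgeModelSpec(robust=True)
        )[0]
        assert abs(plain.estimate - robust.estimate) < 0.01

    def test_robust_fit_resists_contamination(self, measures):
        spoiled = measures.copy()
        spoiled.loc[spoiled.index[:5], "reactivity"] += 40.0
        plain_no_excl = fit_age_model(
            spoiled, "reactivity", AgeModelSpec(outlier_rule="none")
        )[0]
        robust = fit_age_model(
            spoiled, "reactivity",
            AgeModelSpec(outlier_rule="none", robust=True),
        )[0]
        clean = fit_age_model(measures, "reactivity")[0]
        assert abs(robust.estimate - clean.estimate) < abs(
            plain_no_excl.estimate - clean.estimate
        )

    def test_noiseless_balanced_data_matches_ols(self):
        ages = np.tile(np.linspace(5, 21, 30), 2)
        df = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(30)] * 2,
                "wave": [1] * 30 + [2] * 30,
                "age_at_scan": ages,
                "mean_fd": 0.2,
                "scanner": "a",
                "block_order": "o",
                "y": 1.0 - 0.05 * (ages - 12.0),
            }
        )
        est = fit_age_model(df, "y")[0]
        assert abs(est.estimate - (-0.05)) < 1e-6

    def test_degenerate_outcome_rejected(self, measures):
        df = measures.copy()
        df["flat"] = 1.0
        with pytest.raises(ValueError):
            fit_age_model(df, "flat")


class TestWithinBetween:
    def test_cross_sectional_within_flagged(self):
        m = simulate_scan_measures(
            CohortConfig(n_participants_by_scan_count={1: 60}), seed=2
        )
        res = fit_within_between(m, "reactivity")
        assert res["age_within"].inestimable
        assert np.isfinite(res["age_between"].estimate)

    def test_equal_slopes_recovered(self):
        params = replace(GenerativeParams(), habituation_age_interaction=0.0)
        m = simulate_scan_measures(params=params, seed=6)
        res = fit_within_between(m, "reactivity")
        # both decompose the same generative -0.05/yr age effect
        assert abs(res["age_between"].estimate - (-0.05)) < 0.03
        assert res["age_within"].lower <= -0.05 <= res["age_within"].upper
        assert res["difference"].lower <= 0 <= res["difference"].upper


class TestTrialDynamics:
    def test_slopes_on_age_sign_matches_generative_interaction(self, measures):
        """Habituation steeper at younger ages => slopes increase with age
        (positive age coefficient on the Spearman slopes)."""
        est = fit_trial_dynamics_models(measures, "slopes_on_age")[0]
        assert est.estimate > 0

    def _halves_frame(self, m):
        rows = []
        for _, r in m.iterrows():
            for half, col in (("first", "first_half_mean"),
                              ("second", "second_half_mean")):
                rows.append(
                    {
                        "scan_id": r["scan_id"],
                        "participant_id": r["participant_id"],
                        "age_at_scan": r["age_at_scan"],
                        "mean_fd": r["mean_fd"],
                        "half": half,
                        "mean_beta": r[col],
                    }
                )
        return pd.DataFrame(rows)

    def _trial_frame(self, seed=0):
        # trial-level data from the generative amplitude model
        rng = np.random.default_rng(seed)
        params = GenerativeParams()
        rows = []
        for pid in range(60):
            age = rng.uniform(4, 22)
            hab = (
                params.habituation_slope
                + params.habituation_age_interaction * (age - 12)
            )
            for trial in range(1, 25):
                rows.append(
                    {
                        "scan_id": f"p{pid}_w1",
                        "participant_id": f"p{pid}",
                        "age_at_scan": age,
                        "mean_fd": 0.2,
                        "trial_index": trial,
                        "beta": 1.0 + hab * (trial - 1) + rng.normal(0, 0.25),
                    }
                )
        return pd.DataFrame(rows)

    def test_halves_and_single_trial_agree_in_sign(self, measures):
        halves = fit_trial_dynamics_models(
            self._halves_frame(measures), "halves_interaction"
        )[0]
        single = fit_trial_dynamics_models(self._trial_frame(), "single_trial")[0]
        assert np.sign(halves.estimate) == np.sign(single.estimate)
        # steeper habituation at younger ages: both interactions positive
        assert single.estimate > 0

    def test_unknown_variant_rejected(self, measures):
        with pytest.raises(ValueError):
            fit_trial_dynamics_models(measures, "nope")


class TestImputation:
    def test_complete_table_unchanged(self, rng):
        table = pd.DataFrame(rng.normal(size=(10, 4)))
        out = impute_scared_items(table)
        pd.testing.assert_frame_equal(out, table)

    def test_nearest_identical_row(self):
        table = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, np.nan], [9.0, 9.0, 0.0]]
        )
        out = impute_scared_items(table, k=1)
        assert out.iloc[1, 2] == 3.0

    def test_matches_bruteforce_oracle(self, rng):
        """Exhaustive nearest-neighbor search, written independently."""
        for trial in range(10):
            r = np.random.default_rng(trial)
            table = pd.DataFrame(r.normal(size=(20, 8)))
            mask = r.uniform(size=(20, 8)) < 0.1
            mask[mask.all(axis=1)] = False
            vals = table.to_numpy()
            vals[mask] = np.nan
            table = pd.DataFrame(vals)
            out = impute_scared_items(table, k=5)
            mu = np.nanmean(vals, axis=0)
            sd = np.nanstd(vals, axis=0)
            z = (vals - mu) / sd
            for i, j in zip(*np.where(mask)):
                cands = [
                    c for c in range(20) if c != i and not np.isnan(vals[c, j])
                ]
                dists = []
                for c in cands:
                    both = ~np.isnan(z[i]) & ~np.isnan(z[c])
                    both[j] = False
                    d = (
                        np.sqrt(np.sum((z[i, both] - z[c, both]) ** 2))
                        if both.any()
                        else np.inf
                    )
                    dists.append(d)
                order = np.argsort(dists, kind="stable")[:5]
                expected = np.mean([vals[cands[o], j] for o in order])
                assert abs(out.iloc[i, j] - expected) < 1e-12

    def test_row_without_observations_rejected(self):
        table = pd.DataFrame([[1.0, 2.0], [np.nan, np.nan]])
        with pytest.raises(ValueError):
            impute_scared_items(table)


class TestBrainAnxiety:
    def _table(self, coef, seed=0, n=120):
        rng = np.random.default_rng(seed)
        rows = []
        for pid in range(n):
            age = rng.uniform(4, 18)
            brain = rng.normal()
            anx = 5 - 0.3 * (age - 12) + coef * brain + rng.normal(0, 0.8)
            rows.append(
                {
                    "participant_id": f"p{pid}",
                    "age_at_scan": age,
                    "mean_fd": 0.2 + rng.normal(0, 0.02),
                    "brain": brain,
                    "anx": anx,
                }
            )
        return pd.DataFrame(rows)

    def test_strong_effect_sign_recovered(self):
        est = fit_brain_anxiety_model(self._table(0.6), "brain", "anx")
        assert est.estimate > 0 and est.excludes_zero

    def test_invariant_to_affine_rescaling_of_anxiety(self):
        table = self._table(0.4, seed=1)
        a = fit_brain_anxiety_model(table, "brain", "anx")
        table2 = table.copy()
        table2["anx"] = 7.3 * table2["anx"] - 2.0
        b = fit_brain_anxiety_model(table2, "brain", "anx")
        assert np.isclose(a.estimate, b.estimate)

    def test_rows_without_anxiety_dropped(self):
        table = self._table(0.0, seed=2)
        table.loc[table.index[:20], "anx"] = np.nan
        est = fit_brain_anxiety_model(table, "brain", "anx")
        assert est.n_scans == 100
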