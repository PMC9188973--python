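"""Grid enumeration, sweep execution, curves, decision effects."""

import numpy as np
import pandas as pd
import pytest

from specverse.aims import run_aim
from specverse.group_models import GroupEstimate
from specverse.multiverse import (
    build_spec_curve,
    decision_effects,
    enumerate_specs,
    run_multiverse,
)


def _toy_estimate(value, width=0.1):
    return GroupEstimate(
        term="age", estimate=value, lower=value - width, upper=value + width,
        n_scans=10, n_participants=10,
    )


class TestEnumeration:
    def test_factorial_cross_product(self):
        specs = enumerate_specs(
            {"factors": {"a": ["x", "y"], "b": ["1", "2", "3", "4"]}}
        )
        assert len(specs) == 8
        assert len({s.fork_id for s in specs}) == 8

    def test_deterministic_order_and_ids(self):
        grid = {"factors": {"a": ["x", "y"], "b": ["1", "2"]}}
        s1 = enumerate_specs(grid)
        s2 = enumerate_specs(grid)
        assert [s.fork_id for s in s1] == [s.fork_id for s in s2]

    def test_duplicate_levels_rejected(self):
        with pytest.raises(ValueError):
            enumerate_specs({"factors": {"a": ["x", "x"]}})

    def test_curated_crossing(self):
        specs = enumerate_specs(
            {
                "factors": {"a": ["x", "y"]},
                "curated": [{"core": "c1"}, {"core": "c2"}, {"core": "c3"}],
            }
        )
        assert len(specs) == 6


class TestRunMultiverse:
    def test_smoke_8_specs(self):
        specs = enumerate_specs({"factors": {"a": ["x", "y"], "b": list("1234")}})
        table, failures = run_multiverse(specs, lambda s: _toy_estimate(0.5))
        assert len(table) == 8 and not failures

    def test_single_failure_isolated(self):
        specs = enumerate_specs({"factors": {"a": list("abcdefgh")}})
        bad = specs[3].fork_id

        def executor(spec):
            if spec.fork_id == bad:
                raise RuntimeError("boom")
            return _toy_estimate(1.0)

        table, failures = run_multiverse(specs, executor)
        assert len(table) == 7
        assert len(failures) == 1 and failures[0]["error"] == "RuntimeError"

    def test_excess_failures_abort(self):
        specs = enumerate_specs({"factors": {"a": list("abcd")}})

        def executor(spec):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="failure fraction"):
            run_multiverse(specs, executor)

    def test_resume_skips_existing(self):
        specs = enumerate_specs({"factors": {"a": list("abcd")}})
        first, _ = run_multiverse(specs[:2], lambda s: _toy_estimate(1.0))
        calls = []

        def executor(spec):
            calls.append(spec.fork_id)
            return _toy_estimate(2.0)

        table, _ = run_multiverse(specs, executor, existing=first)
        assert len(table) == 4
        assert set(calls) == {s.fork_id for s in specs[2:]}

    def test_deterministic_rerun(self, measures):
        from specverse.multiverse import run_reduced_reactivity

        t1, _ = run_reduced_reactivity(measures)
        t2, _ = run_reduced_reactivity(measures)
        pd.testing.assert_frame_equal(t1, t2)


class TestSpecCurve:
    def _table(self, values, widths=0.1):
        rows = []
        for i, v in enumerate(values):
            rows.append(
                {
                    "fork_id": f"f{i}",
                    "choice": "a" if i % 2 else "b",
                    "other": "p" if i < len(values) / 2 else "q",
                    "term": "age",
                    "estimate": v,
                    "lower": v - widths,
                    "upper": v + widths,
                    "excludes_zero": not (v - widths <= 0 <= v + widths),
                    "sign": int(np.sign(v)),
                    "converged": True,
                }
            )
        return pd.DataFrame(rows)

    def test_all_negative_excluding_zero(self):
        curve = build_spec_curve(self._table([-1.0, -0.8, -0.5], widths=0.1))
        assert curve.prop_same_sign == 1.0
        assert curve.prop_excluding_zero["negative"] == 1.0
        assert curve.prop_excluding_zero["same_direction_as_median"] == 1.0

    def test_symmetric_estimates_split_sign(self):
        vals = np.concatenate([np.linspace(-1, -0.1, 10), np.linspace(0.1, 1, 10)])
        curve = build_spec_curve(self._table(list(vals), widths=5.0))
        assert abs(curve.prop_same_sign - 0.5) <= 0.05

    def test_sorted_ascending_and_order_invariant_median(self, rng):
        vals = list(rng.normal(size=15))
        a = build_spec_curve(self._table(vals))
        b = build_spec_curve(self._table(vals[::-1]))
        assert np.all(np.diff(a.table["estimate"]) >= 0)
        assert a.median == b.median
        assert a.prop_same_sign == b.prop_same_sign

    def test_rank_summaries_match_bruteforce(self, rng):
        table = self._table(list(rng.normal(size=20)))
        curve = build_spec_curve(table)
        df = table.sort_values("estimate", kind="stable").reset_index(drop=True)
        df["rank"] = np.arange(1, 21)
        for _, row in curve.rank_summary.iterrows():
            ranks = df.loc[df[row["decision"]] == row["level"], "rank"]
            assert row["median_rank"] == ranks.median()
            assert row["iqr_low"] == ranks.quantile(0.25)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_spec_curve(self._table([]))


class TestDecisionEffects:
    def _grid_table(self, effect=0.1, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for a in ("yes", "no"):
            for b in ("p", "q", "r"):
                for c in ("u", "v"):
                    est = (
                        effect * (a == "no")
                        + rng.normal(0, noise)
                    )
                    rows.append(
                        {
                            "fork_id": f"{a}{b}{c}",
                            "deconvolution": a,
                            "roi": b,
                            "cov": c,
                            "term": "age",
                            "estimate": est,
                            "lower": est - 1,
                            "upper": est + 1,
                            "excludes_zero": False,
                            "sign": 1,
                            "converged": True,
                        }
                    )
        return pd.DataFrame(rows)

    def test_planted_effect_recovered(self):
        effects = decision_effects(self._grid_table(effect=0.1))
        row = effects[
            (effects["decision"] == "deconvolution") & (effects["level"] == "yes")
        ].iloc[0]
        # reference level is "no": switching to "yes" removes the 0.1
        assert abs(row["coef"] - (-0.1)) < 1e-10
        others = effects[effects["decision"] != "deconvolution"]
        assert np.abs(others["coef"]).max() < 1e-10

    def test_matches_closed_form_ols(self):
        table = self._grid_table(effect=0.07, noise=0.05, seed=3)
        effects = decision_effects(table)
        dummies = pd.get_dummies(
            table[["deconvolution", "roi", "cov"]], drop_first=True, dtype=float
        )
        X = np.column_stack([np.ones(len(table)), dummies.to_numpy()])
        beta = np.linalg.lstsq(X, table["estimate"].to_numpy(), rcond=None)[0]
        assert np.allclose(sorted(effects["coef"]), sorted(beta[1:]), atol=1e-10)

    def test_aliased_decisions_rejected(self):
        table = self._grid_table()
        table["alias"] = table["deconvolution"]
        with pytest.raises(ValueError, match="aliased"):
            decision_effects(table)

    def test_needs_two_varying_decisions(self):
        table = self._grid_table()
        with pytest.raises(ValueError):
            decision_effects(table[["fork_id", "deconvolution", "estimate"]])


class TestRunAimSmoke:
    def test_reactivity_grid_completes(self, small_study):
        grid = {
            "factors": {
                "amygdala_roi": ["amyg_bilateral", "amyg_left", "amyg_right"],
                "estimate_type": ["beta", "t"],
                "hrf": ["double_gamma", "single_gamma"],
                "covariates": ["mean_fd", "mean_fd+scanner"],
            }
        }
        res = run_aim("reactivity", small_study, grid=grid, seed=1)
        assert len(res.estimates) == 24 and not res.failures
        assert len(res.curve.table) == 24
        assert res.effects is not None

    def test_gppi_and_bsc_complete(self, small_study):
        g = {
            "factors": {
                "deconvolution": ["yes", "no"],
                "mpfc_roi": ["mpfc1", "vmpfc_large"],
            }
        }
        res = run_aim("gppi", small_study, grid=g, seed=1)
        assert len(res.estimates) == 4 and not res.failures
        g2 = {
            "factors": {
                "amygdala_roi": ["amyg_bilateral"],
                "mpfc_roi": ["mpfc1", "mpfc2"],
                "gss": ["yes", "no"],
            }
        }
        res2 = run_aim("bsc", small_study, grid=g2, seed=1)
        assert len(res2.estimates) == 4 and not res2.failures

    def test_trial_dynamics_and_anxiety_complete(self, small_study):
        g = {
            "factors": {
                "amygdala_roi": ["amyg_bilateral"],
                "gss": ["yes", "no"],
                "covariates": ["mean_fd", "mean_fd+scanner"],
            }
        }
        res = run_aim("trial_dynamics", small_study, grid=g, seed=1)
        assert len(res.estimates) == 4 and not res.failures
        res2 = run_aim("anxiety", small_study, seed=1)
        assert len(res2.estimates) == 18 and not res2.failures

    def test_unknown_aim_rejected(self, small_study):
        with pytest.raises(ValueError):
            run_aim("nope", small_study)
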