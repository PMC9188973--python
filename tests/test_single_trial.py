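"""LSS single-trial betas, global-signal centering, trial dynamics."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specverse.design import generate_task_design
from specverse.hrf import convolve_events, make_hrf
from specverse.simulate import ROI_PANEL, simulate_scan
from specverse.single_trial import (
    apply_global_signal_centering,
    fit_lss,
    half_means,
    slopes_table,
    trial_slope,
)

from conftest import CLEAN, META


def _beta_frame(betas, condition="fear", roi="amyg_bilateral", scan_id="s1"):
    return pd.DataFrame(
        {
            "scan_id": scan_id,
            "roi": roi,
            "condition": condition,
            "trial_index": np.arange(1, len(betas) + 1),
            "beta": betas,
            "gss_applied": False,
        }
    )


class TestLSS:
    def test_48_models_per_scan(self, scan):
        table = fit_lss(scan, rois=("amyg_bilateral",))
        assert len(table) == 48
        assert (table.groupby("condition").size() == 24).all()

    def test_lss_equals_lsa_for_nonoverlapping_trials(self):
        """Trials >= 32 s apart have no HRF overlap, so per-trial and
        all-trials-separate estimates coincide (LSA oracle)."""
        design = generate_task_design(
            n_fear=3, n_neutral=3, iti_bounds=(36.0, 40.0), iti_median=37.0,
            n_volumes=130, seed=2,
        )
        params = replace(CLEAN, habituation_slope=0.0)
        scan = simulate_scan(design, META, params, seed=4)
        lss = fit_lss(
            scan, rois=("amyg_bilateral",), nuisance_set="none",
            drift="none", include_intercept=False,
        )
        # LSA oracle: all trials in one GLM, one regressor per trial
        hrf = make_hrf()
        X = np.column_stack(
            [
                convolve_events(
                    design.trial_onsets[[k]], design.trial_durations[[k]],
                    np.ones(1), hrf, design.tr, design.n_volumes,
                )
                for k in range(design.n_trials)
            ]
        )
        y = scan.roi_timeseries["amyg_bilateral"].to_numpy()
        lsa = np.linalg.lstsq(X, y, rcond=None)[0][: design.n_trials]
        order = np.lexsort((design.trial_index, design.trial_conditions))
        lss_sorted = lss.sort_values(["condition", "trial_index"])["beta"].to_numpy()
        assert np.abs(lss_sorted - lsa[order]).max() < 1e-6

    def test_constant_amplitude_noiseless_betas_equal(self, design):
        params = replace(
            CLEAN,
            habituation_slope=0.0,
            habituation_age_interaction=0.0,
            trial_amplitude_sd=0.0,
            age_slope={"fear": 0.0, "neutral": 0.0},
            baseline_amplitude={"fear": 1.0, "neutral": 1.0},
        )
        scan = simulate_scan(design, META, params, seed=4)
        table = fit_lss(scan, rois=("amyg_bilateral",), nuisance_set="6")
        assert table["beta"].std() < 1e-6


class TestGlobalSignalCentering:
    def test_two_roi_centering(self):
        table = pd.concat(
            [
                _beta_frame([3.0], roi="a"),
                _beta_frame([1.0], roi="b"),
            ]
        )
        out = apply_global_signal_centering(table)
        assert sorted(out["beta"]) == [-1.0, 1.0]
        assert out["gss_applied"].all()

    def test_invariance_to_common_offset(self, rng):
        betas = {roi: rng.normal(size=24) for roi in ("a", "b", "c")}
        t1 = pd.concat([_beta_frame(b, roi=r) for r, b in betas.items()])
        t2 = pd.concat(
            [_beta_frame(b + 5.0, roi=r) for r, b in betas.items()]
        )
        c1 = apply_global_signal_centering(t1).sort_values(["roi", "trial_index"])
        c2 = apply_global_signal_centering(t2).sort_values(["roi", "trial_index"])
        assert np.allclose(c1["beta"].to_numpy(), c2["beta"].to_numpy())

    def test_pairwise_differences_preserved(self, rng):
        betas = {roi: rng.normal(size=24) for roi in ("a", "b")}
        table = pd.concat([_beta_frame(b, roi=r) for r, b in betas.items()])
        out = apply_global_signal_centering(table)
        raw_diff = betas["a"] - betas["b"]
        cen = out.pivot_table(index="trial_index", columns="roi", values="beta")
        assert np.allclose(cen["a"] - cen["b"], raw_diff)

    def test_single_roi_rejected(self):
        with pytest.raises(ValueError):
            apply_global_signal_centering(_beta_frame([1.0, 2.0]))

    def test_centering_restores_coupling_under_global_artifact(self, rng):
        """A shared per-trial global component inflates the raw seed-target
        correlation; centering over a whole-brain-like panel restores the
        generative value. (Centering over a P-region panel attenuates the
        correlation by ~(1+2 rho)/P, so a large panel is used here.)"""
        rho, n_trials, reps, n_other = 0.5, 24, 100, 100
        raw_rs, cen_rs = [], []
        for _ in range(reps):
            z = rng.normal(size=n_trials)
            g = rng.normal(size=n_trials) * 2.0  # strong global artifact
            seed = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal(size=n_trials)
            targ = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal(size=n_trials)
            others = rng.normal(size=(n_other, n_trials))
            panel = {"seed": seed + g, "targ": targ + g}
            panel.update({f"r{i}": others[i] + g for i in range(n_other)})
            table = pd.concat(
                [_beta_frame(v, roi=k) for k, v in panel.items()]
            )
            cen = apply_global_signal_centering(table).pivot_table(
                index="trial_index", columns="roi", values="beta"
            )
            raw_rs.append(np.corrcoef(panel["seed"], panel["targ"])[0, 1])
            cen_rs.append(np.corrcoef(cen["seed"], cen["targ"])[0, 1])
        assert np.mean(raw_rs) > rho + 0.15  # inflation
        assert abs(np.mean(cen_rs) - rho) < 0.06  # restored within MC error


class TestTrialSlope:
    def test_perfect_monotone_series(self):
        dec = _beta_frame(np.arange(24, 0, -1, dtype=float))
        inc = _beta_frame(np.arange(1, 25, dtype=float))
        assert np.isclose(trial_slope(dec, "fear").value, -1.0)
        assert np.isclose(trial_slope(inc, "fear").value, 1.0)

    def test_constant_series_degenerate(self):
        res = trial_slope(_beta_frame(np.ones(24)), "fear")
        assert res.value == 0.0 and res.degenerate

    def test_too_few_trials_missing(self):
        res = trial_slope(_beta_frame([1.0, 2.0]), "fear")
        assert res.missing and "3" in res.reason

    def test_matches_bruteforce_spearman(self, rng):
        """Rank both vectors by hand (ties mid-ranked) and correlate."""

        def naive(x, y):
            def rank(v):
                order = np.argsort(v, kind="stable")
                ranks = np.empty(len(v), dtype=float)
                ranks[order] = np.arange(1, len(v) + 1)
                for val in np.unique(v):
                    m = v == val
                    ranks[m] = ranks[m].mean()
                return ranks

            rx, ry = rank(x), rank(y)
            return np.corrcoef(rx, ry)[0, 1]

        for _ in range(100):
            betas = np.round(rng.normal(size=24), 1)  # induces ties
            res = trial_slope(_beta_frame(betas), "fear")
            expected = naive(np.arange(1, 25), betas)
            assert abs(res.value - expected) < 1e-12

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariant_to_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        betas = r.normal(size=24)
        a = trial_slope(_beta_frame(betas), "fear").value
        b = trial_slope(_beta_frame(np.exp(2 * betas) + 1), "fear").value
        assert abs(a - b) < 1e-12


class TestHalfMeans:
    def test_arithmetic(self):
        m1, m2, n1, n2 = half_means(
            _beta_frame(np.arange(1, 25, dtype=float)), "fear"
        )
        assert (m1, m2) == (6.5, 18.5)
        assert (n1, n2) == (12, 12)

    def test_missing_trial_reduces_count(self):
        betas = np.arange(1, 25, dtype=float)
        frame = _beta_frame(betas)
        frame.loc[frame["trial_index"] == 1, "beta"] = np.nan
        m1, _, n1, _ = half_means(frame, "fear")
        assert n1 == 11
        assert np.isclose(m1, np.mean(betas[1:12]))

    def test_empty_half_missing(self):
        frame = _beta_frame(np.arange(1, 25, dtype=float))
        frame.loc[frame["trial_index"] <= 12, "beta"] = np.nan
        m1, m2, n1, _ = half_means(frame, "fear")
        assert np.isnan(m1) and n1 == 0 and np.isfinite(m2)

    def test_habituation_shows_as_half_difference(self, design):
        """With habituation slope h per trial, first-half mean exceeds the
        second-half mean by 12|h| (closed form on generative amplitudes)."""
        h = -0.05
        params = replace(
            CLEAN, habituation_slope=h, habituation_age_interaction=0.0,
            trial_amplitude_sd=0.0, age_slope={"fear": 0.0, "neutral": 0.0},
        )
        scan = simulate_scan(
            design, {**META, "age_at_scan": 12.0}, params, seed=4
        )
        amps = scan.amplitudes
        frame = _beta_frame(
            amps[amps["condition"] == "fear"]
            .sort_values("trial_index")["amyg_bilateral"]
            .to_numpy()
        )
        m1, m2, _, _ = half_means(frame, "fear")
        assert abs((m1 - m2) - 12 * abs(h)) < 1e-10


def test_slopes_table_covers_all_groups(scan):
    table = fit_lss(scan, rois=ROI_PANEL[:2])
    st_ = slopes_table(table)
    assert len(st_) == 2 * 2  # 2 ROIs x 2 conditions
    assert st_["trial_slope"].between(-1, 1).all()
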