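"""Accelerated-longitudinal cohort and parent-report anxiety score generation.

The emulated cohort spans ages 4-22 years with 1-3 scans per participant at
~18-month intervals. Starting ages are approximately uniform over the age
range so that age coverage is assembled across participants rather than
within them, and the third study wave switches scanner (a site change the
group models can absorb as a covariate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AGE_CENTER = 12.0  # years; centering constant used throughout the package
N_SCARED_ITEMS = 8
BLOCK_ORDERS = ("order_1", "order_2", "order_3")


@dataclass(frozen=True)
class CohortConfig:
    """Composition of the simulated accelerated-longitudinal cohort."""

    n_participants_by_scan_count: dict[int, int] = field(
        default_factory=lambda: {1: 40, 2: 31, 3: 27}
    )
    age_range: tuple[float, float] = (4.0, 22.0)
    inter_scan_interval: float = 1.5  # years (~18 months)
    scanner_by_wave: dict[int, str] = field(
        default_factory=lambda: {1: "scanner_A", 2: "scanner_A", 3: "scanner_B"}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_participants_by_scan_count:
            raise ValueError("cohort composition is empty")
        if any(n < 0 for n in self.n_participants_by_scan_count.values()):
            raise ValueError("participant counts must be non-negative")
        if sum(self.n_participants_by_scan_count.values()) == 0:
            raise ValueError("cohort has no participants")


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """One row per scan: participant_id, wave, age_at_scan, scanner, block_order.

    Ages at later waves are starting age + (wave-1) x interval, capped at the
    top of the age range.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    rows = []
    pid = 0
    for n_scans in sorted(config.n_participants_by_scan_count):
        for _ in range(config.n_participants_by_scan_count[n_scans]):
            pid += 1
            participant = f"sub{pid:03d}"
            start_age = rng.uniform(lo, hi)
            block = BLOCK_ORDERS[rng.integers(len(BLOCK_ORDERS))]
            for wave in range(1, n_scans + 1):
                age = min(start_age + (wave - 1) * config.inter_scan_interval, hi)
                rows.append(
                    {
                        "participant_id": participant,
                        "wave": wave,
                        "age_at_scan": age,
                        "scanner": config.scanner_by_wave.get(wave, "scanner_A"),
                        "block_order": block,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnxietyParams:
    """Generative parameters for parent-report separation-anxiety scores.

    Raw subscale scores decrease with age (as in real parent reports);
    t-scores are age-standardized by construction. ``brain_coef`` injects a
    dependence of anxiety on a scan-level brain measure (0 = null).
    """

    age_effect: float = -0.35  # raw-score units per year
    baseline: float = 8.0
    trait_sd: float = 1.5  # stable participant trait
    noise_sd: float = 1.0
    missing_fraction: float = 0.0  # per item-cell
    adult_age: float = 18.0  # no parent report at/after this age
    brain_coef: float = 0.0


def generate_anxiety_scores(
    cohort: pd.DataFrame,
    params: AnxietyParams = AnxietyParams(),
    seed: int = 0,
    brain_measure: pd.Series | None = None,
) -> pd.DataFrame:
    """Per scan: rcads_raw, scared_raw, scared_t plus SCARED item columns.

    Item-level entries are set missing at the configured fraction (for
    imputation tests); adults receive no parent report at all.
    """
    rng = np.random.default_rng(seed)
    out = cohort[["participant_id", "wave", "age_at_scan"]].copy()
    traits = {
        p: rng.normal(0.0, params.trait_sd)
        for p in cohort["participant_id"].unique()
    }
    age = out["age_at_scan"].to_numpy()
    trait = out["participant_id"].map(traits).to_numpy()
    latent = (
        params.baseline
        + params.age_effect * (age - AGE_CENTER)
        + trait
        + rng.normal(0.0, params.noise_sd, len(out))
    )
    if brain_measure is not None and params.brain_coef != 0.0:
        brain = np.asarray(brain_measure, dtype=float)
        bz = (brain - np.nanmean(brain)) / np.nanstd(brain)
        latent = latent + params.brain_coef * bz
    # SCARED items: split the latent score over items with item noise, on a
    # 0-2 ordinal-like scale
    item_cols = [f"scared_item{i}" for i in range(1, N_SCARED_ITEMS + 1)]
    items = np.clip(
        latent[:, None] / N_SCARED_ITEMS
        + rng.normal(0.0, 0.3, (len(out), N_SCARED_ITEMS)),
        0.0,
        2.0,
    )
    for j, col in enumerate(item_cols):
        out[col] = items[:, j]
    out["scared_raw"] = items.sum(axis=1)
    out["rcads_raw"] = np.clip(
        latent + rng.normal(0.0, params.noise_sd, len(out)), 0.0, None
    )
    # t-score: standardized against the expected score at the child's age,
    # hence age-invariant by construction
    expected = params.baseline + params.age_effect * (age - AGE_CENTER)
    sd = np.sqrt(params.trait_sd**2 + params.noise_sd**2)
    out["scared_t"] = 50.0 + 10.0 * (out["scared_raw"] - expected) / sd
    if params.missing_fraction > 0:
        mask = rng.uniform(size=(len(out), N_SCARED_ITEMS)) < params.missing_fraction
        vals = out[item_cols].to_numpy()
        vals[mask] = np.nan
        out[item_cols] = vals
        incomplete = np.isnan(vals).any(axis=1)
        out.loc[incomplete, "scared_raw"] = np.nan
    adult = age >= params.adult_age
    score_cols = item_cols + ["scared_raw", "rcads_raw", "scared_t"]
    out.loc[adult, score_cols] = np.nan
    return out
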