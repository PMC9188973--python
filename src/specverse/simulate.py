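"""Generative model for ROI BOLD timeseries with known trial amplitudes.

Each trial's neural amplitude is

    a_i = baseline_c + age_slope_c * (age - 12) + habituation(trial_i, age)
          + participant offset + sqrt(rho_c) * z_i * sd + unique noise,

where the shared standard-normal component ``z_i`` induces a per-condition
trial-amplitude correlation ``rho_c`` between the amygdala seed and the mPFC
targets. BOLD is the HRF convolution of the amplitude-weighted event train
plus AR(1) noise, polynomial drift, a low-frequency global component common
to all ROIs, and motion-coupled artifacts whose magnitude decreases with age
(younger children move more). The generative amplitudes are returned with
every record so downstream estimators have an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .cohort import AGE_CENTER, CohortConfig, generate_cohort
from .design import CONDITIONS, TaskDesign, generate_task_design
from .hrf import HRFKernel, convolve_events, make_hrf

SEED_ROIS = ("amyg_bilateral", "amyg_left", "amyg_right")
TARGET_ROIS = ("mpfc1", "mpfc2", "mpfc3", "vmpfc_large")
TISSUE_ROIS = ("wm", "csf")
ROI_PANEL = SEED_ROIS + TARGET_ROIS
ALL_COLUMNS = ROI_PANEL + TISSUE_ROIS + ("global",)

_ROTATION_RADIUS_MM = 50.0  # rotations-to-mm conversion for FD


@dataclass(frozen=True)
class GenerativeParams:
    """Effect sizes and noise structure of the simulated study.

    Defaults encode the qualitative pattern of the emulated study: a
    detectable negative age slope of amygdala reactivity to fear faces,
    within-run habituation that is steeper at younger ages, condition-
    dependent seed-target coupling (fear > neutral), and mean framewise
    displacement decreasing with age.
    """

    baseline_amplitude: dict[str, float] = field(
        default_factory=lambda: {"fear": 1.0, "neutral": 0.8}
    )
    age_slope: dict[str, float] = field(
        default_factory=lambda: {"fear": -0.05, "neutral": -0.03}
    )
    habituation_slope: float = -0.02  # amplitude units per trial at age 12
    habituation_age_interaction: float = 0.002  # per trial per year
    participant_sd: float = 0.2  # stable participant amplitude offset
    trial_amplitude_sd: float = 0.25
    coupling_rho: dict[str, float] = field(
        default_factory=lambda: {"fear": 0.35, "neutral": 0.15}
    )
    target_baseline: float = 0.5
    roi_split_sd: float = 0.15  # left/right amygdala unique amplitude noise
    target_roi_sd: float = 0.15  # per-target-ROI unique amplitude noise
    ar1_coef: float = 0.3
    noise_sd: float = 0.5
    drift_coefs: tuple[float, ...] = (0.0, 0.4, -0.25)  # linear, quadratic, ...
    global_amp: float = 0.3
    motion_artifact_gain: float = 0.5
    # random-walk step scale; mean FD ~ 4.6 x step scale, so the defaults
    # give mean FD ~ 0.3 mm at age 4 falling to ~ 0.1 mm at age 22
    motion_base: float = 0.045  # mm at age 12
    motion_age_slope: float = -0.0025  # per year
    hrf_kind: str = "double_gamma"

    def __post_init__(self) -> None:
        for c, rho in self.coupling_rho.items():
            if abs(rho) > 1:
                raise ValueError(f"|coupling_rho[{c}]| must be <= 1")
        if not (0 <= self.ar1_coef < 1):
            raise ValueError("ar1_coef must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def null(self) -> "GenerativeParams":
        """Copy with all age/habituation/coupling effects removed."""
        return replace(
            self,
            age_slope={c: 0.0 for c in CONDITIONS},
            habituation_slope=0.0,
            habituation_age_interaction=0.0,
            coupling_rho={c: 0.0 for c in CONDITIONS},
        )


@dataclass(frozen=True)
class ScanRecord:
    """One scan: ROI timeseries, confounds, metadata, generative truth."""

    participant_id: str
    wave: int
    age_at_scan: float
    scanner: str
    block_order: str
    roi_timeseries: pd.DataFrame = field(repr=False)
    realignment_params: pd.DataFrame = field(repr=False)
    fd_series: np.ndarray = field(repr=False)
    amplitudes: pd.DataFrame = field(repr=False)  # generative trial amplitudes
    design: TaskDesign = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.roi_timeseries) != self.design.n_volumes:
            raise ValueError("timeseries length must equal n_volumes")
        if np.any(self.fd_series < 0):
            raise ValueError("fd_series must be non-negative")

    @property
    def mean_fd(self) -> float:
        return float(np.mean(self.fd_series))

    @property
    def scan_id(self) -> str:
        return f"{self.participant_id}_w{self.wave}"


def _simulate_motion(
    rng: np.random.Generator, n_volumes: int, step_scale: float
) -> tuple[pd.DataFrame, np.ndarray]:
    """Random-walk realignment parameters and the implied FD series.

    FD is the sum of absolute backward differences of the six parameters
    with rotations converted to mm on a 50 mm radius; the first volume is
    assigned 0.
    """
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    # heavy-tailed steps give occasional spikes, as in real head motion
    steps = rng.standard_t(df=4, size=(n_volumes, 6)) * step_scale / np.sqrt(2)
    steps[0] = 0.0
    steps[:, 3:] /= _ROTATION_RADIUS_MM  # rotations stored in radians
    params = pd.DataFrame(np.cumsum(steps, axis=0), columns=cols)
    diffs = np.abs(np.diff(params.to_numpy(), axis=0))
    diffs[:, 3:] *= _ROTATION_RADIUS_MM
    fd = np.concatenate([[0.0], diffs.sum(axis=1)])
    return params, fd


def compute_fd(realignment_params: pd.DataFrame) -> np.ndarray:
    """FD from a 6-column realignment table (rotations in radians)."""
    vals = realignment_params.to_numpy(dtype=float).copy()
    vals[:, 3:] *= _ROTATION_RADIUS_MM
    diffs = np.abs(np.diff(vals, axis=0))
    return np.concatenate([[0.0], diffs.sum(axis=1)])


def _ar1_noise(
    rng: np.random.Generator, n: int, phi: float, sd: float
) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1 - phi**2)
    e = rng.normal(0.0, innov_sd, n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + e[t]
    return out


def trial_amplitudes(
    design: TaskDesign,
    age: float,
    params: GenerativeParams,
    rng: np.random.Generator,
    participant_offset: float = 0.0,
) -> pd.DataFrame:
    """Draw the generative per-trial amplitude table for all ROIs."""
    n = design.n_trials
    cond = design.trial_conditions
    idx = design.trial_index
    dage = age - AGE_CENTER
    hab = params.habituation_slope + params.habituation_age_interaction * dage
    mean_seed = np.array(
        [
            params.baseline_amplitude[c]
            + params.age_slope[c] * dage
            + hab * (i - 1)
            + participant_offset
            for c, i in zip(cond, idx)
        ]
    )
    mean_target = np.full(n, params.target_baseline)
    sd = params.trial_amplitude_sd
    z = rng.normal(size=n)
    e_seed = rng.normal(size=n)
    e_targ = rng.normal(size=n)
    rho = np.array([params.coupling_rho[c] for c in cond])
    sgn = np.sign(rho) + (rho == 0)
    a = np.sqrt(np.abs(rho))
    seed_amp = mean_seed + sd * (a * z + np.sqrt(1 - np.abs(rho)) * e_seed)
    targ_amp = mean_target + sd * (
        sgn * a * z + np.sqrt(1 - np.abs(rho)) * e_targ
    )
    table = pd.DataFrame(
        {
            "condition": cond,
            "trial_index": idx,
            "onset": design.trial_onsets,
            "amyg_bilateral": seed_amp,
        }
    )
    for roi in ("amyg_left", "amyg_right"):
        table[roi] = seed_amp + rng.normal(0.0, params.roi_split_sd, n)
    for roi in TARGET_ROIS:
        table[roi] = targ_amp + rng.normal(0.0, params.target_roi_sd, n)
    return table


def simulate_scan(
    design: TaskDesign,
    meta: pd.Series | dict,
    params: GenerativeParams = GenerativeParams(),
    seed: int = 0,
    participant_offset: float = 0.0,
    hrf: HRFKernel | None = None,
) -> ScanRecord:
    """Simulate one scan's ROI panel from the generative model."""
    meta = dict(meta)
    age = float(meta["age_at_scan"])
    rng = np.random.default_rng(seed)
    if hrf is None:
        hrf = make_hrf(params.hrf_kind)
    amps = trial_amplitudes(design, age, params, rng, participant_offset)
    n_vol = design.n_volumes
    t = np.linspace(-1.0, 1.0, n_vol)
    drift = np.zeros(n_vol)
    for k, c in enumerate(params.drift_coefs, start=1):
        drift += c * t**k
    # low-frequency global fluctuation shared by all ROIs
    phase = rng.uniform(0, 2 * np.pi, 2)
    tt = np.arange(n_vol) * design.tr
    glob = np.sin(2 * np.pi * 0.004 * tt + phase[0]) + 0.5 * np.sin(
        2 * np.pi * 0.008 * tt + phase[1]
    )
    step_scale = max(
        0.005, params.motion_base + params.motion_age_slope * (age - AGE_CENTER)
    )
    realign, fd = _simulate_motion(rng, n_vol, step_scale)
    motion_art = params.motion_artifact_gain * fd
    series = {}
    for roi in ROI_PANEL:
        task = convolve_events(
            design.trial_onsets,
            design.trial_durations,
            amps[roi].to_numpy(),
            hrf,
            design.tr,
            n_vol,
        )
        noise = _ar1_noise(rng, n_vol, params.ar1_coef, params.noise_sd)
        series[roi] = (
            task + drift + params.global_amp * glob + motion_art + noise
        )
    for roi in TISSUE_ROIS:
        noise = _ar1_noise(rng, n_vol, params.ar1_coef, params.noise_sd)
        series[roi] = (
            drift + 1.2 * params.global_amp * glob + 1.5 * motion_art + noise
        )
    ts = pd.DataFrame(series)
    ts["global"] = ts[list(ROI_PANEL + TISSUE_ROIS)].mean(axis=1)
    return ScanRecord(
        participant_id=str(meta["participant_id"]),
        wave=int(meta["wave"]),
        age_at_scan=age,
        scanner=str(meta.get("scanner", "scanner_A")),
        block_order=str(meta.get("block_order", "order_1")),
        roi_timeseries=ts,
        realignment_params=realign,
        fd_series=fd,
        amplitudes=amps,
        design=design,
    )


@dataclass
class SimulatedStudy:
    """A full simulated study: cohort table, shared design, scan records."""

    cohort: pd.DataFrame
    design: TaskDesign
    scans: list[ScanRecord]
    params: GenerativeParams

    def scan_table(self) -> pd.DataFrame:
        rows = []
        for s in self.scans:
            rows.append(
                {
                    "scan_id": s.scan_id,
                    "participant_id": s.participant_id,
                    "wave": s.wave,
                    "age_at_scan": s.age_at_scan,
                    "scanner": s.scanner,
                    "block_order": s.block_order,
                    "mean_fd": s.mean_fd,
                }
            )
        return pd.DataFrame(rows)


def simulate_study(
    config: CohortConfig = CohortConfig(),
    params: GenerativeParams = GenerativeParams(),
    seed: int = 0,
    design: TaskDesign | None = None,
) -> SimulatedStudy:
    """Simulate a whole accelerated-longitudinal study.

    Participant amplitude offsets are drawn once per participant so that
    repeated scans of the same child share a stable trait (this is what
    gives the measures a nonzero test-retest ICC). The task design is fixed
    across participants, as in the emulated study.
    """
    rng = np.random.default_rng(seed)
    cohort = generate_cohort(
        CohortConfig(**{**config.__dict__, "seed": int(rng.integers(2**31))})
    )
    if design is None:
        design = generate_task_design(seed=int(rng.integers(2**31)))
    offsets = {
        p: rng.normal(0.0, params.participant_sd)
        for p in cohort["participant_id"].unique()
    }
    hrf = make_hrf(params.hrf_kind)
    scans = [
        simulate_scan(
            design,
            row,
            params,
            seed=int(rng.integers(2**31)),
            participant_offset=offsets[row["participant_id"]],
            hrf=hrf,
        )
        for _, row in cohort.iterrows()
    ]
    return SimulatedStudy(cohort=cohort, design=design, scans=scans, params=params)


def simulate_scan_measures(
    config: CohortConfig = CohortConfig(),
    params: GenerativeParams = GenerativeParams(),
    seed: int = 0,
    estimation_noise_sd: float = 0.3,
    condition: str = "fear",
    n_trials: int = 24,
) -> pd.DataFrame:
    """Scan-level reactivity measures drawn directly from the amplitude model.

    A fast surrogate for the full BOLD -> GLM pipeline used in group-model
    calibration studies: each scan's measure is its mean generative trial
    amplitude plus GLM estimation noise. Also returns per-scan trial-slope
    and half-mean summaries of the generative amplitudes.
    """
    rng = np.random.default_rng(seed)
    cohort = generate_cohort(
        CohortConfig(**{**config.__dict__, "seed": int(rng.integers(2**31))})
    )
    offsets = {
        p: rng.normal(0.0, params.participant_sd)
        for p in cohort["participant_id"].unique()
    }
    dage = cohort["age_at_scan"].to_numpy() - AGE_CENTER
    hab = params.habituation_slope + params.habituation_age_interaction * dage
    trial_idx = np.arange(1, n_trials + 1)
    rows = []
    for i, (_, row) in enumerate(cohort.iterrows()):
        mean_amp = (
            params.baseline_amplitude[condition]
            + params.age_slope[condition] * dage[i]
            + hab[i] * (trial_idx - 1).mean()
            + offsets[row["participant_id"]]
        )
        trial_amps = (
            params.baseline_amplitude[condition]
            + params.age_slope[condition] * dage[i]
            + hab[i] * (trial_idx - 1)
            + offsets[row["participant_id"]]
            + rng.normal(0.0, params.trial_amplitude_sd, n_trials)
        )
        est = mean_amp + rng.normal(0.0, estimation_noise_sd)
        # rank-order trend across trials (same statistic the pipeline uses)
        slope = spearmanr(trial_idx, trial_amps).statistic
        step = max(
            0.005,
            params.motion_base + params.motion_age_slope * dage[i],
        )
        row_out = {
            "scan_id": f"{row['participant_id']}_w{row['wave']}",
            "participant_id": row["participant_id"],
            "wave": row["wave"],
            "age_at_scan": row["age_at_scan"],
            "scanner": row["scanner"],
            "block_order": row["block_order"],
            "mean_fd": 4.6 * step * abs(rng.normal(1.0, 0.2)),
            "reactivity": est,
            "reactivity_amyg_bilateral": est,
            "trial_slope": slope,
            "first_half_mean": trial_amps[: n_trials // 2].mean(),
            "second_half_mean": trial_amps[n_trials // 2 :].mean(),
        }
        # unilateral ROI measures share the bilateral signal plus ROI noise
        for roi in ("amyg_left", "amyg_right"):
            row_out[f"reactivity_{roi}"] = est + rng.normal(
                0.0, params.roi_split_sd
            )
        rows.append(row_out)
    return pd.DataFrame(rows)
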