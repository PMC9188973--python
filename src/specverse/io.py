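"""Plain-text readers/writers for the pipeline's external interfaces.

Events and confounds use the BIDS tab-separated dialects; ROI timeseries
and cohort/anxiety tables are headed CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

EVENTS_COLUMNS = ["onset", "duration", "trial_type"]
CONFOUND_COLUMNS = [
    "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
    "framewise_displacement",
]


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events[EVENTS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events file missing columns: {sorted(missing)}")
    return df[EVENTS_COLUMNS]


def write_confounds(
    realignment_params: pd.DataFrame, fd_series: np.ndarray, path: str | Path
) -> None:
    out = realignment_params.copy()
    out.columns = CONFOUND_COLUMNS[:6]
    out["framewise_displacement"] = fd_series
    out.to_csv(path, sep="\t", index=False)


def read_confounds(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    missing = set(CONFOUND_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"confounds file missing columns: {sorted(missing)}")
    return df[CONFOUND_COLUMNS[:6]], df["framewise_displacement"].to_numpy()


def write_roi_timeseries(ts: pd.DataFrame, path: str | Path) -> None:
    ts.to_csv(path, index=False)


def read_roi_timeseries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_scan(scan, out_dir: str | Path) -> None:
    """Write one scan record as events/confounds/timeseries text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = scan.scan_id
    write_events(scan.design.events_frame(), out / f"{stem}_events.tsv")
    write_confounds(
        scan.realignment_params, scan.fd_series, out / f"{stem}_confounds.tsv"
    )
    write_roi_timeseries(scan.roi_timeseries, out / f"{stem}_timeseries.csv")


def write_study(study, out_dir: str | Path) -> None:
    """Write a full simulated study (cohort CSV plus per-scan files)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.cohort.to_csv(out / "cohort.csv", index=False)
    study.scan_table().to_csv(out / "scans.csv", index=False)
    for scan in study.scans:
        write_scan(scan, out / "scans")
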