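"""Detection records, independence filtering, occasion matrices, survey summaries.

Raw camera-trap triggers are collapsed into *independent detections* with a
sliding time rule: a record counts as independent iff it is the station's
first record or falls at least ``gap_minutes`` (default 30) after the
immediately preceding raw record at that station. Independent detections are
then binned into fixed-length occasions (default 5-day windows) anchored at
each station's own deployment start, giving the station x occasion 0/1
matrix that the occupancy models consume. Occasions past a station's last
active day are missing (NaN).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DetectionHistory",
    "filter_independent",
    "build_history",
    "survey_summary",
    "summarize_sites",
]


@dataclass
class DetectionHistory:
    """Station x occasion detection/non-detection matrix.

    Attributes
    ----------
    matrix : DataFrame
        Rows indexed by station_id, columns ``occ_1..occ_m``; cells are
        1.0 (detected), 0.0 (not detected) or NaN (station inactive).
    window_days : int
        Occasion length in days.
    occasion_spans : dict
        station_id -> list of (start_date, end_date) ISO date strings per
        occasion, inclusive on both ends.
    """

    matrix: pd.DataFrame
    window_days: int
    occasion_spans: dict

    @property
    def n_stations(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.matrix.shape[1]

    def detections(self) -> pd.Series:
        """Number of occasions with a detection, per station."""
        return self.matrix.sum(axis=1, skipna=True)

    def occasions_observed(self) -> pd.Series:
        """Number of non-missing occasions, per station."""
        return self.matrix.notna().sum(axis=1)

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        out = self.matrix.copy()
        out.index.name = "station_id"
        out.to_csv(path, na_rep="NA")
        if sidecar is not None:
            payload = {"window_days": self.window_days, "occasion_spans": self.occasion_spans}
            Path(sidecar).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path, sidecar: str | Path) -> "DetectionHistory":
        matrix = pd.read_csv(path, index_col="station_id", na_values=["NA"])
        payload = json.loads(Path(sidecar).read_text())
        return cls(matrix, int(payload["window_days"]), payload["occasion_spans"])


def _parse_timestamps(records: pd.DataFrame) -> pd.Series:
    ts = pd.to_datetime(records["timestamp"], format="ISO8601", errors="coerce")
    bad = ts.isna() & records["timestamp"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unparseable timestamp {records['timestamp'].iloc[row]!r} at row {row}"
        )
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise ValueError(f"missing timestamp at row {row}")
    return ts


def filter_independent(records: pd.DataFrame, gap_minutes: float = 30) -> pd.DataFrame:
    """Collapse clustered triggers into independent detections (sliding rule).

    Per station, a record is retained iff it is the first record or its
    timestamp is >= ``gap_minutes`` after the *immediately preceding raw
    record* at that station (a gap of exactly ``gap_minutes`` counts as
    independent). Output is sorted by (station_id, timestamp).
    """
    if records.empty:
        return records.copy()
    rec = records.copy()
    rec["timestamp"] = _parse_timestamps(rec)
    rec = rec.sort_values(["station_id", "timestamp"], kind="stable").reset_index(drop=True)
    gap = pd.Timedelta(minutes=gap_minutes)
    prev_ts = rec.groupby("station_id")["timestamp"].shift(1)
    keep = prev_ts.isna() | ((rec["timestamp"] - prev_ts) >= gap)
    return rec.loc[keep].reset_index(drop=True)


def _deployment_days(dep: pd.DataFrame) -> pd.Series:
    start = pd.to_datetime(dep["start_date"])
    end = pd.to_datetime(dep["end_date"])
    days = (end - start).dt.days + 1
    if (days < 1).any():
        bad = dep.loc[days < 1, "station_id"].iloc[0]
        raise ValueError(f"station {bad!r} has end_date before start_date")
    return days


def build_history(
    records: pd.DataFrame,
    deployments: pd.DataFrame,
    window_days: int = 5,
    drop_partial: bool = False,
) -> DetectionHistory:
    """Bin independence-filtered records into per-station occasion matrices.

    Occasion k of a station spans deployment days [k*w, (k+1)*w) counted from
    that station's own start date; a trailing partial window with at least one
    active day is kept as an occasion unless ``drop_partial``. Stations are
    padded with NaN to the maximum occasion count.

    Raises
    ------
    ValueError
        If a record falls outside its station's deployment span.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    dep = deployments.sort_values("station_id").reset_index(drop=True)
    days = _deployment_days(dep)
    n_occ = (
        np.floor(days / window_days) if drop_partial else np.ceil(days / window_days)
    ).astype(int)
    n_occ = np.maximum(n_occ, 0)
    max_occ = int(n_occ.max())

    starts = pd.to_datetime(dep["start_date"]).reset_index(drop=True)
    station_ids = dep["station_id"].tolist()
    mat = np.full((len(dep), max_occ), np.nan)
    spans: dict[str, list] = {}
    for i, sid in enumerate(station_ids):
        mat[i, : n_occ[i]] = 0.0
        spans[sid] = []
        for k in range(n_occ[i]):
            d0 = k * window_days
            d1 = min((k + 1) * window_days, int(days[i])) - 1
            spans[sid].append(
                [
                    (starts[i] + pd.Timedelta(days=d0)).date().isoformat(),
                    (starts[i] + pd.Timedelta(days=d1)).date().isoformat(),
                ]
            )

    if not records.empty:
        rec = records.copy()
        rec["timestamp"] = _parse_timestamps(rec)
        idx = {sid: i for i, sid in enumerate(station_ids)}
        start_by = {sid: starts[i] for i, sid in enumerate(station_ids)}
        days_by = {sid: int(days[i]) for i, sid in enumerate(station_ids)}
        for sid, ts in zip(rec["station_id"], rec["timestamp"]):
            if sid not in idx:
                raise ValueError(f"record at station {sid!r} has no deployment")
            day = (ts.normalize() - start_by[sid].normalize()).days
            if day < 0 or day >= days_by[sid]:
                raise ValueError(
                    f"record at station {sid!r} on {ts.date()} is outside "
                    f"the deployment span"
                )
            k = day // window_days
            if k < n_occ[idx[sid]]:
                mat[idx[sid], k] = 1.0

    matrix = pd.DataFrame(
        mat, index=pd.Index(station_ids, name="station_id"),
        columns=[f"occ_{k + 1}" for k in range(max_occ)],
    )
    return DetectionHistory(matrix, window_days, spans)


def summarize_sites(site_table: pd.DataFrame) -> dict:
    """Derived survey statistics from a per-site effort table.

    ``site_table`` needs columns ``site``, ``trap_nights``, ``n_stations``,
    ``detections``, ``occupied_stations``. Returns the table augmented with
    encounter rate (independent detections per 100 trap nights, 1 decimal)
    and naive occupancy (2 decimals), plus grand totals and across-site
    mean/SD (population SD, divisor n) of effort and detections.
    """
    t = site_table.copy()
    if (t["trap_nights"] <= 0).any():
        bad = t.loc[t["trap_nights"] <= 0, "site"].iloc[0]
        raise ValueError(f"site {bad!r} has zero trap nights")
    t["encounter_rate"] = (100.0 * t["detections"] / t["trap_nights"]).round(1)
    t["naive_occupancy"] = (t["occupied_stations"] / t["n_stations"]).round(2)
    tn = t["trap_nights"].to_numpy(dtype=float)
    det = t["detections"].to_numpy(dtype=float)
    return {
        "table": t,
        "total_trap_nights": float(tn.sum()),
        "total_detections": float(det.sum()),
        "total_stations": int(t["n_stations"].sum()),
        "mean_trap_nights": float(tn.mean()),
        "sd_trap_nights": float(tn.std(ddof=0)),
        "mean_detections": float(det.mean()),
        "sd_detections": float(det.std(ddof=0)),
    }


def survey_summary(records: pd.DataFrame, deployments: pd.DataFrame) -> dict:
    """Per-site survey effort, detections, encounter rate and naive occupancy.

    ``records`` must already be independence-filtered. Trap nights are summed
    station active days; the encounter rate is detections per 100 trap nights.
    """
    dep = deployments.copy()
    dep["active_days"] = _deployment_days(dep)
    if records.empty:
        counts = pd.Series(0, index=dep["station_id"])
    else:
        counts = records.groupby("station_id").size()
    dep["detections"] = dep["station_id"].map(counts).fillna(0).astype(int)
    per_site = (
        dep.groupby("site")
        .agg(
            trap_nights=("active_days", "sum"),
            n_stations=("station_id", "count"),
            detections=("detections", "sum"),
            occupied_stations=("detections", lambda s: int((s > 0).sum())),
        )
        .reset_index()
    )
    return summarize_sites(per_site)
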