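"""Detection-log data model, readers/writers, and cleaning rules.

Passive acoustic telemetry produces detection logs: one row per decoded
tag transmission at a moored receiver.  Before any residency or movement
metric is computed the logs are cleaned in two steps:

1. *False-detection removal* -- a receiver that logs a tag exactly once
   in a calendar day is treated as a possible code collision and that
   single detection is discarded.
2. *Minimum-days filter* -- animals detected on fewer than a minimum
   number of distinct days (default 5) carry too little information and
   are excluded from analysis.

Receivers moored within about a kilometre of each other cannot be told
apart by a moving animal, so closely spaced stations are merged into
single network *nodes* for movement analysis, while the original
station identities are retained for the roaming index (which is defined
against the physical receiver count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DetectionSet",
    "NodeMap",
    "assign_size_class",
    "read_detections",
    "write_detections",
    "remove_false_detections",
    "apply_minimum_days_filter",
    "merge_receiver_nodes",
    "default_station_ids",
    "default_node_map",
    "load_table1",
]

EVENT_COLUMNS = ["timestamp", "receiver_id", "transmitter_id"]

#: Sex-specific total-length (cm) breakpoints separating the juvenile (A),
#: subadult (B) and mature (C) life-history stages.  The B range is
#: inclusive on both ends.
SIZE_CLASS_BREAKS = {"F": (150.0, 180.0), "M": (130.0, 160.0)}


def assign_size_class(sex: str, tl: float) -> str:
    """Assign life-history stage A/B/C from sex and total length (cm).

    Females: A < 150, 150 <= B <= 180, C > 180.
    Males:   A < 130, 130 <= B <= 160, C > 160.
    """
    if sex not in SIZE_CLASS_BREAKS:
        raise ValueError(f"unknown sex {sex!r}; expected 'F' or 'M'")
    if not np.isfinite(tl) or tl <= 0:
        raise ValueError(f"total length must be positive, got {tl!r}")
    lo, hi = SIZE_CLASS_BREAKS[sex]
    if tl < lo:
        return "A"
    if tl <= hi:
        return "B"
    return "C"


@dataclass(frozen=True)
class NodeMap:
    """Surjective mapping from receiver stations onto network nodes.

    Stations that are merged share a node id; every station must be
    mapped.  ``node_ids`` preserves first-appearance order.
    """

    mapping: Mapping[str, str]

    @property
    def node_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for node in self.mapping.values():
            seen.setdefault(node, None)
        return list(seen)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def node_of(self, receiver_id: str) -> str:
        try:
            return self.mapping[str(receiver_id)]
        except KeyError:
            raise KeyError(f"station {receiver_id!r} is not covered by the node map")

    @classmethod
    def identity(cls, station_ids: Iterable[str]) -> "NodeMap":
        return cls({str(s): str(s) for s in station_ids})


def default_station_ids() -> list[str]:
    """The default 18-station array labelling: '1'..'19' with '17' unused."""
    return [str(i) for i in range(1, 20) if i != 17]


def default_node_map(station_ids: Sequence[str] | None = None) -> NodeMap:
    """Default node map: stations 15+16 and 18+19 merged, 16 nodes from 18.

    The pairs sit less than a kilometre apart (the two Blue Hole
    receivers, and the two at the northeastern point), close enough that
    presence at one cannot be distinguished from presence at the other.
    """
    if station_ids is None:
        station_ids = default_station_ids()
    merged = {"15": "15_16", "16": "15_16", "18": "18_19", "19": "18_19"}
    return NodeMap({str(s): merged.get(str(s), str(s)) for s in station_ids})


@dataclass
class DetectionSet:
    """A cleaned (or cleanable) set of detections plus its metadata.

    Attributes
    ----------
    events : DataFrame with columns ``timestamp`` (tz-aware UTC),
        ``receiver_id``, ``transmitter_id`` and, after node merging,
        ``node_id``.  Sorted by timestamp (ties by receiver_id, then
        input order).
    stations : DataFrame with ``receiver_id``, ``lat``, ``lon``, ``depth_m``.
    sharks : DataFrame with ``shark_id``, ``sex``, ``tl_cm``,
        ``date_tagged``, ``capture_date``, ``size_class``.
    filter_log : per-rule record of removed rows.
    parse_errors : row-level diagnostics from reading.
    quarantined : events whose receiver is absent from the station table.
    """

    events: pd.DataFrame
    stations: pd.DataFrame
    sharks: pd.DataFrame
    filter_log: pd.DataFrame = field(
        default_factory=lambda: _empty_filter_log()
    )
    parse_errors: list = field(default_factory=list)
    quarantined: pd.DataFrame | None = None
    node_map: NodeMap | None = None

    def __post_init__(self) -> None:
        self.events = _sort_events(self.events)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def shark_ids(self) -> list[str]:
        return sorted(self.events["transmitter_id"].unique())

    def events_for(self, shark_id: str) -> pd.DataFrame:
        return self.events[self.events["transmitter_id"] == str(shark_id)]


def _empty_filter_log() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["rule", "shark_id", "receiver_id", "day", "rows_removed"]
    )


def _sort_events(events: pd.DataFrame) -> pd.DataFrame:
    ev = events.copy()
    if "_order" not in ev.columns:
        ev["_order"] = np.arange(len(ev))
    ev = ev.sort_values(
        ["timestamp", "receiver_id", "_order"], kind="mergesort"
    ).reset_index(drop=True)
    return ev


def _parse_timestamps(raw: pd.Series) -> pd.Series:
    ts = pd.to_datetime(raw, errors="coerce", utc=True, format="mixed")
    # store at second resolution; sub-second precision is not meaningful
    return ts.dt.floor("s")


def read_stations(path) -> pd.DataFrame:
    st = pd.read_csv(path, dtype={"receiver_id": str})
    required = {"receiver_id", "lat", "lon"}
    missing = required - set(st.columns)
    if missing:
        raise ValueError(f"stations file missing columns {sorted(missing)}")
    if st["receiver_id"].duplicated().any():
        raise ValueError("duplicate receiver_id in station table")
    bad = st[(st.lat.abs() > 90) | (st.lon.abs() > 180)]
    if len(bad):
        raise ValueError(f"station coordinates out of range: {bad.receiver_id.tolist()}")
    if "depth_m" not in st.columns:
        st["depth_m"] = np.nan
    return st.reset_index(drop=True)


def read_sharks(path) -> pd.DataFrame:
    sh = pd.read_csv(path, dtype={"shark_id": str})
    sh["date_tagged"] = pd.to_datetime(sh["date_tagged"])
    if "capture_date" in sh.columns:
        sh["capture_date"] = pd.to_datetime(sh["capture_date"])
    else:
        sh["capture_date"] = pd.NaT
    if "size_class" not in sh.columns:
        sh["size_class"] = [
            assign_size_class(s, t) for s, t in zip(sh["sex"], sh["tl_cm"])
        ]
    return sh


def read_detections(path, stations=None, sharks=None) -> DetectionSet:
    """Read a detection CSV (columns timestamp, receiver_id, transmitter_id).

    Unparseable timestamps are rejected row by row and reported in
    ``parse_errors`` as ``(line_number, message)`` (line numbers count the
    header as line 1).  Detections at receivers absent from the station
    table are moved to ``quarantined`` with a warning.
    """
    raw = pd.read_csv(path, dtype={"receiver_id": str, "transmitter_id": str})
    missing = set(EVENT_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"detections file missing columns {sorted(missing)}")
    ts = _parse_timestamps(raw["timestamp"])
    bad = ts.isna() & raw["timestamp"].notna()
    parse_errors = [
        (int(i) + 2, f"unparseable timestamp {raw['timestamp'].iloc[i]!r}")
        for i in np.flatnonzero(bad.to_numpy())
    ]
    events = raw.loc[~bad, EVENT_COLUMNS].copy()
    events["timestamp"] = ts[~bad]

    if stations is not None and not isinstance(stations, pd.DataFrame):
        stations = read_stations(stations)
    if sharks is not None and not isinstance(sharks, pd.DataFrame):
        sharks = read_sharks(sharks)
    if stations is None:
        stations = pd.DataFrame(
            {"receiver_id": sorted(events["receiver_id"].unique())}
        ).assign(lat=np.nan, lon=np.nan, depth_m=np.nan)
    if sharks is None:
        sharks = pd.DataFrame(
            {"shark_id": sorted(events["transmitter_id"].unique())}
        )

    quarantined = None
    known = set(stations["receiver_id"].astype(str))
    unknown_mask = ~events["receiver_id"].isin(known)
    if unknown_mask.any():
        quarantined = events[unknown_mask].reset_index(drop=True)
        events = events[~unknown_mask]
        warnings.warn(
            f"{len(quarantined)} detections at unknown receivers quarantined: "
            f"{sorted(quarantined['receiver_id'].unique())}",
            stacklevel=2,
        )
    return DetectionSet(
        events=events.reset_index(drop=True),
        stations=stations,
        sharks=sharks,
        parse_errors=parse_errors,
        quarantined=quarantined,
    )


def write_detections(ds: DetectionSet, outdir) -> dict:
    """Write detections/stations/sharks/filter-log CSVs; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    ev = ds.events[EVENT_COLUMNS].copy()
    ev["timestamp"] = ev["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    paths["detections"] = outdir / "detections.csv"
    ev.to_csv(paths["detections"], index=False)
    paths["stations"] = outdir / "stations.csv"
    ds.stations.to_csv(paths["stations"], index=False, float_format="%.6f")
    paths["sharks"] = outdir / "sharks.csv"
    sh = ds.sharks.copy()
    for col in ("date_tagged", "capture_date"):
        if col in sh.columns:
            sh[col] = pd.to_datetime(sh[col]).dt.strftime("%Y-%m-%d")
    sh.to_csv(paths["sharks"], index=False)
    paths["filter_log"] = outdir / "filter_log.csv"
    ds.filter_log.to_csv(paths["filter_log"], index=False)
    return paths


def _day_of(events: pd.DataFrame, tz_offset_hours: float = 0.0) -> pd.Series:
    """Calendar day of each event, after shifting by a fixed UTC offset."""
    ts = events["timestamp"]
    if tz_offset_hours:
        ts = ts + pd.Timedelta(hours=tz_offset_hours)
    return ts.dt.floor("D")


def remove_false_detections(
    ds: DetectionSet,
    scope: str = "receiver-day",
    tz_offset_hours: float = 0.0,
) -> DetectionSet:
    """Drop single detections per calendar day, the false-detection screen.

    ``scope='receiver-day'`` (default) drops every (animal, receiver, day)
    group holding exactly one detection; ``scope='array-day'`` applies the
    rule per (animal, day) across the whole array.  Idempotent: groups of
    two or more are never touched, so a second pass removes nothing.
    """
    if scope not in ("receiver-day", "array-day"):
        raise ValueError(f"unknown scope {scope!r}")
    ev = ds.events
    if not len(ev):
        return replace(ds, events=ev.copy(), filter_log=ds.filter_log.copy())
    day = _day_of(ev, tz_offset_hours)
    keys = ["transmitter_id", "receiver_id"] if scope == "receiver-day" else ["transmitter_id"]
    grouped = ev.assign(_day=day).groupby(keys + ["_day"], observed=True, sort=False)
    sizes = grouped["timestamp"].transform("size")
    singleton = sizes == 1
    removed = ev[singleton].assign(_day=day[singleton])
    log_rows = removed.groupby(
        ["transmitter_id", "receiver_id", "_day"], observed=True
    ).size()
    log = pd.DataFrame(
        {
            "rule": "single-detection-" + scope,
            "shark_id": log_rows.index.get_level_values(0),
            "receiver_id": log_rows.index.get_level_values(1),
            "day": log_rows.index.get_level_values(2).strftime("%Y-%m-%d"),
            "rows_removed": log_rows.to_numpy(),
        }
    )
    new_log = log if ds.filter_log.empty else pd.concat([ds.filter_log, log], ignore_index=True)
    return replace(
        ds, events=ev[~singleton].reset_index(drop=True), filter_log=new_log
    )


def detection_days(
    ds: DetectionSet,
    min_detections_per_day: int = 2,
    tz_offset_hours: float = 0.0,
) -> pd.Series:
    """Count of qualifying detection days per animal.

    A day qualifies when the animal was logged at least
    ``min_detections_per_day`` times anywhere in the array (the daily
    occurrence rule; default twice per day).
    """
    ev = ds.events
    if not len(ev):
        return pd.Series(dtype=int, name="days_detected")
    day = _day_of(ev, tz_offset_hours)
    per_day = ev.assign(_day=day).groupby(
        ["transmitter_id", "_day"], observed=True
    ).size()
    ok = per_day[per_day >= min_detections_per_day]
    counts = ok.groupby(level=0, observed=True).size()
    counts.name = "days_detected"
    return counts


def apply_minimum_days_filter(
    ds: DetectionSet,
    min_days: int = 5,
    min_detections_per_day: int = 2,
    tz_offset_hours: float = 0.0,
) -> tuple[DetectionSet, list[str]]:
    """Exclude animals detected on fewer than ``min_days`` distinct days.

    Returns the retained DetectionSet and the excluded transmitter ids
    (animals with zero qualifying days are excluded too, including tagged
    animals never detected at all).  Run after false-detection removal.
    """
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    days = detection_days(ds, min_detections_per_day, tz_offset_hours)
    tagged = set(ds.sharks["shark_id"].astype(str)) if "shark_id" in ds.sharks else set()
    detected = set(ds.events["transmitter_id"].unique())
    all_ids = sorted(tagged | detected)
    excluded = [
        sid for sid in all_ids if int(days.get(sid, 0)) < min_days
    ]
    keep = ~ds.events["transmitter_id"].isin(excluded)
    removed = ds.events[~keep]
    log = pd.DataFrame(
        {
            "rule": "min-days",
            "shark_id": removed.groupby("transmitter_id", observed=True).size().index,
            "receiver_id": "*",
            "day": "*",
            "rows_removed": removed.groupby("transmitter_id", observed=True)
            .size()
            .to_numpy(),
        }
    )
    sharks = ds.sharks
    if "shark_id" in sharks:
        sharks = sharks[~sharks["shark_id"].astype(str).isin(excluded)].reset_index(
            drop=True
        )
    if log.empty:
        new_log = ds.filter_log.copy()
    elif ds.filter_log.empty:
        new_log = log
    else:
        new_log = pd.concat([ds.filter_log, log], ignore_index=True)
    retained = replace(
        ds,
        events=ds.events[keep].reset_index(drop=True),
        sharks=sharks,
        filter_log=new_log,
    )
    return retained, excluded


def merge_receiver_nodes(ds: DetectionSet, node_map: NodeMap | None = None) -> DetectionSet:
    """Label every event with its network node, keeping station identity.

    Adds a ``node_id`` column (events are otherwise untouched: count and
    timestamps preserved).  Raises on any station the map does not cover.
    """
    if node_map is None:
        node_map = default_node_map(ds.stations["receiver_id"].astype(str))
    ev = ds.events.copy()
    rx = ev["receiver_id"]
    unmapped = set(map(str, rx.unique())) - set(node_map.mapping)
    if unmapped:
        raise KeyError(f"stations not covered by node map: {sorted(unmapped)}")
    if isinstance(rx.dtype, pd.CategoricalDtype):
        # map via category codes: cheap on multi-million-row logs
        vals = np.array([node_map.mapping[str(c)] for c in rx.cat.categories], dtype=object)
        ev["node_id"] = pd.Categorical(vals[rx.cat.codes])
    else:
        ev["node_id"] = rx.astype(str).map(node_map.mapping)
    return replace(ds, events=ev, node_map=node_map)


def load_table1() -> pd.DataFrame:
    """Load the packaged per-shark summary table (77 animals).

    One row per tagged shark retained by the 5-day filter, with the
    published sex, size class, tagging date, total length, days detected,
    receivers visited, residency indices, roaming index and core activity
    space (50% kernel-density area, km^2; missing where the animal lacked
    sufficient relocations).  Shark ids are unique only jointly with sex
    (one id was issued to one animal of each sex), so a composite ``uid``
    column is provided.
    """
    with resources.files("atollnet.data").joinpath("table1.csv").open("rb") as fh:
        df = pd.read_csv(fh, dtype={"shark_id": str})
    df["date_tagged"] = pd.to_datetime(df["date_tagged"])
    df["uid"] = df["shark_id"] + "_" + df["sex"]
    if df["uid"].duplicated().any():
        raise AssertionError("fixture (shark_id, sex) keys are not unique")
    return df
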