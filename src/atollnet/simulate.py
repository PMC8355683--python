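"""Synthetic acoustic-telemetry cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be tested end to end without field data:

* an 18-station ring array (two closely spaced mergeable pairs -> 16
  nodes) with ~5.5 km mean nearest-neighbour spacing;
* per-animal hourly movement drawn from a sex-by-size-class Markov
  kernel over the 16 nodes plus an ABSENT state -- exactly the state
  space the movement-chain estimator works on, making parameter
  recovery a clean test;
* detections emitted while present as a thinned regular transmission
  process (nominal 90 s interval, per-slot detection probability);
* optional planted single-detection receiver-days that exercise the
  false-detection screen, with full bookkeeping.

Everything derives deterministically from the master seed; each animal
draws from its own seed substream so cohorts are reproducible
regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DetectionSet, NodeMap, assign_size_class, default_node_map, default_station_ids
from .edmc import ABSENT

__all__ = [
    "GroupParams",
    "SimulationConfig",
    "GroundTruth",
    "build_group_kernel",
    "simulate_array",
    "simulate_tracks",
    "simulate_detections",
    "simulate_cohort",
    "recovery_report",
    "paper_like_config",
]

#: cohort composition of the study population (sex, size class) -> count
STUDY_COMPOSITION = {
    ("F", "A"): 14, ("F", "B"): 5, ("F", "C"): 20,
    ("M", "A"): 10, ("M", "B"): 9, ("M", "C"): 19,
}

#: total-length draw ranges (cm) per sex and size class
TL_RANGES = {
    ("F", "A"): (96.0, 149.0), ("F", "B"): (150.0, 180.0), ("F", "C"): (181.0, 233.0),
    ("M", "A"): (96.0, 129.0), ("M", "B"): (130.0, 160.0), ("M", "C"): (161.0, 210.0),
}


@dataclass(frozen=True)
class GroupParams:
    """Hourly movement-bout parameters of one sex-by-size-class group.

    ``p_leave``: present -> absent per hour (1/mean present-bout hours).
    ``p_exit_absent``: absent -> present per hour (1/mean absent-bout h).
    ``p_move``: present -> a different node per hour.
    ``home_bias``: share of re-entry mass directed to the group's home
    node (the rest spreads uniformly over all nodes).
    """

    p_leave: float
    p_exit_absent: float
    p_move: float = 0.06
    home_node: int = 0
    home_bias: float = 0.5

    def stationary_absent(self) -> float:
        """Long-run absent fraction of the two-state presence process."""
        return self.p_leave / (self.p_leave + self.p_exit_absent)


#: Default per-group bout parameters.  Chosen from the two-state
#: occupancy closed form so long-run absent fractions span ~0.86-0.95
#: (mature females the most present) and so multi-day absences keep the
#: fraction of detected days well under one half for most animals.
DEFAULT_GROUP_PARAMS = {
    ("F", "A"): GroupParams(0.20, 0.013, 0.06, home_node=10),
    ("F", "B"): GroupParams(0.18, 0.011, 0.07, home_node=11),
    ("F", "C"): GroupParams(0.12, 0.020, 0.04, home_node=4),
    ("M", "A"): GroupParams(0.22, 0.012, 0.07, home_node=10),
    ("M", "B"): GroupParams(0.20, 0.012, 0.06, home_node=12),
    ("M", "C"): GroupParams(0.18, 0.013, 0.05, home_node=9),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic cohort; the seed fixes everything."""

    seed: int = 0
    group_sizes: dict = field(default_factory=lambda: dict(STUDY_COMPOSITION))
    group_params: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_PARAMS))
    kernels: dict | None = None  # optional explicit per-group kernels
    detection_prob: float = 0.8
    transmit_interval_s: float = 90.0
    tag_life_days: int = 1877
    study_start: str = "2007-04-23"
    study_end: str = "2014-05-09"
    tagging_end: str = "2009-05-11"
    singleton_rate: float = 0.0  # planted false-detection rate per receiver-day
    array_center: tuple = (17.19, -87.53)
    pair_separation_km: float = 0.9
    mean_nn_spacing_km: float = 5.5
    max_duration_days: int | None = None  # cap per-animal simulated span

    def __post_init__(self):
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in [0, 1]")
        if self.transmit_interval_s <= 0 or self.tag_life_days <= 0:
            raise ValueError("interval and tag life must be positive")


@dataclass
class GroundTruth:
    """Generator bookkeeping: everything the pipeline should recover."""

    sharks: pd.DataFrame
    state_labels: list[str]
    states: dict  # shark_id -> (start_hour Timestamp, int16 array of labels)
    kernels: dict  # (sex, size_class) -> DataFrame over state_labels
    config: SimulationConfig
    planted_singletons: pd.DataFrame | None = None
    month_day_counts: dict = field(default_factory=dict)  # shark_id -> Series

    def occupancy(self, shark_id: str) -> pd.Series:
        """Empirical fraction of hours per state for one animal."""
        _, arr = self.states[shark_id]
        counts = np.bincount(arr, minlength=len(self.state_labels))
        return pd.Series(counts / counts.sum(), index=self.state_labels)

    def true_days_detected(self, shark_id: str) -> int:
        return int(self.month_day_counts[shark_id].sum()) if shark_id in self.month_day_counts else 0


def simulate_array(cfg: SimulationConfig | None = None) -> tuple[pd.DataFrame, NodeMap]:
    """The default 18-station ring array with two mergeable pairs.

    Sixteen node positions sit on a ring whose chord is solved so the
    18-station mean nearest-neighbour spacing equals the configured
    value (default 5.5 km); the stations of each merged pair (15+16 and
    18+19) are split ``pair_separation_km`` apart.  Station labels are
    '1'..'19' with '17' unused.  The layout is deterministic.
    """
    cfg = cfg or SimulationConfig()
    node_map = default_node_map()
    nodes = node_map.node_ids
    n_nodes = len(nodes)
    pair_sep = cfg.pair_separation_km
    n_pairs = sum(1 for n in nodes if "_" in n)
    n_single = 18 - 2 * n_pairs
    chord = (18 * cfg.mean_nn_spacing_km - 2 * n_pairs * pair_sep) / n_single
    if chord <= pair_sep:
        raise ValueError("degenerate layout: ring chord not larger than pair separation")
    radius = chord / (2 * np.sin(np.pi / n_nodes))
    theta = 2 * np.pi * np.arange(n_nodes) / n_nodes
    nx_km = radius * np.cos(theta)
    ny_km = radius * np.sin(theta)
    rows = []
    for i, node in enumerate(nodes):
        members = [s for s, n in node_map.mapping.items() if n == node]
        if len(members) == 1:
            offsets = [(0.0, 0.0)]
        else:
            # split the pair tangentially about the node position
            tx, ty = -np.sin(theta[i]), np.cos(theta[i])
            d = pair_sep / 2
            offsets = [(-d * tx, -d * ty), (d * tx, d * ty)]
        for station, (ox, oy) in zip(sorted(members, key=int), offsets):
            rows.append({"receiver_id": station, "x_km": nx_km[i] + ox, "y_km": ny_km[i] + oy})
    st = pd.DataFrame(rows)
    lat0, lon0 = cfg.array_center
    km_per_deg = np.pi * 2 * 6371.0088 / 360.0
    st["lat"] = lat0 + st["y_km"] / km_per_deg
    st["lon"] = lon0 + st["x_km"] / (km_per_deg * np.cos(np.radians(lat0)))
    st["depth_m"] = np.round(8 + 17 * (np.arange(len(st)) % 7) / 6.0, 1)
    st = st.sort_values("receiver_id", key=lambda s: s.astype(int), ignore_index=True)
    return st[["receiver_id", "lat", "lon", "depth_m"]], node_map


def build_group_kernel(
    params: GroupParams, nodes: list[str]
) -> pd.DataFrame:
    """Hourly transition kernel over nodes + ABSENT from bout parameters.

    While present the animal stays at its node, hops to a ring neighbour
    (80% of the move mass) or any other node (20%), or departs to
    ABSENT.  From ABSENT it re-enters at the home node with probability
    ``home_bias`` of the exit mass, else uniformly.
    """
    n = len(nodes)
    states = list(nodes) + [ABSENT]
    K = np.zeros((n + 1, n + 1))
    for i in range(n):
        stay = 1.0 - params.p_leave - params.p_move
        if stay < 0:
            raise ValueError("p_leave + p_move exceeds 1")
        K[i, i] = stay
        K[i, n] = params.p_leave
        neigh = [(i - 1) % n, (i + 1) % n]
        others = [j for j in range(n) if j != i]
        for j in neigh:
            K[i, j] += 0.8 * params.p_move / len(neigh)
        for j in others:
            K[i, j] += 0.2 * params.p_move / len(others)
    K[n, n] = 1.0 - params.p_exit_absent
    enter = np.full(n, (1.0 - params.home_bias) * params.p_exit_absent / n)
    enter[params.home_node % n] += params.home_bias * params.p_exit_absent
    K[n, :n] = enter
    return pd.DataFrame(K, index=states, columns=states)


def _shark_rng(seed: int, index: int) -> np.random.Generator:
    # per-animal substream: reproducible independent of generation order
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _make_sharks(cfg: SimulationConfig, nodes: list[str]) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 10_000_000]))
    start = pd.Timestamp(cfg.study_start)
    tag_end = pd.Timestamp(cfg.tagging_end)
    span_days = (tag_end - start).days
    rows = []
    idx = 0
    for (sex, cls), n in sorted(cfg.group_sizes.items()):
        lo, hi = TL_RANGES[(sex, cls)]
        for _ in range(n):
            tl = float(np.round(rng.uniform(lo, hi) * 2) / 2)
            tagged = start + pd.Timedelta(days=int(rng.integers(0, span_days + 1)))
            rows.append(
                {
                    "shark_id": f"S{idx:03d}",
                    "sex": sex,
                    "size_class": assign_size_class(sex, tl),
                    "tl_cm": tl,
                    "date_tagged": tagged,
                    "capture_date": pd.NaT,
                    "index": idx,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def simulate_tracks(cfg: SimulationConfig | None = None) -> GroundTruth:
    """Draw each animal's hourly state sequence from its group kernel.

    States run from the tagging hour to the earlier of tag death and
    study end (optionally capped at ``max_duration_days``), starting at
    a random node.
    """
    cfg = cfg or SimulationConfig()
    _, node_map = simulate_array(cfg)
    nodes = node_map.node_ids
    n_nodes = len(nodes)
    labels = nodes + [ABSENT]
    kernels = {}
    for group in cfg.group_sizes:
        if cfg.kernels and group in cfg.kernels:
            K = pd.DataFrame(cfg.kernels[group])
            if list(K.index) != labels:
                K.index = labels
                K.columns = labels
        else:
            K = build_group_kernel(cfg.group_params[group], nodes)
        if not np.allclose(K.to_numpy().sum(axis=1), 1.0):
            raise ValueError(f"kernel for group {group} is not row-stochastic")
        kernels[group] = K
    sharks = _make_sharks(cfg, nodes)
    study_end = pd.Timestamp(cfg.study_end)
    states = {}
    for _, sh in sharks.iterrows():
        rng = _shark_rng(cfg.seed, int(sh["index"]))
        tagged = sh["date_tagged"]
        end = min(tagged + pd.Timedelta(days=cfg.tag_life_days), study_end)
        if cfg.max_duration_days is not None:
            end = min(end, tagged + pd.Timedelta(days=cfg.max_duration_days))
        n_hours = int((end - tagged) / pd.Timedelta(hours=1))
        K = kernels[(sh["sex"], sh["size_class"])].to_numpy()
        cum = np.cumsum(K, axis=1)
        us = rng.random(n_hours)
        seq = np.empty(n_hours, dtype=np.int16)
        s = int(rng.integers(0, n_nodes))
        for t in range(n_hours):
            s = int(np.searchsorted(cum[s], us[t], side="right"))
            seq[t] = s
        start_hour = tagged.tz_localize("UTC") if tagged.tzinfo is None else tagged
        states[sh["shark_id"]] = (start_hour, seq)
    return GroundTruth(
        sharks=sharks, state_labels=labels, states=states, kernels=kernels, config=cfg
    )


def simulate_detections(truth: GroundTruth, cfg: SimulationConfig | None = None) -> DetectionSet:
    """Emit detections from the true states as a thinned 90 s process.

    Every present hour yields transmission slots at the nominal interval
    (40 slots per hour at 90 s) with a random sub-interval phase; each
    slot is detected with ``detection_prob``.  Hours at a merged node
    are assigned to one of the pair's stations (per hour).  Planted
    single-detection receiver-days are injected at ``singleton_rate``
    on receiver-days with no true detections, and recorded.

    Fills ``truth.month_day_counts`` (calendar days with >= 2 true
    detections, per month) and ``truth.planted_singletons``.
    """
    cfg = cfg or truth.config
    stations, node_map = simulate_array(cfg)
    nodes = node_map.node_ids
    n_nodes = len(nodes)
    interval = cfg.transmit_interval_s
    n_slots = int(np.floor(3600.0 / interval))
    members = {
        node: sorted((s for s, n in node_map.mapping.items() if n == node), key=int)
        for node in nodes
    }
    all_ts, all_rx, all_tx = [], [], []
    planted_rows = []
    hour_ns = np.int64(3_600_000_000_000)
    for _, sh in truth.sharks.iterrows():
        sid = sh["shark_id"]
        rng = _shark_rng(cfg.seed, 1_000_000 + int(sh["index"]))
        start_hour, seq = truth.states[sid]
        present = np.flatnonzero(seq < n_nodes)
        start_ns = start_hour.value
        if len(present):
            hour_starts = start_ns + present.astype(np.int64) * hour_ns
            phases = rng.uniform(0.0, interval, size=len(present))
            keep = rng.random((len(present), n_slots)) < cfg.detection_prob
            offs = (phases[:, None] + interval * np.arange(n_slots)[None, :]) * 1e9
            times = (hour_starts[:, None] + offs.astype(np.int64))[keep]
            # station choice: fixed per hour, random member for merged nodes
            stat_choice = rng.integers(0, 2, size=len(present))
            rx_hour = np.array(
                [
                    members[nodes[s]][c % len(members[nodes[s]])]
                    for s, c in zip(seq[present], stat_choice)
                ],
                dtype=object,
            )
            rx = np.repeat(rx_hour, keep.sum(axis=1))
            all_ts.append(times)
            all_rx.append(rx)
            all_tx.append(np.full(len(times), sid, dtype=object))
        # planted false singletons
        if cfg.singleton_rate > 0:
            n_days = int(np.ceil(len(seq) / 24))
            day_starts = start_hour.floor("D").value + np.arange(n_days) * 24 * hour_ns
            hits = np.argwhere(
                rng.random((n_days, len(stations))) < cfg.singleton_rate
            )
            if len(hits):
                # exclude receiver-days already holding true detections
                true_pairs = set()
                if len(present):
                    days_of = ((hour_starts - start_hour.floor("D").value) // (24 * hour_ns))
                    for d, r in zip(days_of, rx_hour):
                        true_pairs.add((int(d), r))
                rx_ids = stations["receiver_id"].to_numpy()
                for d, r_i in hits:
                    rx_id = rx_ids[r_i]
                    if (int(d), rx_id) in true_pairs:
                        continue
                    t = day_starts[d] + np.int64(rng.integers(0, 86_400)) * np.int64(1e9)
                    all_ts.append(np.array([t]))
                    all_rx.append(np.array([rx_id], dtype=object))
                    all_tx.append(np.array([sid], dtype=object))
                    planted_rows.append(
                        {
                            "shark_id": sid,
                            "receiver_id": rx_id,
                            "day": pd.Timestamp(day_starts[d], tz="UTC").strftime("%Y-%m-%d"),
                        }
                    )
    if all_ts:
        ts = pd.to_datetime(np.concatenate(all_ts), utc=True).floor("s")
        events = pd.DataFrame(
            {
                "timestamp": ts,
                # categorical labels keep groupbys cheap on multi-million-row logs
                "receiver_id": pd.Categorical(np.concatenate(all_rx)),
                "transmitter_id": pd.Categorical(np.concatenate(all_tx)),
            }
        )
    else:
        events = pd.DataFrame(columns=["timestamp", "receiver_id", "transmitter_id"])
        events["timestamp"] = pd.to_datetime(events["timestamp"], utc=True)
    truth.planted_singletons = pd.DataFrame(
        planted_rows, columns=["shark_id", "receiver_id", "day"]
    )
    _fill_month_day_counts(truth, events)
    sharks = truth.sharks.drop(columns=["index"])
    return DetectionSet(events=events, stations=stations, sharks=sharks)


def _fill_month_day_counts(truth: GroundTruth, events: pd.DataFrame) -> None:
    """True detection-day counts per month (days with >= 2 true detections)."""
    planted = truth.planted_singletons
    key = set(
        zip(planted["shark_id"], planted["receiver_id"], planted["day"])
    ) if planted is not None and len(planted) else set()
    truth.month_day_counts = {}
    if not len(events):
        return
    ev = events
    if key:
        day_str = ev["timestamp"].dt.strftime("%Y-%m-%d")
        is_planted = [
            (t, r, d) in key
            for t, r, d in zip(ev["transmitter_id"], ev["receiver_id"], day_str)
        ]
        ev = ev[~np.asarray(is_planted)]
    day = ev["timestamp"].dt.floor("D").dt.tz_localize(None)
    per_day = ev.assign(_day=day).groupby(["transmitter_id", "_day"], observed=True).size()
    good = per_day[per_day >= 2].reset_index(name="n")
    good["month"] = good["_day"].dt.to_period("M")
    for sid, grp in good.groupby("transmitter_id", observed=True):
        truth.month_day_counts[str(sid)] = grp.groupby("month").size()


def simulate_cohort(cfg: SimulationConfig | None = None) -> tuple[DetectionSet, GroundTruth]:
    """Convenience: tracks + detections in one call."""
    cfg = cfg or SimulationConfig()
    truth = simulate_tracks(cfg)
    ds = simulate_detections(truth, cfg)
    return ds, truth


def _parse_group(key) -> tuple[str, str]:
    if isinstance(key, tuple):
        return key
    parts = str(key).replace("_", "")
    if len(parts) != 2 or parts[0] not in "FM" or parts[1] not in "ABC":
        raise ValueError(f"cannot parse group key {key!r} (expected e.g. 'F_A')")
    return parts[0], parts[1]


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from plain (YAML-friendly) mappings.

    Group keys may be written 'F_A' / 'FA'; group_params values may be
    mappings of GroupParams fields.
    """
    d = dict(d)
    if "group_sizes" in d:
        d["group_sizes"] = {_parse_group(k): int(v) for k, v in d["group_sizes"].items()}
    if "group_params" in d:
        d["group_params"] = {
            _parse_group(k): (v if isinstance(v, GroupParams) else GroupParams(**v))
            for k, v in d["group_params"].items()
        }
    return SimulationConfig(**d)


def paper_like_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The study-emulating profile: 77 animals in the published sex-by-size
    composition, sparse presence, nominal 90 s transmissions over a
    1877 d tag life inside the 2007-2014 monitoring window."""
    return SimulationConfig(seed=seed, **overrides)


def empirical_group_matrix(ds: DetectionSet, truth: GroundTruth, group) -> pd.DataFrame:
    """Pooled empirical transition matrix of one group from a DetectionSet."""
    from .edmc import group_chain

    sharks = truth.sharks
    ids = sharks[
        (sharks["sex"] == group[0]) & (sharks["size_class"] == group[1])
    ]["shark_id"].tolist()
    return group_chain(ds, ids, label=f"{group[0]}{group[1]}", states=truth.state_labels).transition_matrix


def recovery_report(
    truth: GroundTruth,
    cleaned: DetectionSet,
    residency_table: pd.DataFrame | None = None,
    monthly: dict | None = None,
    group_matrices: dict | None = None,
    kd_coverage: bool = False,
) -> dict:
    """Compare pipeline outputs against the generator's ground truth.

    Reports max/mean absolute error of empirical transition matrices
    against the generating kernels, the residency-index bias against
    true detection-day counts, monthly-series exactness, planted-
    singleton removal accounting and (optionally) whether each animal's
    50% kernel-density core covers its true highest-occupancy node.
    Raises on unknown animal ids.
    """
    out: dict = {}
    known = set(truth.sharks["shark_id"])
    if residency_table is not None:
        bad = set(residency_table["shark_id"]) - known
        if bad:
            raise KeyError(f"residency table holds unknown ids {sorted(bad)}")
        errs = []
        for _, row in residency_table.iterrows():
            true_days = truth.true_days_detected(row["shark_id"])
            errs.append(abs(row["ri"] - true_days / truth.config.tag_life_days))
        out["ri_max_abs_error"] = float(max(errs)) if errs else float("nan")
    if monthly is not None:
        exact = 0
        total = 0
        for sid, series in monthly.items():
            if sid not in known:
                raise KeyError(f"unknown id {sid!r} in monthly series")
            true_counts = truth.month_day_counts.get(sid, pd.Series(dtype=int))
            total += 1
            days_in_month = series.index.days_in_month
            recon = (series * days_in_month).round().astype(int)
            tc = true_counts.reindex(series.index).fillna(0).astype(int)
            if (recon == tc).all():
                exact += 1
        out["monthly_exact_fraction"] = exact / total if total else float("nan")
    if group_matrices is not None:
        per_group = {}
        for group, P_hat in group_matrices.items():
            K = truth.kernels[group]
            common = [s for s in P_hat.index if s in K.index]
            diff = (P_hat.loc[common, common] - K.loc[common, common]).abs().to_numpy()
            per_group[f"{group[0]}{group[1]}"] = {
                "max_abs_error": float(diff.max()),
                "mean_abs_error": float(diff.mean()),
            }
        out["transition_matrix_error"] = per_group
    if kd_coverage and cleaned is not None:
        from .activity import (
            build_relocation_series,
            estimate_kernel_density,
            node_positions,
            percent_volume_contour,
        )

        positions = node_positions(cleaned)
        covered, assessed = 0, 0
        for sid in truth.sharks["shark_id"]:
            occ = truth.occupancy(sid).drop(ABSENT)
            if occ.sum() == 0:
                continue
            top_node = occ.idxmax()
            rel = build_relocation_series(cleaned, sid, positions=positions)
            if len(rel) < 10 or rel["node_id"].nunique() < 3:
                continue
            surf = estimate_kernel_density(rel, 1000.0, 200.0)
            res = percent_volume_contour(surf, 0.50)
            hx, hy = positions.loc[top_node, ["x_km", "y_km"]]
            iy = int(np.argmin(np.abs(surf.ys - hy)))
            ix = int(np.argmin(np.abs(surf.xs - hx)))
            assessed += 1
            if surf.density[iy, ix] >= res.threshold:
                covered += 1
        out["kd_core_covers_top_node"] = covered / assessed if assessed else float("nan")
    if truth.planted_singletons is not None and cleaned is not None:
        log = cleaned.filter_log
        removed = int(
            log[log["rule"].str.startswith("single-detection")]["rows_removed"].sum()
        )
        out["planted_singletons"] = int(len(truth.planted_singletons))
        out["singletons_removed"] = removed
    return out
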