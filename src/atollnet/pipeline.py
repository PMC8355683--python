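"""Pipeline orchestration: filter -> residency -> KDE -> movement chains.

``run_pipeline`` ties the stages together from a single configuration,
writes every stage's outputs under one directory and assembles a
versioned ``report.json`` of cohort statistics.  Two input modes exist:
raw detection CSVs (or an in-memory DetectionSet), and ``from_table``
mode, which skips detection processing and recomputes the cohort
statistics and regressions directly from the packaged per-shark summary
table -- the regression-test path, since the raw study data were never
deposited.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import KdeConfig, core_activity_spaces, summarize_activity_by_class
from .edmc import group_chain, export_network
from .io import (
    DetectionSet,
    default_node_map,
    load_table1,
    merge_receiver_nodes,
    apply_minimum_days_filter,
    read_detections,
    remove_false_detections,
    write_detections,
)
from .residency import (
    StudyConfig,
    build_residency_table,
    compute_monthly_series,
    fit_linear_model,
    select_linear_model,
    summarize_cohort,
)

REPORT_SCHEMA_VERSION = 1

#: rounding conventions used in report output (decimal places)
ROUNDING = {"indices": 3, "regression": 4, "areas_km2": 1}


@dataclass
class PipelineConfig:
    """Everything run_pipeline needs; mirrors the study's settings."""

    out_dir: Path = Path("atollnet_out")
    detections: Path | None = None
    stations: Path | None = None
    sharks: Path | None = None
    from_table: bool = False
    study: StudyConfig = field(default_factory=StudyConfig)
    kde: KdeConfig = field(default_factory=KdeConfig)
    edmc_tol: float = 1e-10
    edmc_max_iter: int = 100_000
    group_by: str = "sex_size"  # or "individual"
    min_days: int = 5
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("out_dir", "detections", "stations", "sharks"):
            if key in raw and raw[key] is not None:
                kwargs[key] = Path(raw[key])
        for key in ("from_table", "edmc_tol", "edmc_max_iter", "group_by", "min_days", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "study" in raw:
            kwargs["study"] = StudyConfig(
                **{
                    k: pd.Timestamp(v) if "date" in k or k.endswith("_end") or k.endswith("_start") else v
                    for k, v in raw["study"].items()
                }
            )
        if "kde" in raw:
            kwargs["kde"] = KdeConfig(**raw["kde"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in (self.detections, self.stations, self.sharks):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input {p} does not exist")
        if self.kde.h_m <= 0 or self.kde.cell_m <= 0:
            raise ValueError("KDE settings must be positive")
        if not self.from_table and self.detections is None:
            raise ValueError("either from_table or a detections path is required")


class _RunLog:
    """Human log to stderr plus machine-readable JSONL."""

    def __init__(self, path: Path):
        self.path = path
        self.fh = open(path, "w")

    def log(self, stage: str, **fields) -> None:
        rec = {"t": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()), "stage": stage, **fields}
        self.fh.write(json.dumps(rec) + "\n")
        self.fh.flush()
        print(f"[atollnet] {stage}: {fields}", file=sys.stderr)

    def close(self):
        self.fh.close()


def _round_floats(obj, nd=4):
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), nd) if np.isfinite(obj) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def table_report(table: pd.DataFrame) -> dict:
    """Cohort statistics and regressions recomputed from a per-shark table."""
    from .io import assign_size_class

    t = table.copy()
    t["size_class_recomputed"] = [
        assign_size_class(s, tl) for s, tl in zip(t["sex"], t["tl_cm"])
    ]
    cohort = summarize_cohort(t.assign(size_class=t["size_class_recomputed"]))
    roam_fit = fit_linear_model(t, "roaming_index", ("tl",))
    ri_fit = fit_linear_model(t, "ri", ("tl", "sex"))
    kd = summarize_activity_by_class(t, value="kd50_km2")
    kd_col = t["kd50_km2"].dropna()
    report = {
        "cohort": cohort,
        "size_class_agreement": float(
            (t["size_class"] == t["size_class_recomputed"]).mean()
        ),
        "roaming_recomputed_matches_3dp": bool(
            (
                np.round(t["receivers_visited"] / 18, 3) == np.round(t["roaming_index"], 3)
            ).all()
        ),
        "regressions": {
            "roaming_index~TL": roam_fit.to_frame().round(4).to_dict(),
            "ri~TL+sex": ri_fit.to_frame().round(4).to_dict(),
        },
        "kd50": {
            "n": int(len(kd_col)),
            "mean_km2": float(kd_col.mean()),
            "min_km2": float(kd_col.min()),
            "max_km2": float(kd_col.max()),
            "by_size_class": {
                cls: {"mean": float(row["mean"]), "sd": float(row["sd"]), "n": int(row["n"])}
                for cls, row in kd.iterrows()
            },
        },
    }
    return report


def run_pipeline(cfg: PipelineConfig, ds: DetectionSet | None = None) -> dict:
    """Execute the full analysis; returns the report dict.

    Any stage failure aborts with the stage name and cause; outputs
    written so far are kept and MANIFEST.json marks the run incomplete.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run_log.jsonl")
    manifest = {"complete": False, "stages": [], "version": __version__}
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "rounding": ROUNDING,
    }
    stage = "configure"
    try:
        cfg.validate()
        if cfg.from_table:
            stage = "from_table"
            table = load_table1()
            report["table"] = _round_floats(table_report(table), 4)
            manifest["stages"].append(stage)
            log.log(stage, rows=len(table))
        else:
            stage = "read"
            if ds is None:
                ds = read_detections(cfg.detections, cfg.stations, cfg.sharks)
            log.log(stage, events=ds.n_events, sharks=len(ds.sharks))

            stage = "filter"
            ds = remove_false_detections(ds)
            ds, excluded = apply_minimum_days_filter(ds, cfg.min_days)
            ds = merge_receiver_nodes(ds, default_node_map(ds.stations["receiver_id"]))
            write_detections(ds, out / "cleaned")
            manifest["stages"].append(stage)
            log.log(stage, events=ds.n_events, excluded=len(excluded))

            stage = "residency"
            table = build_residency_table(ds, cfg.study)
            table.to_csv(out / "residency_summary.csv", index=False, float_format="%.3f")
            cohort = summarize_cohort(table)
            monthly = {
                sid: compute_monthly_series(ds, sid, cfg.study)
                for sid in table["shark_id"]
            }
            report["cohort"] = cohort
            if table["tl_cm"].notna().all() and table["sex"].notna().all():
                best_ri, _ = select_linear_model(table, "ri")
                best_roam, _ = select_linear_model(table, "roaming_index")
                report["regressions"] = {
                    "ri": {"terms": best_ri.terms, "estimates": best_ri.estimates.tolist()},
                    "roaming_index": {
                        "terms": best_roam.terms,
                        "estimates": best_roam.estimates.tolist(),
                    },
                }
            manifest["stages"].append(stage)
            log.log(stage, sharks=len(table))

            stage = "kde"
            activity = core_activity_spaces(ds, cfg.kde)
            cols = ["shark_id", "n_relocations", "kd50_km2", "kd95_km2", "h_m"]
            activity[cols].to_csv(out / "activity_spaces.csv", index=False, float_format="%.3f")
            kd_summary = summarize_activity_by_class(activity, ds.sharks)
            report["kd50_by_size_class"] = {
                str(k): {"mean": float(v["mean"]), "sd": float(v["sd"]), "n": int(v["n"])}
                for k, v in kd_summary.iterrows()
            }
            manifest["stages"].append(stage)
            log.log(stage, eligible=int(activity["eligible"].sum()))

            stage = "edmc"
            chains = {}
            if cfg.group_by == "individual":
                groups = {sid: [sid] for sid in table["shark_id"]}
            else:
                groups = {
                    f"{sex}{cls}": ds.sharks[
                        (ds.sharks["sex"] == sex) & (ds.sharks["size_class"] == cls)
                    ]["shark_id"].astype(str).tolist()
                    for sex in ("F", "M")
                    for cls in ("A", "B", "C")
                }
            net_dir = out / "networks"
            report["edmc"] = {}
            for label, ids in groups.items():
                ids = [i for i in ids if i in set(ds.events["transmitter_id"])]
                if not ids:
                    continue
                res = group_chain(
                    ds, ids, label=label, tol=cfg.edmc_tol, max_iter=cfg.edmc_max_iter
                )
                chains[label] = res
                export_network(res, net_dir)
                res.transition_matrix.to_csv(net_dir / f"transition_matrix_{label}.csv")
                res.centrality.to_csv(net_dir / f"centrality_{label}.csv")
                report["edmc"][label] = {
                    "n_sharks": res.n_sharks,
                    "absent_centrality": float(res.centrality.get("ABSENT", np.nan)),
                    "dropped_states": res.dropped_states,
                }
            manifest["stages"].append(stage)
            log.log(stage, groups=len(chains))

        stage = "report"
        manifest["complete"] = True
        (out / "report.json").write_text(json.dumps(_round_floats(report, 6), indent=2))
        log.log(stage, path=str(out / "report.json"))
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        log.close()
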