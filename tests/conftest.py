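import numpy as np
import pandas as pd
import pytest

from atollnet import (
    apply_minimum_days_filter,
    load_table1,
    merge_receiver_nodes,
    remove_false_detections,
)
from atollnet.io import DetectionSet
from atollnet.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def small_sim():
    """A small lossless cohort (5 sharks, 60 d) with planted singletons."""
    cfg = SimulationConfig(
        seed=5,
        group_sizes={("F", "C"): 3, ("M", "A"): 2},
        max_duration_days=60,
        detection_prob=1.0,
        singleton_rate=0.01,
    )
    ds, truth = simulate_cohort(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def cleaned_sim(small_sim):
    """The small cohort after the standard cleaning chain + node merging."""
    ds, truth = small_sim
    ds = remove_false_detections(ds)
    ds, excluded = apply_minimum_days_filter(ds)
    ds = merge_receiver_nodes(ds)
    return ds, truth, excluded


def make_detection_set(rows, stations=None, sharks=None) -> DetectionSet:
    """Build a DetectionSet from (timestamp, receiver, transmitter) tuples."""
    events = pd.DataFrame(rows, columns=["timestamp", "receiver_id", "transmitter_id"])
    events["timestamp"] = pd.to_datetime(events["timestamp"], utc=True)
    if stations is None:
        ids = sorted(events["receiver_id"].unique())
        stations = pd.DataFrame(
            {
                "receiver_id": ids,
                "lat": np.linspace(17.0, 17.3, len(ids)),
                "lon": np.linspace(-87.6, -87.4, len(ids)),
                "depth_m": 12.0,
            }
        )
    if sharks is None:
        sharks = pd.DataFrame(
            {
                "shark_id": sorted(events["transmitter_id"].unique()),
                "sex": "F",
                "tl_cm": 190.0,
                "date_tagged": pd.Timestamp("2007-04-23"),
                "capture_date": pd.NaT,
                "size_class": "C",
            }
        )
    return DetectionSet(events=events, stations=stations, sharks=sharks)
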