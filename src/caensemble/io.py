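"""Plain-text readers and writers for every pipeline artifact.

Traces travel as CSV (rows = cells, columns = frames, first column
``cell_id``, header row of frame indices) with a JSON sidecar carrying
the sampling rate and session label; events, edges, metrics, labels and
partitions as TSV with headers; timelines, ground truth, regression
reports and run manifests as JSON. Everything a writer emits is readable
by the matching reader with value equality.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EventTrain, SessionTimeline, TraceMatrix
from .graphs import CorrelationGraph, GraphMetrics

__all__ = [
    "write_traces",
    "read_traces",
    "write_events",
    "read_events",
    "write_timeline",
    "read_timeline",
    "write_edges",
    "read_edges",
    "write_metrics",
    "read_metrics",
    "write_labels",
    "read_labels",
    "write_partition",
    "read_partition",
    "write_deltas",
    "write_centroids",
    "read_centroids",
    "write_json",
    "read_json",
]


def write_traces(path: str | Path, traces: TraceMatrix) -> None:
    path = Path(path)
    df = pd.DataFrame(
        traces.values, columns=[str(i) for i in range(traces.n_frames)]
    )
    df.insert(0, "cell_id", traces.cell_ids)
    df.to_csv(path, index=False, float_format="%.6g")
    sidecar = {"fps": traces.fps, "session": traces.session}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_traces(path: str | Path) -> TraceMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return TraceMatrix(
        df.drop(columns="cell_id").to_numpy(dtype=float),
        fps=float(sidecar["fps"]),
        cell_ids=[str(c) for c in df["cell_id"]],
        session=sidecar.get("session", ""),
    )


def write_events(path: str | Path, trains: list[EventTrain]) -> None:
    rows = [
        {"cell_id": t.cell_id, "time_s": tt, "amplitude_sd": aa}
        for t in trains
        for tt, aa in zip(t.times, t.amplitudes)
    ]
    df = pd.DataFrame(rows, columns=["cell_id", "time_s", "amplitude_sd"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_events(
    path: str | Path, cell_ids: list[str] | None = None
) -> list[EventTrain]:
    """Read events TSV; ``cell_ids`` restores silent cells (empty trains)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    ids = cell_ids if cell_ids is not None else sorted(df["cell_id"].unique())
    trains = []
    for cid in ids:
        sub = df[df["cell_id"] == cid]
        trains.append(
            EventTrain(
                cid,
                sub["time_s"].to_numpy(dtype=float),
                sub["amplitude_sd"].to_numpy(dtype=float),
            )
        )
    return trains


def write_timeline(path: str | Path, timeline: SessionTimeline) -> None:
    Path(path).write_text(json.dumps(timeline.to_dict(), indent=1))


def read_timeline(path: str | Path) -> SessionTimeline:
    return SessionTimeline.from_dict(json.loads(Path(path).read_text()))


def write_edges(path: str | Path, graph: CorrelationGraph) -> None:
    index = {cid: i for i, cid in enumerate(graph.cell_ids)}
    thr = graph.threshold
    rows = []
    n = len(graph.cell_ids)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = graph.cell_ids[i], graph.cell_ids[j]
            t = thr[i, j] if isinstance(thr, np.ndarray) else thr
            rows.append(
                {
                    "cell_i": a,
                    "cell_j": b,
                    "r": graph.r[i, j],
                    "threshold": t,
                    "significant": int(
                        (a, b) in graph.edges or (b, a) in graph.edges
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_edges(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cell_i": str, "cell_j": str})


def write_metrics(
    path: str | Path, metrics: dict[str, GraphMetrics]
) -> None:
    rows = []
    for session, gm in metrics.items():
        for cid in gm.cell_ids:
            rows.append(
                {
                    "cell_id": cid,
                    "session": session,
                    "pair_ratio": gm.pair_ratio[cid],
                    "clustering": gm.clustering[cid],
                    "component_member": gm.component_member[cid],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cell_id": str})


def write_labels(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cell_id": str})


def write_partition(path: str | Path, classes: dict[str, str]) -> None:
    df = pd.DataFrame(
        [{"cell_id": c, "class": k} for c, k in sorted(classes.items())]
    )
    df.to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["cell_id"], df["class"]))


def write_deltas(path: str | Path, deltas, labels=None) -> None:
    """Deltas TSV: session, metric, cell_id, delta (+class if given)."""
    rows = []
    for session, per_metric in deltas.deltas.items():
        for metric, table in per_metric.items():
            for cid, val in table.items():
                row = {
                    "session": session,
                    "metric": metric,
                    "cell_id": cid,
                    "delta": val,
                }
                if labels is not None:
                    row["class"] = labels.classes.get(cid, "")
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_centroids(
    path: str | Path, centroids: dict[str, tuple[float, float]]
) -> None:
    df = pd.DataFrame(
        [{"cell_id": c, "x": xy[0], "y": xy[1]} for c, xy in centroids.items()]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_centroids(path: str | Path) -> dict[str, tuple[float, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    return {
        str(r.cell_id): (float(r.x), float(r.y)) for r in df.itertuples()
    }


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
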