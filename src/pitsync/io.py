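"""Readers and writers for the package's plain-text formats.

Formats:

* traces CSV — one row per cell, first column ``cell_id``, remaining column
  headers are frame timestamps in seconds.
* ROI CSV — columns ``cell_id, x_um, y_um, radius_um``.
* ground-truth JSON sidecar — responder flags/classes, onsets, coupling
  weights, simulation config.
* paired-sweep CSV — long format ``sweep, time_s, i_pa, v1_mv, v2_mv`` with
  ``# key=value`` header lines for step timing and holding potential.
* pair-level TSV — ``cell_a, cell_b, window, rho, p_value, distance_um,
  group, degenerate``.
* optional multi-frame TIFF rendering of a simulated field for image-reader
  testing, with mean-ROI trace extraction back out of it.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .simulate import CellLayout, PairedSweepSet, RecordingDataset
from .synchrony import PairCorrelation

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_rois_csv",
    "read_rois_csv",
    "write_dataset",
    "read_dataset",
    "write_sweeps_csv",
    "read_sweeps_csv",
    "write_pairs_tsv",
    "read_pairs_tsv",
    "write_responder_calls_tsv",
    "export_correlation_map",
    "write_tiff_stack",
    "extract_traces_from_tiff",
]

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# traces + ROIs + ground truth
# ---------------------------------------------------------------------------


def write_traces_csv(dataset: RecordingDataset, path: PathLike) -> None:
    header = ["cell_id"] + [f"{t:.6g}" for t in dataset.timestamps]
    df = pd.DataFrame(dataset.fluorescence, columns=header[1:])
    df.insert(0, "cell_id", list(dataset.layout.cell_ids))
    df.to_csv(path, index=False, float_format="%.8g")


def read_traces_csv(path: PathLike) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Returns (cell_ids, fluorescence cells × frames, timestamps)."""
    df = pd.read_csv(path)
    if "cell_id" not in df.columns:
        raise ValueError(f"{path}: traces CSV must have a cell_id column")
    ids = df["cell_id"].astype(str).tolist()
    timestamps = np.asarray([float(c) for c in df.columns[1:]])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return ids, values, timestamps


def write_rois_csv(layout: CellLayout, path: PathLike) -> None:
    pd.DataFrame(
        {
            "cell_id": list(layout.cell_ids),
            "x_um": layout.x,
            "y_um": layout.y,
            "radius_um": layout.radius,
        }
    ).to_csv(path, index=False, float_format="%.8g")


def read_rois_csv(path: PathLike) -> CellLayout:
    df = pd.read_csv(path)
    required = {"cell_id", "x_um", "y_um", "radius_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: ROI CSV missing columns {sorted(missing)}")
    return CellLayout(
        cell_ids=tuple(df["cell_id"].astype(str)),
        x=df["x_um"].to_numpy(dtype=float),
        y=df["y_um"].to_numpy(dtype=float),
        radius=df["radius_um"].to_numpy(dtype=float),
    )


def write_dataset(dataset: RecordingDataset, out_dir: PathLike) -> Path:
    """Write traces.csv, rois.csv and (if present) ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_traces_csv(dataset, out / "traces.csv")
    write_rois_csv(dataset.layout, out / "rois.csv")
    if dataset.ground_truth is not None:
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(dataset.ground_truth, fh, indent=1, sort_keys=True)
    if dataset.label:
        (out / "label.txt").write_text(dataset.label + "\n")
    return out


def read_dataset(in_dir: PathLike, label: Optional[str] = None) -> RecordingDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Trace and ROI cell ids must match one-to-one; unmatched ids are
    reported.
    """
    in_dir = Path(in_dir)
    traces_path = in_dir / "traces.csv"
    if not traces_path.exists():
        raise FileNotFoundError(f"missing trace file: {traces_path}")
    ids, values, timestamps = read_traces_csv(traces_path)
    layout = read_rois_csv(in_dir / "rois.csv")
    if list(layout.cell_ids) != ids:
        trace_only = sorted(set(ids) - set(layout.cell_ids))
        roi_only = sorted(set(layout.cell_ids) - set(ids))
        raise ValueError(
            f"{in_dir}: trace/ROI cell ids do not match "
            f"(traces only: {trace_only}; ROIs only: {roi_only})"
        )
    gt_path = in_dir / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else None
    if label is None:
        label_path = in_dir / "label.txt"
        label = label_path.read_text().strip() if label_path.exists() else ""
    return RecordingDataset(
        fluorescence=values,
        timestamps=timestamps,
        layout=layout,
        ground_truth=ground_truth,
        label=label,
    )


# ---------------------------------------------------------------------------
# paired sweeps
# ---------------------------------------------------------------------------


def write_sweeps_csv(sweeps: PairedSweepSet, path: PathLike) -> None:
    meta = {
        "step_onset_s": sweeps.step_onset_s,
        "step_duration_s": sweeps.step_duration_s,
        "holding_mv": sweeps.holding_mv,
        "true_cc": sweeps.true_cc,
    }
    n_sweeps, n_samples = sweeps.v1_mv.shape
    sweep_idx = np.repeat(np.arange(n_sweeps), n_samples)
    frame = pd.DataFrame(
        {
            "sweep": sweep_idx,
            "time_s": np.tile(sweeps.time_s, n_sweeps),
            "i_pa": np.repeat(sweeps.i_pa, n_samples),
            "v1_mv": sweeps.v1_mv.ravel(),
            "v2_mv": sweeps.v2_mv.ravel(),
        }
    )
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        frame.to_csv(fh, index=False, float_format="%.8g")


def read_sweeps_csv(path: PathLike) -> PairedSweepSet:
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = None if val == "None" else float(val)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    sweeps = sorted(df["sweep"].unique())
    time_s = df.loc[df["sweep"] == sweeps[0], "time_s"].to_numpy(dtype=float)
    v1 = np.vstack(
        [df.loc[df["sweep"] == s, "v1_mv"].to_numpy(dtype=float) for s in sweeps]
    )
    v2 = np.vstack(
        [df.loc[df["sweep"] == s, "v2_mv"].to_numpy(dtype=float) for s in sweeps]
    )
    i_pa = np.asarray(
        [df.loc[df["sweep"] == s, "i_pa"].iloc[0] for s in sweeps], dtype=float
    )
    return PairedSweepSet(
        time_s=time_s,
        i_pa=i_pa,
        v1_mv=v1,
        v2_mv=v2,
        step_onset_s=float(meta.get("step_onset_s", 0.1)),
        step_duration_s=float(meta.get("step_duration_s", 0.5)),
        holding_mv=float(meta.get("holding_mv", -60.0)),
        true_cc=meta.get("true_cc"),
    )


# ---------------------------------------------------------------------------
# analysis tables
# ---------------------------------------------------------------------------


def write_pairs_tsv(pairs: Sequence[PairCorrelation], path: PathLike) -> None:
    pd.DataFrame([asdict(p) for p in pairs]).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path: PathLike) -> list[PairCorrelation]:
    df = pd.read_csv(path, sep="\t")
    return [
        PairCorrelation(
            cell_a=str(r.cell_a),
            cell_b=str(r.cell_b),
            window=str(r.window),
            rho=float(r.rho),
            p_value=float(r.p_value),
            distance_um=float(r.distance_um),
            group=("" if pd.isna(r.group) else str(r.group)),
            degenerate=bool(r.degenerate),
        )
        for r in df.itertuples()
    ]


def write_responder_calls_tsv(calls, path: PathLike) -> None:
    pd.DataFrame([asdict(c) for c in calls]).to_csv(path, sep="\t", index=False)


def export_correlation_map(
    pairs: Sequence[PairCorrelation],
    layout: CellLayout,
    path: PathLike,
    p_threshold: float = 0.001,
) -> dict:
    """Node/edge JSON for a correlation map figure.

    Nodes are cells with coordinates; edges are pairs whose window rho is
    significant at `p_threshold`.
    """
    nodes = [
        {"cell_id": cid, "x_um": float(x), "y_um": float(y), "radius_um": float(r)}
        for cid, x, y, r in zip(layout.cell_ids, layout.x, layout.y, layout.radius)
    ]
    edges = [
        {
            "cell_a": p.cell_a,
            "cell_b": p.cell_b,
            "rho": p.rho,
            "p_value": p.p_value,
            "distance_um": p.distance_um,
        }
        for p in pairs
        if not p.degenerate and p.p_value < p_threshold
    ]
    doc = {"p_threshold": p_threshold, "nodes": nodes, "edges": edges}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
    return doc


# ---------------------------------------------------------------------------
# optional TIFF rendering / ingestion
# ---------------------------------------------------------------------------


def write_tiff_stack(
    dataset: RecordingDataset, path: PathLike, um_per_px: float = 1.0
) -> None:
    """Render the recording as a multi-frame TIFF of uniform-intensity disks."""
    import tifffile

    w = int(np.ceil((dataset.layout.x + dataset.layout.radius).max() / um_per_px)) + 2
    h = int(np.ceil((dataset.layout.y + dataset.layout.radius).max() / um_per_px)) + 2
    yy, xx = np.mgrid[0:h, 0:w]
    masks = []
    for cx, cy, r in zip(dataset.layout.x, dataset.layout.y, dataset.layout.radius):
        masks.append(
            (xx * um_per_px - cx) ** 2 + (yy * um_per_px - cy) ** 2 <= r**2
        )
    n_frames = dataset.fluorescence.shape[1]
    stack = np.zeros((n_frames, h, w), dtype=np.float32)
    for mask, trace in zip(masks, dataset.fluorescence):
        stack[:, mask] = np.maximum(stack[:, mask], trace[:, None])
    tifffile.imwrite(str(path), stack)


def extract_traces_from_tiff(
    path: PathLike, layout: CellLayout, um_per_px: float = 1.0
) -> np.ndarray:
    """Mean-ROI traces (cells × frames) from a multi-frame TIFF."""
    import tifffile

    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    h, w = stack.shape[1:]
    yy, xx = np.mgrid[0:h, 0:w]
    out = np.zeros((len(layout), stack.shape[0]))
    for i, (cx, cy, r) in enumerate(zip(layout.x, layout.y, layout.radius)):
        mask = (xx * um_per_px - cx) ** 2 + (yy * um_per_px - cy) ** 2 <= r**2
        if not mask.any():
            raise ValueError(f"ROI {layout.cell_ids[i]} covers no pixels")
        out[i] = stack[:, mask].mean(axis=1)
    return out
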