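"""Plain-text file formats for every pipeline artifact.

All artifacts are human-readable CSV or JSON:

* **rig JSON** — list of cameras with name, focal, principal point, image
  size, row-major rotation and translation, so that projection =
  intrinsics x [rotation | translation].
* **keypoint CSV** — ``frame, time_s`` then ``<keypoint>_x, <keypoint>_y``
  per keypoint; missing observations are empty cells.
* **angle-trace CSV** — ``frame, time_s, angle_deg`` with ``#`` header
  comments recording task, rate, sign convention and seed.
* **3D-series CSV** — ``frame, time_s`` then ``<keypoint>_x/_y/_z`` plus a
  per-frame mean ``residual_px``.
* **paired-trace CSV** — ``grid_index, t_norm, test_deg, ref_deg`` with
  provenance comments.
* **report CSV/JSON** — Table-style agreement rows.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import AlignedTracePair
from .cameras import CameraModel
from .errors import ConfigurationError
from .reliability import ReliabilityResult
from .series import AngleTrace, KeypointSeries2D, SignConvention, Skeleton3DSeries, Task

__all__ = [
    "save_rig", "load_rig",
    "save_keypoints", "load_keypoints",
    "save_angle_trace", "load_angle_trace",
    "save_skeleton3d", "load_skeleton3d",
    "save_pair", "load_pair",
    "save_report",
]


# ---------------------------------------------------------------- rig JSON
def save_rig(cameras: list[CameraModel], path: str | Path) -> None:
    data = [
        {
            "name": c.name,
            "focal_px": list(c.focal_px),
            "principal_point_px": list(c.principal_point_px),
            "image_size_px": list(c.image_size_px),
            "rotation": [list(row) for row in c.rotation],
            "translation": list(c.translation),
        }
        for c in cameras
    ]
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def load_rig(path: str | Path) -> list[CameraModel]:
    data = json.loads(Path(path).read_text())
    if not isinstance(data, list):
        raise ConfigurationError(f"rig file {path} must contain a JSON list of cameras")
    return [
        CameraModel(
            name=c["name"],
            focal_px=tuple(c["focal_px"]),
            principal_point_px=tuple(c["principal_point_px"]),
            image_size_px=tuple(c["image_size_px"]),
            rotation=np.array(c["rotation"]),
            translation=np.array(c["translation"]),
        )
        for c in data
    ]


# ---------------------------------------------------------- keypoint CSV
def save_keypoints(series: KeypointSeries2D, path: str | Path) -> None:
    cols: dict[str, np.ndarray] = {
        "frame": np.arange(series.n_frames),
        "time_s": series.times,
    }
    for j, name in enumerate(series.keypoints):
        cols[f"{name}_x"] = series.coords[:, j, 0]
        cols[f"{name}_y"] = series.coords[:, j, 1]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# camera: {series.camera}\n# rate_hz: {series.rate_hz}\n")
        df.to_csv(fh, index=False, na_rep="")


def _read_commented_csv(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    header: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    header[k.strip()] = v.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    return header, df


def load_keypoints(path: str | Path) -> KeypointSeries2D:
    header, df = _read_commented_csv(path)
    kp_names = []
    for col in df.columns:
        if col.endswith("_x"):
            kp_names.append(col[:-2])
    coords = np.stack(
        [np.column_stack([df[f"{n}_x"].to_numpy(float), df[f"{n}_y"].to_numpy(float)]) for n in kp_names],
        axis=1,
    )
    return KeypointSeries2D(
        camera=header.get("camera", Path(path).stem),
        keypoints=tuple(kp_names),
        coords=coords,
        rate_hz=float(header.get("rate_hz", 0) or 0) or _infer_rate(df),
    )


def _infer_rate(df: pd.DataFrame) -> float:
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise ConfigurationError("cannot infer sample rate from fewer than 2 frames")
    dt = np.median(np.diff(t))
    if dt <= 0:
        raise ConfigurationError("non-increasing time_s column")
    return 1.0 / dt


# ------------------------------------------------------- angle-trace CSV
def save_angle_trace(trace: AngleTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        if trace.task is not None:
            fh.write(f"# task: {trace.task.value}\n")
        fh.write(f"# rate_hz: {trace.rate_hz}\n")
        fh.write(f"# sign_convention: {trace.convention.value}\n")
        if "seed" in trace.meta:
            fh.write(f"# seed: {trace.meta['seed']}\n")
        pd.DataFrame(
            {"frame": np.arange(len(trace)), "time_s": trace.times, "angle_deg": trace.values}
        ).to_csv(fh, index=False, na_rep="")


def load_angle_trace(path: str | Path) -> AngleTrace:
    header, df = _read_commented_csv(path)
    meta = {}
    if "seed" in header:
        meta["seed"] = int(header["seed"])
    return AngleTrace(
        values=df["angle_deg"].to_numpy(float),
        rate_hz=float(header.get("rate_hz", 0) or 0) or _infer_rate(df),
        task=Task(header["task"]) if "task" in header else None,
        convention=SignConvention(header.get("sign_convention", "unsigned_0_180")),
        meta=meta,
    )


# --------------------------------------------------------- 3D-series CSV
def save_skeleton3d(skel: Skeleton3DSeries, path: str | Path) -> None:
    cols: dict[str, np.ndarray] = {
        "frame": np.arange(skel.n_frames),
        "time_s": skel.times,
    }
    for j, name in enumerate(skel.keypoints):
        for d, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = skel.positions[:, j, d]
    if skel.residual_px is not None:
        with np.errstate(invalid="ignore"):
            cols["residual_px"] = np.nanmean(skel.residual_px, axis=1)
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# rate_hz: {skel.rate_hz}\n")
        df.to_csv(fh, index=False, na_rep="")


def load_skeleton3d(path: str | Path) -> Skeleton3DSeries:
    header, df = _read_commented_csv(path)
    names = [c[:-2] for c in df.columns if c.endswith("_x") and f"{c[:-2]}_z" in df.columns]
    positions = np.stack(
        [
            np.column_stack([df[f"{n}_{ax}"].to_numpy(float) for ax in "xyz"])
            for n in names
        ],
        axis=1,
    )
    return Skeleton3DSeries(
        keypoints=tuple(names),
        positions=positions,
        rate_hz=float(header.get("rate_hz", 0) or 0) or _infer_rate(df),
    )


# ------------------------------------------------------ paired-trace CSV
def save_pair(pair: AlignedTracePair, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sign_convention: {pair.convention.value}\n")
        for key in ("participant", "task", "side"):
            if key in pair.provenance:
                fh.write(f"# {key}: {pair.provenance[key]}\n")
        pd.DataFrame(
            {
                "grid_index": np.arange(pair.n_frames),
                "t_norm": pair.t_norm,
                "test_deg": pair.test,
                "ref_deg": pair.reference,
            }
        ).to_csv(fh, index=False)


def load_pair(path: str | Path) -> AlignedTracePair:
    header, df = _read_commented_csv(path)
    prov = {k: header[k] for k in ("participant", "task", "side") if k in header}
    return AlignedTracePair(
        test=df["test_deg"].to_numpy(float),
        reference=df["ref_deg"].to_numpy(float),
        t_norm=df["t_norm"].to_numpy(float),
        convention=SignConvention(header.get("sign_convention", "unsigned_0_180")),
        provenance=prov,
    )


# -------------------------------------------------------------- reports
_REPORT_COLUMNS = [
    "task", "participant", "side", "m", "sd", "icc_form", "icc",
    "ci_low", "ci_high", "cv_pct", "sem_deg", "mdc95_deg", "band",
    "cv_variant", "sem_variant",
]


def report_frame(rows: list[ReliabilityResult]) -> pd.DataFrame:
    """Agreement rows as a DataFrame in stable column order."""
    return pd.DataFrame([vars(r) for r in rows], columns=_REPORT_COLUMNS)


def save_report(rows: list[ReliabilityResult], path: str | Path) -> None:
    path = Path(path)
    df = report_frame(rows)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2) + "\n")
    else:
        df.to_csv(path, index=False)
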