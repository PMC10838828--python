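"""File formats: pose CSV, calibration JSON, masks, border polygons."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .geometry import CameraModel, RigidTransform, SensorReading

POSE_COLUMNS = ["frame_id", "x_mm", "y_mm", "z_mm",
                "azimuth_deg", "elevation_deg", "roll_deg"]


def read_pose_csv(path) -> list[SensorReading]:
    """Read 6DoF sensor readings from CSV (header required, '.' decimal)."""
    df = pd.read_csv(path)
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pose CSV {path} missing columns: {missing}")
    return [
        SensorReading(
            position=np.array([row.x_mm, row.y_mm, row.z_mm]),
            azimuth=row.azimuth_deg,
            elevation=row.elevation_deg,
            roll=row.roll_deg,
            frame_id=int(row.frame_id),
        )
        for row in df.itertuples()
    ]


def write_pose_csv(path, readings: list[SensorReading]) -> None:
    rows = [
        dict(frame_id=r.frame_id, x_mm=r.position[0], y_mm=r.position[1],
             z_mm=r.position[2], azimuth_deg=r.azimuth,
             elevation_deg=r.elevation, roll_deg=r.roll)
        for r in readings
    ]
    pd.DataFrame(rows, columns=POSE_COLUMNS).to_csv(path, index=False)


def write_calibration_json(path, cam: CameraModel | None = None,
                           hand_eye: RigidTransform | None = None) -> None:
    """Write (or update) the calibration file.

    ``hand_eye`` is stored in the package's canonical direction: it maps
    sensor-frame coordinates into the camera frame (the AT=TB solution).
    """
    path = Path(path)
    doc = {}
    if path.exists():
        doc = json.loads(path.read_text())
    if cam is not None:
        doc["intrinsics"] = {
            "fx": cam.fx, "fy": cam.fy, "cx": cam.cx, "cy": cam.cy,
            "skew": cam.skew, "k1": cam.k1, "k2": cam.k2, "k3": cam.k3,
            "p1": cam.p1, "p2": cam.p2,
            "width": cam.width, "height": cam.height,
        }
    if hand_eye is not None:
        doc["hand_eye"] = {
            "rotation": hand_eye.rotation.tolist(),
            "translation_mm": hand_eye.translation.tolist(),
        }
    path.write_text(json.dumps(doc, indent=2))


def read_calibration_json(path) -> tuple[CameraModel | None, RigidTransform | None]:
    doc = json.loads(Path(path).read_text())
    cam = None
    hand_eye = None
    if "intrinsics" in doc:
        d = doc["intrinsics"]
        cam = CameraModel(
            fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"],
            skew=d.get("skew", 0.0),
            k1=d.get("k1", 0.0), k2=d.get("k2", 0.0), k3=d.get("k3", 0.0),
            p1=d.get("p1", 0.0), p2=d.get("p2", 0.0),
            width=int(d["width"]), height=int(d["height"]),
        )
    if "hand_eye" in doc:
        d = doc["hand_eye"]
        hand_eye = RigidTransform(
            np.array(d["rotation"]), np.array(d["translation_mm"]),
            from_frame="sensor", to_frame="camera",
        )
    return cam, hand_eye


def write_mask_png(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask_png(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img > 127


def write_border_csv(path, border: np.ndarray) -> None:
    pd.DataFrame(border, columns=["u_px", "v_px"]).to_csv(path, index=False)


def read_border_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["u_px", "v_px"]].to_numpy(float)
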