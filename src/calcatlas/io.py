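"""Readers and writers for the pipeline's on-disk formats.

Text formats only: XYZ / ASCII-PLY point clouds, JSON landmark and seed
files, per-bone coefficient CSV (columns q, l, m, c with the scale radius
and order in comment headers), wide atlas CSV (bones x Q), raw-array +
JSON-metadata volume fixtures, and the supplementary-style wide coefficient
workbook (xlsx via openpyxl, or a CSV conversion).  DICOM series reading is
available when pydicom is installed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pose import LANDMARK_NAMES, LandmarkSet
from .preprocessing import Volume
from .segmentation import SeedSpec
from .spharm import BasisSpec, SpharmCoefficients

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_ply",
    "write_ply",
    "read_landmarks",
    "write_landmarks",
    "read_seeds",
    "write_seeds",
    "read_coefficients_csv",
    "write_coefficients_csv",
    "read_atlas_csv",
    "write_atlas_csv",
    "read_raw_volume",
    "write_raw_volume",
    "read_dicom_series",
    "read_s1_workbook",
]


# ---------------------------------------------------------------- point clouds

def write_xyz(path: str | Path, points: np.ndarray) -> None:
    points = np.asarray(points, dtype=float)
    np.savetxt(path, points, fmt="%.9g")


def read_xyz(path: str | Path) -> np.ndarray:
    points = np.loadtxt(path, dtype=float, ndmin=2)
    if points.shape[1] != 3:
        raise ValueError(f"{path}: expected whitespace-separated x y z triples")
    return points


def write_ply(path: str | Path, points: np.ndarray) -> None:
    """ASCII PLY vertex cloud (properties x y z, no faces)."""
    points = np.asarray(points, dtype=float)
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {len(points)}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "end_header\n"
        )
        for x, y, z in points:
            fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


def read_ply(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path}: not a PLY file")
        n_vertex = None
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated PLY header")
            token = line.strip()
            if token.startswith("format") and "ascii" not in token:
                raise ValueError(f"{path}: only ASCII PLY is supported")
            if token.startswith("element vertex"):
                n_vertex = int(token.split()[-1])
            if token == "end_header":
                break
        if n_vertex is None:
            raise ValueError(f"{path}: missing 'element vertex' in header")
        rows = [fh.readline().split()[:3] for _ in range(n_vertex)]
    return np.asarray(rows, dtype=float).reshape(n_vertex, 3)


# ------------------------------------------------------------------ landmarks

def write_landmarks(path: str | Path, landmarks: LandmarkSet) -> None:
    data = {name: [float(v) for v in getattr(landmarks, name)] for name in LANDMARK_NAMES}
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Landmark file: JSON mapping {A..F: [x, y, z]} or CSV (name, x, y, z)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        frame = pd.read_csv(path)
        frame.columns = [c.strip().lower() for c in frame.columns]
        data = {
            str(row["name"]).strip(): [row["x"], row["y"], row["z"]]
            for _, row in frame.iterrows()
        }
    else:
        data = json.loads(path.read_text())
    missing = [n for n in LANDMARK_NAMES if n not in data]
    extra = [n for n in data if n not in LANDMARK_NAMES]
    if missing or extra:
        raise ValueError(
            f"{path}: landmark names must be exactly A..F "
            f"(missing {missing or 'none'}, unexpected {extra or 'none'})"
        )
    return LandmarkSet(**{n: np.asarray(data[n], dtype=float) for n in LANDMARK_NAMES})


# ---------------------------------------------------------------------- seeds

def write_seeds(path: str | Path, seeds: Sequence[SeedSpec]) -> None:
    data = [
        {"slice": s.slice_index, "row": s.row, "col": s.col, "tolerance": s.tolerance}
        for s in seeds
    ]
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def read_seeds(path: str | Path) -> list[SeedSpec]:
    data = json.loads(Path(path).read_text())
    return [
        SeedSpec(
            slice_index=int(d["slice"]),
            row=int(d["row"]),
            col=int(d["col"]),
            tolerance=float(d.get("tolerance", 0.2)),
        )
        for d in data
    ]


# --------------------------------------------------------------- coefficients

def write_coefficients_csv(path: str | Path, coeffs: SpharmCoefficients) -> None:
    """Per-bone coefficient table: columns q, l, m, c; scale/order in comments."""
    spec = BasisSpec(coeffs.order)
    with open(path, "w") as fh:
        fh.write(f"# order_L={coeffs.order}\n# scale_radius_mm={float(coeffs.scale)!r}\n")
        fh.write("q,l,m,c\n")
        for q, ((l, m), c) in enumerate(zip(spec.degrees_orders, coeffs.values), start=1):
            fh.write(f"{q},{l},{m},{float(c)!r}\n")


def read_coefficients_csv(path: str | Path) -> SpharmCoefficients:
    scale, order = None, None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            if key.strip() == "scale_radius_mm":
                scale = float(value)
            elif key.strip() == "order_L":
                order = int(value)
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    values = frame.sort_values("q")["c"].to_numpy(dtype=float)
    if order is None:
        order = int(round(np.sqrt(values.size))) - 1
    if scale is None:
        raise ValueError(f"{path}: missing '# scale_radius_mm=' header")
    return SpharmCoefficients(values=values, scale=scale, order=order)


def write_atlas_csv(path: str | Path, matrix: np.ndarray, scale_radii: np.ndarray, order: int) -> None:
    """Wide atlas table: one row per bone, columns c_q plus the scale radius."""
    spec = BasisSpec(order)
    cols = [f"c{q}_l{l}_m{m}" for q, (l, m) in enumerate(spec.degrees_orders, start=1)]
    frame = pd.DataFrame(np.asarray(matrix, dtype=float), columns=cols)
    frame.insert(0, "scale_radius_mm", np.asarray(scale_radii, dtype=float))
    frame.to_csv(path, index=False)


def read_atlas_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    frame = pd.read_csv(path)
    radii = frame.pop("scale_radius_mm").to_numpy(dtype=float)
    return frame.to_numpy(dtype=float), radii


# -------------------------------------------------------------------- volumes

def write_raw_volume(json_path: str | Path, volume: Volume) -> None:
    """Raw-array + JSON-metadata fixture: keys shape, spacing_mm, dtype, data."""
    json_path = Path(json_path)
    data_path = json_path.with_suffix(".raw")
    arr = np.asarray(volume.intensities, dtype=np.float32)
    arr.tofile(data_path)
    meta = {
        "shape": list(arr.shape),
        "spacing_mm": list(volume.spacing),
        "dtype": str(arr.dtype),
        "data": data_path.name,
        "frame_note": volume.frame_note,
    }
    json_path.write_text(json.dumps(meta, indent=2) + "\n")


def read_raw_volume(json_path: str | Path) -> Volume:
    json_path = Path(json_path)
    meta = json.loads(json_path.read_text())
    data_path = json_path.parent / meta["data"]
    arr = np.fromfile(data_path, dtype=np.dtype(meta["dtype"])).reshape(meta["shape"])
    return Volume(
        intensities=arr.astype(float),
        spacing=tuple(meta["spacing_mm"]),
        frame_note=meta.get("frame_note", "FFS"),
    )


def read_dicom_series(directory: str | Path) -> Volume:
    """Read a DICOM series into a Volume (requires the optional pydicom).

    Pixel Spacing (0028,0030) supplies xt, yt and Slice Thickness
    (0018,0050) zt; slices are ordered by Instance Number.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("DICOM input requires the optional 'pydicom' package") from exc
    paths = sorted(Path(directory).glob("*.dcm"))
    if not paths:
        raise ValueError(f"{directory}: no .dcm files found")
    datasets = [pydicom.dcmread(p) for p in paths]
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    first = datasets[0]
    yt, xt = (float(v) for v in first.PixelSpacing)
    zt = float(first.SliceThickness)
    stack = np.stack([d.pixel_array.astype(float) for d in datasets], axis=2)
    return Volume(
        intensities=stack,
        spacing=(xt, yt, zt),
        frame_note=str(getattr(first, "PatientPosition", "FFS")),
    )


# ------------------------------------------------- supplementary-style tables

def read_s1_workbook(path: str | Path) -> dict[str, np.ndarray]:
    """Read a wide per-side coefficient table (cohort supplementary layout).

    Accepts an .xlsx workbook (one sheet per side named 'left'/'right', or a
    single sheet with a 'side' column) or a CSV with a 'side' column; the
    remaining numeric columns are the Q coefficients per bone.  Returns
    {'left': (bones x Q), 'right': (bones x Q)}.  Note: the legacy binary
    .xls container is not supported — convert to .xlsx or CSV first.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path}: supplementary coefficient table not found; place the cohort "
            "coefficient data (xlsx or csv conversion) at this path"
        )
    if path.suffix.lower() == ".csv":
        sheets = {"": pd.read_csv(path)}
    elif path.suffix.lower() == ".xlsx":
        sheets = pd.read_excel(path, sheet_name=None, engine="openpyxl")
    else:
        raise ValueError(f"{path}: expected .xlsx or .csv (legacy .xls unsupported)")

    out: dict[str, np.ndarray] = {}
    for name, frame in sheets.items():
        cols_lower = {str(c).strip().lower(): c for c in frame.columns}
        if "side" in cols_lower:
            side_col = cols_lower["side"]
            for side, sub in frame.groupby(frame[side_col].astype(str).str.lower()):
                numeric = sub.drop(columns=[side_col]).select_dtypes("number")
                out[side] = numeric.to_numpy(dtype=float)
        else:
            key = str(name).strip().lower()
            if key in ("left", "right"):
                out[key] = frame.select_dtypes("number").to_numpy(dtype=float)
    if set(out) != {"left", "right"}:
        raise ValueError(
            f"{path}: could not identify left/right coefficient blocks "
            "(need 'left'/'right' sheets or a 'side' column)"
        )
    return out
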