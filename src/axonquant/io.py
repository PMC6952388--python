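"""File I/O: TIFF images with pixel-size metadata, profile/trace/score CSVs,
and ground-truth JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidInputError
from .geometry import AxonTrace
from .profiles import ImageFrame, ImageStack, LineProfile


# ---------------------------------------------------------------- TIFF

def save_frame(path, frame: ImageFrame) -> None:
    """Write a single-plane grayscale TIFF with pixel size in the
    resolution tags (pixels per µm, ImageJ-style unit metadata)."""
    res = 1.0 / frame.pixel_size_xy
    tifffile.imwrite(path, frame.pixels.astype(np.float32),
                     resolution=(res, res), metadata={"unit": "um"},
                     imagej=True)


def save_stack(path, stack: ImageStack) -> None:
    res = 1.0 / stack.pixel_size_xy
    tifffile.imwrite(path, stack.planes.astype(np.float32),
                     resolution=(res, res),
                     metadata={"unit": "um", "spacing": stack.plane_spacing_z},
                     imagej=True)


def _pixel_size_from_tif(tif) -> float:
    page = tif.pages[0]
    try:
        num, den = page.tags["XResolution"].value
        if num > 0:
            return den / num
    except (KeyError, TypeError, ZeroDivisionError):
        pass
    return None


def load_frame(path, pixel_size: float = None) -> ImageFrame:
    """Read a grayscale TIFF; pixel size from metadata unless overridden."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_px = _pixel_size_from_tif(tif)
    data = np.squeeze(np.asarray(data, dtype=float))
    if data.ndim != 2:
        raise InvalidInputError(f"{path}: expected a single plane, got shape {data.shape}")
    px = pixel_size if pixel_size is not None else meta_px
    if px is None:
        raise InvalidInputError(f"{path}: no pixel size in metadata; pass pixel_size")
    return ImageFrame(data, px)


def load_stack(path, pixel_size: float = None, plane_spacing_z: float = 0.130) -> ImageStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_px = _pixel_size_from_tif(tif)
        ij = tif.imagej_metadata or {}
    data = np.squeeze(np.asarray(data, dtype=float))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise InvalidInputError(f"{path}: expected a z-stack, got shape {data.shape}")
    px = pixel_size if pixel_size is not None else meta_px
    if px is None:
        raise InvalidInputError(f"{path}: no pixel size in metadata; pass pixel_size")
    return ImageStack(data, px, ij.get("spacing", plane_spacing_z))


# ---------------------------------------------------------------- traces

def save_trace(path, trace: AxonTrace) -> None:
    """Polyline as CSV (x_um, y_um) or JSON depending on suffix."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps({"vertices_um": trace.vertices.tolist()}))
    else:
        pd.DataFrame(trace.vertices, columns=["x_um", "y_um"]).to_csv(path, index=False)


def load_trace(path) -> AxonTrace:
    path = Path(path)
    if path.suffix == ".json":
        return AxonTrace(np.asarray(json.loads(path.read_text())["vertices_um"], float))
    df = pd.read_csv(path)
    return AxonTrace(df[["x_um", "y_um"]].to_numpy(float))


# ---------------------------------------------------------------- profiles

def save_profile(path, profile: LineProfile) -> None:
    df = pd.DataFrame({
        "arc_length_um": profile.arc_positions,
        "raw_au": profile.raw,
        "normalized_au": (np.full(len(profile), np.nan)
                          if profile.normalized is None else profile.normalized),
        "excluded": profile.exclusion_mask.astype(int),
    })
    df.to_csv(path, index=False)


def load_profile(path) -> LineProfile:
    df = pd.read_csv(path)
    x = df["arc_length_um"].to_numpy(float)
    if len(x) < 2:
        raise InvalidInputError(f"{path}: profile needs >= 2 samples")
    norm = df["normalized_au"].to_numpy(float) if "normalized_au" in df else None
    if norm is not None and np.all(np.isnan(norm)):
        norm = None
    return LineProfile(
        sampling_interval=float(x[1] - x[0]),
        arc_positions=x,
        raw=df["raw_au"].to_numpy(float),
        exclusion_mask=df["excluded"].to_numpy(bool) if "excluded" in df else None,
        normalized=norm,
    )


# ---------------------------------------------------------------- tables / truth

def save_ground_truth(path, truth) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def load_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def load_scored_table(path) -> pd.DataFrame:
    """Scored-animal table: either (condition, n, x) counts or long-form
    (animal_id, condition, broken) rows, which are aggregated."""
    df = pd.read_csv(path)
    if {"condition", "n", "x"}.issubset(df.columns):
        return df[["condition", "n", "x"]]
    if {"condition", "broken"}.issubset(df.columns):
        g = df.groupby("condition")["broken"]
        return pd.DataFrame({"condition": g.size().index,
                             "n": g.size().to_numpy(),
                             "x": g.sum().to_numpy().astype(int)})
    raise InvalidInputError(f"{path}: need columns (condition, n, x) or (condition, broken)")
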