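"""Readers, writers and validated configuration for the pipeline's external formats.

The pipeline touches four kinds of files: grayscale TIFF image stacks,
delimited trajectory tables produced by an upstream single-molecule
localization engine, ROI definitions (named polygons or label masks with a
role tag), and a flat YAML configuration.  Conventions used throughout:

* pixel coordinates are 0-based ``(row=y, col=x)`` with the origin at the
  top-left pixel; physical coordinates are micrometres from the image origin;
* image stacks are always normalized to a ``(frame, channel, y, x)`` axis
  order;
* a pixel belongs to a polygon ROI iff its *center* lies strictly inside the
  polygon (half-open rasterization), which keeps masks deterministic and
  area-consistent.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
import yaml
from shapely.geometry import Polygon

__all__ = [
    "ImageStack",
    "TrajectorySet",
    "Roi",
    "RoiSet",
    "ROI_ROLES",
    "read_image_stack",
    "write_image_stack",
    "read_trajectories",
    "write_trajectories",
    "read_rois",
    "write_rois",
    "load_config",
    "save_config",
    "CONFIG_DEFAULTS",
]

TRAJECTORY_COLUMNS = ("track_id", "frame", "t_s", "x_um", "y_um")
OPTIONAL_TRAJECTORY_COLUMNS = ("z_um", "sx_um", "sy_um", "sz_um")

ROI_ROLES = frozenset(
    {"bleached", "control", "whole_condensate", "background", "cell", "polar"}
)


@dataclass
class ImageStack:
    """A grayscale image stack with physical calibration.

    Parameters
    ----------
    pixels
        Intensity array indexed ``(frame, channel, y, x)``.
    pixel_size
        Lateral pixel size in μm/px (must be positive).
    frame_interval
        Time between consecutive frames in seconds (0 for a single snapshot).
    channel_names
        One label per channel.
    """

    pixels: np.ndarray
    pixel_size: float
    frame_interval: float = 0.0
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None, None]
        elif self.pixels.ndim == 3:
            self.pixels = self.pixels[:, None]
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must be 2D, 3D or 4D, got ndim={self.pixels.ndim}"
            )
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.frame_interval < 0:
            raise ValueError("frame_interval must be >= 0")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image stack contains non-finite intensities")
        if not self.channel_names:
            self.channel_names = tuple(
                f"ch{i}" for i in range(self.pixels.shape[1])
            )
        if len(self.channel_names) != self.pixels.shape[1]:
            raise ValueError("channel_names length does not match channel axis")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds."""
        return np.arange(self.n_frames) * self.frame_interval

    def frame(self, i: int, channel: int = 0) -> np.ndarray:
        return self.pixels[i, channel]


@dataclass
class TrajectorySet:
    """Localized single-molecule tracks with a common time base.

    ``data`` holds one row per localization with columns ``track_id``,
    ``frame``, ``t_s``, ``x_um``, ``y_um`` and optionally ``z_um`` and the
    per-axis precisions ``sx_um``/``sy_um``/``sz_um``.  Within a track the
    frame index is strictly increasing.
    """

    data: pd.DataFrame
    frame_interval: float

    def __post_init__(self) -> None:
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        missing = [c for c in TRAJECTORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns: {missing}")
        coords = [c for c in ("x_um", "y_um", "z_um") if c in self.data.columns]
        if not np.all(np.isfinite(self.data[coords].to_numpy(float))):
            raise ValueError("trajectory coordinates must be finite")
        if self.data.duplicated(subset=["track_id", "frame"]).any():
            dup = self.data[self.data.duplicated(["track_id", "frame"], keep=False)]
            pair = tuple(dup.iloc[0][["track_id", "frame"]])
            raise ValueError(f"duplicate (track_id, frame) pair, e.g. {pair}")
        self.data = self.data.sort_values(["track_id", "frame"], kind="stable")
        self.data = self.data.reset_index(drop=True)

    @property
    def has_z(self) -> bool:
        return "z_um" in self.data.columns

    @property
    def track_ids(self) -> np.ndarray:
        return self.data["track_id"].unique()

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def __len__(self) -> int:
        return len(self.data)

    def tracks(self) -> Iterator[tuple[int, pd.DataFrame]]:
        """Iterate ``(track_id, frame-sorted sub-table)`` pairs."""
        yield from self.data.groupby("track_id", sort=True)


@dataclass
class Roi:
    """One named region: either a polygon (pixel coordinates) or a boolean mask."""

    role: str
    polygon: np.ndarray | None = None  # (N, 2) array of (x, y) vertices
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.role not in ROI_ROLES:
            raise ValueError(
                f"unknown ROI role {self.role!r}; expected one of {sorted(ROI_ROLES)}"
            )
        if (self.polygon is None) == (self.mask is None):
            raise ValueError("exactly one of polygon or mask must be given")
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, dtype=float)
            if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
                raise ValueError("polygon must be an (N, 2) vertex array")
            if len(self.polygon) < 3:
                raise ValueError("polygon needs at least 3 vertices")
            if not Polygon(self.polygon).is_valid:
                raise ValueError("polygon is self-intersecting or degenerate")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize onto an image of ``shape`` = (ny, nx), center-inside rule."""
        if self.mask is not None:
            if self.mask.shape != tuple(shape):
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match image {shape}"
                )
            return self.mask
        ny, nx = shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        poly = Polygon(self.polygon)
        inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel())
        return inside.reshape(ny, nx)


@dataclass
class RoiSet:
    """A named collection of :class:`Roi` regions."""

    rois: dict[str, Roi] = field(default_factory=dict)

    def add(self, name: str, roi: Roi) -> None:
        self.rois[name] = roi

    def __getitem__(self, name: str) -> Roi:
        return self.rois[name]

    def __contains__(self, name: str) -> bool:
        return name in self.rois

    def __len__(self) -> int:
        return len(self.rois)

    def by_role(self, role: str) -> list[Roi]:
        return [r for r in self.rois.values() if r.role == role]

    def role_mask(self, role: str, shape: tuple[int, int]) -> np.ndarray:
        """Union mask of every ROI carrying ``role``; error if none exist."""
        rois = self.by_role(role)
        if not rois:
            raise ValueError(f"no ROI with role {role!r}")
        out = np.zeros(shape, dtype=bool)
        for r in rois:
            out |= r.to_mask(shape)
        if not out.any():
            raise ValueError(f"ROI(s) with role {role!r} rasterize to an empty mask")
        return out


# ---------------------------------------------------------------------------
# image stacks


def read_image_stack(
    path: str | Path,
    pixel_size: float,
    frame_interval: float = 0.0,
    n_channels: int = 1,
    channel_names: Sequence[str] = (),
) -> ImageStack:
    """Read a grayscale single- or multi-page TIFF into an :class:`ImageStack`.

    Pages are interpreted as frames; for a multi-channel acquisition the
    channel count must be declared (pages are then grouped
    frame-major, i.e. page index = frame * n_channels + channel).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 3:
        if arr.shape[-1] in (3, 4) and arr.shape[-1] != arr.shape[-2]:
            raise ValueError(
                f"{path} looks like an RGB(A) image; declare a channel mapping "
                "or convert to grayscale"
            )
        if n_channels > 1:
            if arr.shape[0] % n_channels:
                raise ValueError(
                    f"{arr.shape[0]} pages not divisible by n_channels={n_channels}"
                )
            arr = arr.reshape(-1, n_channels, *arr.shape[1:])
        else:
            arr = arr[:, None]
    if arr.ndim != 4:
        raise ValueError(f"cannot interpret {path} with shape {arr.shape}")
    return ImageStack(
        pixels=arr,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        channel_names=tuple(channel_names),
    )


def write_image_stack(path: str | Path, stack: ImageStack) -> None:
    """Write as a multi-page grayscale TIFF (frame-major, channel-minor pages).

    Integer data round-trips bit-exactly through :func:`read_image_stack`.
    """
    f, c, ny, nx = stack.shape
    pages = stack.pixels.reshape(f * c, ny, nx)
    tifffile.imwrite(Path(path), pages)


# ---------------------------------------------------------------------------
# trajectories


def read_trajectories(path: str | Path, frame_interval: float) -> TrajectorySet:
    """Read a delimited localization table into a :class:`TrajectorySet`.

    The header must name at least ``track_id``, ``frame``, ``x_um``, ``y_um``
    (``track_id, frame, x, y`` are accepted as aliases).  A missing ``t_s``
    column is derived as ``frame * frame_interval``; missing z/precision
    columns simply yield absent optional fields.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    df = pd.read_csv(path)
    df = df.rename(columns={"x": "x_um", "y": "y_um", "z": "z_um", "t": "t_s"})
    required = ["track_id", "frame", "x_um", "y_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in df.columns:
        if col == "track_id":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() and df[col].notna().any():
            bad = df[col][vals.isna() & df[col].notna()].iloc[0]
            raise ValueError(f"{path}: non-numeric value {bad!r} in column {col}")
        df[col] = vals
    if "t_s" not in df.columns:
        df["t_s"] = df["frame"] * frame_interval
    keep = [c for c in (*TRAJECTORY_COLUMNS, *OPTIONAL_TRAJECTORY_COLUMNS)
            if c in df.columns]
    return TrajectorySet(data=df[keep], frame_interval=frame_interval)


def write_trajectories(path: str | Path, trajs: TrajectorySet) -> None:
    trajs.data.to_csv(Path(path), index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# ROIs


def write_rois(path: str | Path, rois: RoiSet) -> None:
    """Serialize an :class:`RoiSet` to structured text (JSON)."""
    payload = {}
    for name, roi in rois.rois.items():
        entry: dict = {"role": roi.role}
        if roi.polygon is not None:
            entry["polygon"] = roi.polygon.tolist()
        else:
            entry["mask_shape"] = list(roi.mask.shape)
            entry["mask_true_pixels"] = np.argwhere(roi.mask).tolist()
        payload[name] = entry
    Path(path).write_text(json.dumps(payload, indent=1))


def read_rois(path: str | Path) -> RoiSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ROI file not found: {path}")
    payload = json.loads(path.read_text())
    out = RoiSet()
    for name, entry in payload.items():
        if "polygon" in entry:
            out.add(name, Roi(role=entry["role"], polygon=np.asarray(entry["polygon"])))
        else:
            mask = np.zeros(tuple(entry["mask_shape"]), dtype=bool)
            idx = np.asarray(entry["mask_true_pixels"], dtype=int)
            if len(idx):
                mask[idx[:, 0], idx[:, 1]] = True
            out.add(name, Roi(role=entry["role"], mask=mask))
    return out


# ---------------------------------------------------------------------------
# configuration

CONFIG_DEFAULTS: dict[str, float | int | str] = {
    "pixel_size_um": 0.1,
    "frame_interval_s": 0.02,
    "sigma_loc_um": 0.03,
    "lag_frames": 1,
    "dims": 2,
    "n_components": 1,
    "filamentous_threshold_um": 4.0,
    "leakage_fold_threshold": 5.0,
    "segmentation_method": "otsu",
    "fixed_threshold": 0.0,
    "min_area_um2": 0.05,
    "smoothing_sd_px": 1.0,
    "spot_prominence_fraction": 0.3,
    "spot_min_separation_um": 0.4,
    "condensate_min_size_um": 0.0,
    "frap_mode": "literal",
    "frap_bleach_frame": 3,
    "frap_eps_rel": 1e-6,
    "seed": 0,
}

_CONFIG_TYPES = {k: type(v) for k, v in CONFIG_DEFAULTS.items()}


def load_config(path: str | Path | None = None) -> dict:
    """Load the flat YAML configuration, validating keys and types.

    Unknown keys are rejected with a close-match suggestion; absent keys are
    filled with their documented defaults.  ``None`` (or an empty file)
    yields the pure defaults.
    """
    cfg = dict(CONFIG_DEFAULTS)
    if path is None:
        return cfg
    text = Path(path).read_text()
    user = yaml.safe_load(text) or {}
    if not isinstance(user, Mapping):
        raise ValueError(f"config {path} must be a mapping, got {type(user).__name__}")
    for key, value in user.items():
        if key not in CONFIG_DEFAULTS:
            hint = difflib.get_close_matches(key, CONFIG_DEFAULTS, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {key!r}{suggestion}")
        expected = _CONFIG_TYPES[key]
        if expected is float and isinstance(value, int):
            value = float(value)
        if not isinstance(value, expected):
            raise ValueError(
                f"config key {key!r}: expected {expected.__name__}, "
                f"got {type(value).__name__} ({value!r})"
            )
        cfg[key] = value
    return cfg


def save_config(path: str | Path, cfg: Mapping) -> None:
    unknown = set(cfg) - set(CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    Path(path).write_text(yaml.safe_dump(dict(cfg), sort_keys=True))
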