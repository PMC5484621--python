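"""Multiwell grid geometry: well ROIs and the pixel-to-animal mapping.

A recording images a rectangular array of circular wells, one animal per
well.  The grid is supplied explicitly by configuration (rows, cols, origin,
center-to-center pitch, well radius); it is never auto-detected from images.
Pixel coordinates are 0-based ``(x=column, y=row)`` with the origin at the
top-left of the frame, a convention used consistently across the package.

Each well's region of interest (ROI) is the disk of integer pixels within
Euclidean distance ``well_radius_px`` of the well center.  ROIs of a valid
map are pairwise disjoint, so pixel-to-well assignment is a partial function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError

__all__ = ["WellMap", "build_well_map", "load_well_map"]


@dataclass(frozen=True)
class WellMap:
    """Geometry of a multiwell grid and its per-well circular ROIs.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; wells are indexed row-major, ``well = row * n_cols + col``.
    well_centers
        ``(n_wells, 2)`` float array of ``(x, y)`` pixel centers.
    well_radius_px
        ROI radius in pixels.
    plate_id
        Opaque label carried into tidy outputs.
    censor_mask
        Per-well boolean; ``True`` marks wells excluded from analysis
        (e.g. known escapees supplied by an external censor list).
    """

    n_rows: int
    n_cols: int
    well_centers: np.ndarray
    well_radius_px: float
    plate_id: str = "plate"
    censor_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        centers = np.asarray(self.well_centers, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "well_centers", centers)
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError("grid must have at least one row and column")
        if len(centers) != self.n_rows * self.n_cols:
            raise ConfigurationError(
                f"{len(centers)} centers for a {self.n_rows}x{self.n_cols} grid"
            )
        if self.well_radius_px < 0:
            raise ConfigurationError("well radius must be non-negative")
        mask = self.censor_mask
        if mask is None:
            mask = np.zeros(len(centers), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (len(centers),):
            raise ConfigurationError("censor_mask length must equal well count")
        object.__setattr__(self, "censor_mask", mask)

    @property
    def n_wells(self) -> int:
        return len(self.well_centers)

    def pixels_in_well(self, well_index: int) -> np.ndarray:
        """Integer ``(x, y)`` pixels within Euclidean distance r of the center.

        Radius 0 returns exactly the (rounded) center pixel.
        """
        if not 0 <= well_index < self.n_wells:
            raise IndexError(f"well index {well_index} out of range")
        cx, cy = self.well_centers[well_index]
        r = self.well_radius_px
        if r == 0:
            return np.array([[int(round(cx)), int(round(cy))]], dtype=int)
        xs = np.arange(int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1)
        ys = np.arange(int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1)
        gx, gy = np.meshgrid(xs, ys)
        keep = (gx - cx) ** 2 + (gy - cy) ** 2 <= r * r
        return np.column_stack([gx[keep], gy[keep]]).astype(int)

    def roi_indices(self, frame_shape: tuple[int, int]) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-well ``(rows, cols)`` index arrays for fancy indexing into frames.

        Validates at bind time that every ROI lies inside the frame bounds.
        """
        h, w = frame_shape
        out = []
        for i in range(self.n_wells):
            px = self.pixels_in_well(i)
            x, y = px[:, 0], px[:, 1]
            if x.min() < 0 or y.min() < 0 or x.max() >= w or y.max() >= h:
                raise ConfigurationError(
                    f"well {i} ROI extends outside the {h}x{w} frame"
                )
            out.append((y, x))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Audit export: one row per well with grid position and center."""
        rows, cols = np.divmod(np.arange(self.n_wells), self.n_cols)
        return pd.DataFrame(
            {
                "well_index": np.arange(self.n_wells),
                "row": rows,
                "col": cols,
                "center_x": self.well_centers[:, 0],
                "center_y": self.well_centers[:, 1],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_well_map(
    rows: int,
    cols: int,
    origin: tuple[float, float],
    pitch_px: float,
    radius_px: float,
    plate_id: str = "plate",
) -> WellMap:
    """Construct a regular grid of wells.

    Centers are ``origin + (col * pitch, row * pitch)``.  Purely a function of
    its arguments (idempotent).  Raises :class:`ConfigurationError` when the
    pitch would make adjacent ROIs overlap (``pitch <= 2 * radius``).
    """
    if rows < 1 or cols < 1:
        raise ConfigurationError("rows and cols must be >= 1")
    if radius_px > 0 and (rows > 1 or cols > 1) and pitch_px <= 2 * radius_px:
        raise ConfigurationError(
            f"pitch {pitch_px} px <= 2 * radius {radius_px} px: ROIs would overlap"
        )
    ox, oy = origin
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    centers = np.column_stack([ox + cc.ravel() * pitch_px, oy + rr.ravel() * pitch_px])
    return WellMap(rows, cols, centers, radius_px, plate_id=plate_id)


def load_well_map(source) -> WellMap:
    """Build a :class:`WellMap` from a YAML/JSON file path or a dict.

    Expected keys: ``rows, cols, origin_x, origin_y, pitch_px, radius_px``
    and optionally ``plate_id``.
    """
    if isinstance(source, dict):
        cfg = source
    else:
        text = open(source).read()
        cfg = yaml.safe_load(text) if not str(source).endswith(".json") else json.loads(text)
    try:
        return build_well_map(
            int(cfg["rows"]),
            int(cfg["cols"]),
            (float(cfg["origin_x"]), float(cfg["origin_y"])),
            float(cfg["pitch_px"]),
            float(cfg["radius_px"]),
            plate_id=str(cfg.get("plate_id", "plate")),
        )
    except KeyError as exc:  # pragma: no cover - error path
        raise ConfigurationError(f"well-map config missing key {exc}") from exc
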