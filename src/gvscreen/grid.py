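"""Well-plate geometry: mapping wells and background regions to pixel ROIs.

Samples sit in a rectangular grid of wells cast into an agarose phantom
(96 = 8 x 12 by default) and are imaged from above, so each well appears as
a disk in the scan image.  Background ROIs are disks placed in the empty
agarose between wells; the signal-to-background ratios divide well means by
the pooled background mean.

Pixel convention: 0-based row-major coordinates with pixel centers at
integer positions; a pixel belongs to an ROI when the Euclidean distance
from its center to the ROI center is <= the radius (ties included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> plate-style name, e.g. (0, 0) -> 'A1'."""
    if row < 0 or col < 0 or row >= 26:
        raise ValueError(f"invalid well indices ({row}, {col})")
    return f"{chr(ord('A') + row)}{col + 1}"


def well_indices(name: str) -> tuple[int, int]:
    row = ord(name[0].upper()) - ord("A")
    col = int(name[1:]) - 1
    if row < 0 or col < 0:
        raise ValueError(f"invalid well name {name!r}")
    return row, col


@dataclass(frozen=True)
class WellGrid:
    """Geometry of sample wells and background ROIs in a phantom image."""

    n_rows: int = 8
    n_cols: int = 12
    origin: tuple[float, float] = (30.0, 30.0)  # (row, col) px of well A1 center
    pitch: tuple[float, float] = (60.0, 60.0)
    roi_radius: float = 18.0
    background_centers: tuple[tuple[float, float], ...] = ()
    background_radius: float = 18.0
    image_shape: tuple[int, int] = (480, 720)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one well")
        if self.roi_radius <= 0 or self.background_radius <= 0:
            raise ValueError("ROI radii must be positive")
        h, w = self.image_shape
        for (cy, cx), r in self._all_rois():
            if cy - r < 0 or cx - r < 0 or cy + r > h - 1 or cx + r > w - 1:
                raise ValueError(
                    f"ROI at ({cy}, {cx}) radius {r} exceeds image bounds {self.image_shape}"
                )
        for bc in self.background_centers:
            for row in range(self.n_rows):
                for col in range(self.n_cols):
                    wc = self.well_center(row, col)
                    d = np.hypot(wc[0] - bc[0], wc[1] - bc[1])
                    if d <= self.roi_radius + self.background_radius:
                        raise ValueError(
                            f"background ROI at {bc} overlaps well "
                            f"{well_name(row, col)}"
                        )

    def _all_rois(self):
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                yield self.well_center(row, col), self.roi_radius
        for bc in self.background_centers:
            yield bc, self.background_radius

    def well_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin[0] + row * self.pitch[0],
            self.origin[1] + col * self.pitch[1],
        )

    def well_names(self) -> list[str]:
        return [
            well_name(r, c)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
        ]

    def disk_mask(
        self, center: tuple[float, float], radius: float
    ) -> tuple[slice, slice, np.ndarray]:
        """Bounding-box slices plus boolean membership mask for one disk."""
        cy, cx = center
        h, w = self.image_shape
        y0, y1 = max(0, int(np.floor(cy - radius))), min(h, int(np.ceil(cy + radius)) + 1)
        x0, x1 = max(0, int(np.floor(cx - radius))), min(w, int(np.ceil(cx + radius)) + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        return slice(y0, y1), slice(x0, x1), mask

    @classmethod
    def standard(
        cls,
        n_rows: int = 8,
        n_cols: int = 12,
        roi_radius: float = 18.0,
        pitch: float | None = None,
        n_background: int = 4,
        background_radius: float | None = None,
    ) -> "WellGrid":
        """A grid with sensible spacing and background disks placed on the
        diagonal inter-well midpoints of the first row."""
        background_radius = background_radius or roi_radius
        pitch = pitch if pitch is not None else float(
            np.ceil((roi_radius + background_radius + 2) * np.sqrt(2)) + 2
        )
        margin = max(roi_radius, background_radius) + 2
        origin = (margin, margin)
        half = pitch / 2.0
        centers = []
        n_per_row = max(1, n_cols - 1)
        for k in range(n_background):
            row, col = divmod(k, n_per_row)
            cy = origin[0] + row * pitch + half
            cx = origin[1] + col * pitch + half
            centers.append((cy, cx))
        max_y = max(
            [origin[0] + (n_rows - 1) * pitch + roi_radius]
            + [cy + background_radius for cy, _ in centers]
        )
        max_x = max(
            [origin[1] + (n_cols - 1) * pitch + roi_radius]
            + [cx + background_radius for _, cx in centers]
        )
        h = int(np.ceil(max_y + 2)) + 1
        w = int(np.ceil(max_x + 2)) + 1
        return cls(
            n_rows=n_rows,
            n_cols=n_cols,
            origin=origin,
            pitch=(pitch, pitch),
            roi_radius=roi_radius,
            background_centers=tuple(centers),
            background_radius=background_radius,
            image_shape=(h, w),
        )

    def to_yaml(self, path) -> None:
        data = {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "origin": list(self.origin),
            "pitch": list(self.pitch),
            "roi_radius": self.roi_radius,
            "background_centers": [list(c) for c in self.background_centers],
            "background_radius": self.background_radius,
            "image_shape": list(self.image_shape),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "WellGrid":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            n_rows=data["n_rows"],
            n_cols=data["n_cols"],
            origin=tuple(data["origin"]),
            pitch=tuple(data["pitch"]),
            roi_radius=data["roi_radius"],
            background_centers=tuple(tuple(c) for c in data.get("background_centers", [])),
            background_radius=data["background_radius"],
            image_shape=tuple(data["image_shape"]),
        )
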