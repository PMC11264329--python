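"""Per-well ultrasound signal quantification.

Two signal-to-background ratios are computed from nonlinear-signal images,
with all ROI means taken over disks defined by a :class:`~gvscreen.grid.WellGrid`:

* **nonlinear difference SBR** — for pre/post-collapse pairs acquired at the
  same transmit voltage::

      (precollapse sample mean - postcollapse sample mean)
      -----------------------------------------------------
                 postcollapse background mean

  The subtraction cancels everything that survives collapse, isolating the
  GV-specific nonlinear signal.  Negative values (pure noise) are retained
  so null distributions stay symmetric.

* **plain nonlinear SBR** — ``sample mean / background mean``, used for
  collapse-ramp scans where each frame stands alone.

Collapse-ramp curves are summarized by a four-parameter logistic decay
``f(x) = baseline + plateau / (1 + exp((x - midpoint) / width))``; the fitted
midpoint is reported as the collapse pressure (or voltage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .grid import WellGrid, well_name
from .phantom import COLLAPSE_RAMP, POSTCOLLAPSE, PRECOLLAPSE, PRE_POST, VOLTAGE_RAMP, ScanStack


@dataclass(frozen=True)
class ROIStats:
    """Per-well sample means and the pooled background mean of one image."""

    well_means: dict[str, float]
    well_pixel_counts: dict[str, int]
    background_mean: float
    background_pixel_count: int
    voltage: float | None = None


def roi_means(
    image: np.ndarray, grid: WellGrid, voltage: float | None = None
) -> ROIStats:
    """Arithmetic ROI means: per-well disks plus all background disks pooled
    (weighted by pixel count, i.e. a single mean over the union)."""
    if image.shape != grid.image_shape:
        raise ValueError(
            f"image shape {image.shape} != grid image_shape {grid.image_shape}"
        )
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            ys, xs, mask = grid.disk_mask(grid.well_center(r, c), grid.roi_radius)
            pixels = image[ys, xs][mask]
            if pixels.size == 0:
                raise ValueError(f"empty ROI for well {well_name(r, c)}")
            means[well_name(r, c)] = float(pixels.mean())
            counts[well_name(r, c)] = int(pixels.size)
    total = 0.0
    n_bg = 0
    for center in grid.background_centers:
        ys, xs, mask = grid.disk_mask(center, grid.background_radius)
        pixels = image[ys, xs][mask]
        total += float(pixels.sum())
        n_bg += int(pixels.size)
    if n_bg == 0:
        raise ValueError("grid defines no background pixels")
    return ROIStats(
        well_means=means,
        well_pixel_counts=counts,
        background_mean=total / n_bg,
        background_pixel_count=n_bg,
        voltage=voltage,
    )


def sbr(stats: ROIStats) -> dict[str, float]:
    """Plain nonlinear SBR: sample mean / background mean, per well."""
    if stats.background_mean <= 0:
        raise ValueError("background mean must be positive")
    return {w: m / stats.background_mean for w, m in stats.well_means.items()}


def nonlinear_difference_sbr(pre: ROIStats, post: ROIStats) -> dict[str, float]:
    """Nonlinear difference SBR per well.

    The pre- and post-collapse stats must come from frames acquired at the
    same voltage (checked when both carry voltage metadata).
    """
    if pre.voltage is not None and post.voltage is not None:
        if pre.voltage != post.voltage:
            raise ValueError(
                f"pre/post voltage mismatch: {pre.voltage} vs {post.voltage}"
            )
    if post.background_mean <= 0:
        raise ValueError("postcollapse background mean must be positive")
    if set(pre.well_means) != set(post.well_means):
        raise ValueError("pre/post stats cover different wells")
    return {
        w: (pre.well_means[w] - post.well_means[w]) / post.background_mean
        for w in pre.well_means
    }


@dataclass(frozen=True)
class SBRCurve:
    """Per-well (abscissa, SBR) pairs from a ramp scan; abscissa strictly
    increasing (voltage by default, pressure if converted upstream)."""

    x: tuple[float, ...]
    y: tuple[float, ...]
    kind: str  # "diff_sbr" or "sbr"

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError("x and y differ in length")
        if any(b <= a for a, b in zip(self.x, self.x[1:])):
            raise ValueError("abscissa must be strictly increasing")


def ramp_curves(stack: ScanStack, grid: WellGrid) -> dict[str, SBRCurve]:
    """SBR curves per well from a ramp stack.

    voltage_ramp: difference SBR per precollapse frame against its
    same-voltage postcollapse partner.  collapse_ramp: plain SBR per frame.
    """
    scan_type = stack.scan_type
    meta = stack.meta
    if scan_type == COLLAPSE_RAMP:
        points: dict[str, list[tuple[float, float]]] = {}
        order = meta.sort_values("voltage", kind="stable")
        for _, row in order.iterrows():
            stats = roi_means(
                stack.frames[int(row.frame_index)], grid, voltage=float(row.voltage)
            )
            for w, v in sbr(stats).items():
                points.setdefault(w, []).append((float(row.voltage), v))
        return {
            w: SBRCurve(tuple(p[0] for p in pts), tuple(p[1] for p in pts), "sbr")
            for w, pts in points.items()
        }
    if scan_type in (VOLTAGE_RAMP, PRE_POST):
        pre_rows = meta[meta["phase"] == PRECOLLAPSE].sort_values("voltage")
        post_rows = meta[meta["phase"] == POSTCOLLAPSE]
        points = {}
        for _, row in pre_rows.iterrows():
            partners = post_rows[post_rows["voltage"] == row.voltage]
            if len(partners) == 0:
                raise ValueError(
                    f"no postcollapse frame at voltage {row.voltage}"
                )
            post_row = partners.iloc[0]
            pre = roi_means(
                stack.frames[int(row.frame_index)], grid, voltage=float(row.voltage)
            )
            post = roi_means(
                stack.frames[int(post_row.frame_index)],
                grid,
                voltage=float(post_row.voltage),
            )
            for w, v in nonlinear_difference_sbr(pre, post).items():
                points.setdefault(w, []).append((float(row.voltage), v))
        return {
            w: SBRCurve(tuple(p[0] for p in pts), tuple(p[1] for p in pts), "diff_sbr")
            for w, pts in points.items()
        }
    raise ValueError(f"unsupported scan type {scan_type!r}")


def pre_post_difference_sbr(stack: ScanStack, grid: WellGrid) -> dict[str, float]:
    """Single difference SBR per well from a pre/post stack."""
    curves = ramp_curves(stack, grid)
    out = {}
    for w, curve in curves.items():
        if len(curve.y) != 1:
            raise ValueError("pre/post stack has more than one voltage")
        out[w] = curve.y[0]
    return out


@dataclass(frozen=True)
class CollapseFit:
    """Logistic-decay fit of a collapse-ramp SBR curve."""

    baseline: float
    plateau: float
    midpoint: float
    width: float
    residual_norm: float
    success: bool


def _logistic_decay(x, baseline, plateau, midpoint, width):
    z = np.clip((x - midpoint) / width, -500.0, 500.0)
    return baseline + plateau / (1.0 + np.exp(z))


def fit_collapse_midpoint(
    curve: SBRCurve,
    normalize: bool = False,
    residual_tol: float = 0.2,
) -> CollapseFit:
    """Least-squares fit of ``baseline + plateau / (1 + exp((x-mid)/width))``.

    ``normalize=True`` divides the curve by its maximum first, so collapse
    midpoints can be compared across samples with different contrast ("
    normalized for nonlinear contrast").  The fit is flagged unsuccessful —
    without raising — when the curve is flat, the optimizer fails, the
    midpoint leaves the scanned range, or the rms residual exceeds
    ``residual_tol`` times the data range.
    """
    if len(curve.x) < 4:
        raise ValueError("need at least 4 points to fit a collapse curve")
    x = np.asarray(curve.x, dtype=float)
    y = np.asarray(curve.y, dtype=float)
    if normalize:
        top = np.max(np.abs(y))
        if top > 0:
            y = y / top
    span = float(y.max() - y.min())
    if span <= 1e-12:
        return CollapseFit(float(y.mean()), 0.0, np.nan, np.nan, 0.0, False)
    # initial guesses: half-decay crossing for the midpoint
    baseline0 = float(y.min())
    plateau0 = span
    half = baseline0 + plateau0 / 2.0
    below = np.nonzero(y <= half)[0]
    mid0 = float(x[below[0]]) if below.size else float(x[len(x) // 2])
    width0 = max((x[-1] - x[0]) / 10.0, 1e-6)
    try:
        popt, _ = curve_fit(
            _logistic_decay,
            x,
            y,
            p0=(baseline0, plateau0, mid0, width0),
            bounds=(
                (-np.inf, 0.0, -np.inf, 1e-12),
                (np.inf, np.inf, np.inf, np.inf),
            ),
            maxfev=10000,
        )
    except RuntimeError:
        return CollapseFit(np.nan, np.nan, np.nan, np.nan, np.inf, False)
    baseline, plateau, midpoint, width = (float(v) for v in popt)
    resid = y - _logistic_decay(x, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    ok = (
        width > 0
        and x[0] <= midpoint <= x[-1]
        and rms <= residual_tol * span
    )
    return CollapseFit(baseline, plateau, midpoint, width, rms, ok)


def to_decibels(
    image: np.ndarray, reference: float, floor: float = -60.0
) -> np.ndarray:
    """Amplitude image in dB re ``reference``: 20*log10(pixel/reference);
    non-positive pixels map to the floor."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    img = np.asarray(image, dtype=float)
    out = np.full(img.shape, floor, dtype=float)
    pos = img > 0
    out[pos] = np.maximum(20.0 * np.log10(img[pos] / reference), floor)
    return out


def quantify_stack(
    stack: ScanStack,
    grid: WellGrid,
    fit_collapse: bool = True,
) -> pd.DataFrame:
    """Tabulate per-well metrics for any scan type.

    pre_post: one row per well with ``diff_sbr``.  voltage_ramp: one row per
    (well, voltage) with ``diff_sbr``.  collapse_ramp: one row per (well,
    voltage) with ``sbr`` plus, optionally, the fitted collapse midpoint.
    """
    scan_type = stack.scan_type
    rows = []
    curves = ramp_curves(stack, grid)
    fits: Mapping[str, CollapseFit] = {}
    if scan_type == COLLAPSE_RAMP and fit_collapse:
        fits = {
            w: fit_collapse_midpoint(c)
            for w, c in curves.items()
            if len(c.x) >= 4
        }
    for w in sorted(curves):
        curve = curves[w]
        for xv, yv in zip(curve.x, curve.y):
            row = {"well": w, "voltage": xv, "scan_type": scan_type}
            row["diff_sbr" if curve.kind == "diff_sbr" else "sbr"] = yv
            if w in fits:
                row["collapse_midpoint"] = fits[w].midpoint
                row["fit_success"] = fits[w].success
            rows.append(row)
    return pd.DataFrame(rows)
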