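"""Lane geometry, per-row profile integration, baselines and measurements.

A lane is a two-dimensional region of the image described by a polyline of
control nodes ``(row y, center x, half-width w)``, linearly interpolated in
both ``x`` and ``w`` between nodes. Because protein migration separates
molecules along the vertical axis, the lane's signal is collapsed to a
*profile*: for every integer row the image intensity is summed horizontally
across the lane width. The profile is therefore intensity as a function of
the vertical (migration) coordinate, which is what preserves band selections
when a lane is nudged sideways, and why lanes may curve but never run
horizontally — node rows must strictly increase.

A *measurement* integrates the profile minus a per-lane baseline over a
chosen vertical region. Units: the profile is intensity*px (a row sum), the
measurement value is intensity*px^2 (a sum of row sums).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .imageproc import Raster

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LanePath:
    """Polyline of lane-center control nodes ``(y, x, half_width)``.

    Node rows must strictly increase (no horizontal segment); half-widths
    are positive. ``x`` and ``w`` are linearly interpolated between nodes.
    """

    nodes: tuple

    def __init__(self, nodes):
        nodes = tuple((float(y), float(x), float(w)) for (y, x, w) in nodes)
        if len(nodes) < 2:
            raise ValidationError("a lane path needs at least 2 nodes")
        rows = [n[0] for n in nodes]
        for a, b in zip(rows, rows[1:]):
            if b <= a:
                raise ValidationError(
                    "horizontal segment: lane node rows must strictly increase "
                    f"(got {a} then {b})"
                )
        if any(n[2] <= 0 for n in nodes):
            raise ValidationError("lane half-widths must be > 0")
        object.__setattr__(self, "nodes", nodes)

    @property
    def rows(self) -> np.ndarray:
        return np.array([n[0] for n in self.nodes])

    @property
    def row_span(self) -> tuple[float, float]:
        return self.nodes[0][0], self.nodes[-1][0]

    def to_params(self) -> dict:
        return {"nodes": [list(n) for n in self.nodes]}

    @classmethod
    def from_params(cls, d: dict) -> "LanePath":
        return cls(d["nodes"])


def validate_path(p: LanePath, image_shape: tuple[int, int]) -> LanePath:
    """Check ``p`` against an image; returns ``p`` unchanged if acceptable.

    Node rows must lie within the image's rows. A lane whose width extends
    past the left/right image edge is allowed (it will be clipped during
    integration) but logged, since this is usually the result of a tight
    crop rather than intent.
    """
    h, w = image_shape
    y0, y1 = p.row_span
    if y0 < 0 or y1 > h - 1:
        raise ValidationError(
            f"lane path rows [{y0}, {y1}] outside image rows [0, {h - 1}]"
        )
    for y, x, hw in p.nodes:
        if x - hw < 0 or x + hw > w - 1:
            log.warning(
                "lane extends past image columns at row %s (center %s, half-width %s); "
                "it will be clipped",
                y, x, hw,
            )
            break
    return p


def lane_center(p: LanePath, y: float) -> tuple[float, float]:
    """Interpolated ``(center x, half-width w)`` of the lane at row ``y``."""
    y0, y1 = p.row_span
    if not (y0 <= y <= y1):
        raise ValidationError(f"row {y} outside lane span [{y0}, {y1}]")
    rows = p.rows
    xs = np.array([n[1] for n in p.nodes])
    ws = np.array([n[2] for n in p.nodes])
    return float(np.interp(y, rows, xs)), float(np.interp(y, rows, ws))


@dataclass
class LaneProfile:
    """Per-row integrated lane intensity ``p[y]`` starting at row ``y_start``."""

    y_start: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValidationError("profile values must be a 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("profile values must be finite")

    @property
    def y_end(self) -> int:
        """One past the last profile row (half-open span)."""
        return self.y_start + len(self.values)

    def value_at(self, y: int) -> float:
        if not (self.y_start <= y < self.y_end):
            raise ValidationError(f"row {y} outside profile span")
        return float(self.values[y - self.y_start])


def lane_profile(r: Raster, p: LanePath) -> LaneProfile:
    """Integrate the image across the lane width, row by row.

    For each integer row ``y`` spanned by the path, sums ``r[y, x]`` over the
    integer columns whose center lies within the interpolated half-width:
    ``|x - x_c(y)| <= w(y)``, clipped to the image. Integration is horizontal
    (along the row), not perpendicular to the path, so the profile is exactly
    a pixel sum — no resampling.
    """
    validate_path(p, r.shape)
    y0, y1 = p.row_span
    ys = np.arange(math.ceil(y0), math.floor(y1) + 1)
    rows = p.rows
    xs = np.array([n[1] for n in p.nodes])
    ws = np.array([n[2] for n in p.nodes])
    xc = np.interp(ys, rows, xs)
    hw = np.interp(ys, rows, ws)
    lo = np.maximum(np.ceil(xc - hw).astype(int), 0)
    hi = np.minimum(np.floor(xc + hw).astype(int), r.shape[1] - 1)
    values = np.zeros(len(ys))
    px = r.pixels
    for i, y in enumerate(ys):
        if lo[i] <= hi[i]:
            values[i] = px[y, lo[i] : hi[i] + 1].sum()
    return LaneProfile(int(ys[0]), values)


@dataclass(frozen=True)
class Baseline:
    """Per-lane background reference under the profile.

    Piecewise-linear through user anchors ``(row y, value b >= 0)``, constant
    extrapolation beyond the first/last anchor. The default baseline is a
    single anchor at zero, i.e. no per-lane correction beyond the whole-image
    background subtraction.
    """

    anchors: tuple = ((0.0, 0.0),)

    def __init__(self, anchors=((0.0, 0.0),)):
        anchors = tuple((float(y), float(b)) for (y, b) in anchors)
        if not anchors:
            raise ValidationError("baseline needs at least one anchor")
        rows = [a[0] for a in anchors]
        if any(b <= a for a, b in zip(rows, rows[1:])):
            raise ValidationError("baseline anchor rows must strictly increase")
        if any((not math.isfinite(a[1])) or a[1] < 0 for a in anchors):
            raise ValidationError("baseline values must be finite and >= 0")
        object.__setattr__(self, "anchors", anchors)

    def to_params(self) -> dict:
        return {"anchors": [list(a) for a in self.anchors]}

    @classmethod
    def from_params(cls, d: dict) -> "Baseline":
        return cls(d["anchors"])


def baseline_at(b: Baseline, y: float) -> float:
    """Baseline value at row ``y`` (constant beyond the anchor span)."""
    rows = np.array([a[0] for a in b.anchors])
    vals = np.array([a[1] for a in b.anchors])
    return float(np.interp(y, rows, vals))


@dataclass(frozen=True)
class MeasurementRegion:
    """Half-open vertical integration bounds ``[y0, y1)`` on a profile."""

    y0: int
    y1: int

    def __post_init__(self):
        if self.y0 >= self.y1:
            raise ValidationError("measurement region needs y0 < y1")

    def to_params(self) -> dict:
        return {"y0": int(self.y0), "y1": int(self.y1)}

    @classmethod
    def from_params(cls, d: dict) -> "MeasurementRegion":
        return cls(int(d["y0"]), int(d["y1"]))


@dataclass
class RawMeasurement:
    """Raw integrated value ``v`` for one lane/region/measurement type."""

    value: float
    lane_index: int = 0
    measurement_type: str = "measurement"
    success: bool = True

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise ValidationError("measurement value must be finite")


def measure(
    profile: LaneProfile,
    b: Baseline,
    region: MeasurementRegion,
    lane_index: int = 0,
    measurement_type: str = "measurement",
) -> RawMeasurement:
    """Integrate profile-minus-baseline over ``region``.

    ``v = sum_{y=y0}^{y1-1} (p[y] - baseline(y))``. A negative value is
    allowed (it means the baseline sits above the signal) but logged as a
    warning. The success flag starts out true; failures are a curator's
    judgement recorded later, not something this function decides.
    """
    if region.y0 < profile.y_start or region.y1 > profile.y_end:
        raise ValidationError(
            f"region [{region.y0}, {region.y1}) outside profile span "
            f"[{profile.y_start}, {profile.y_end})"
        )
    ys = np.arange(region.y0, region.y1)
    p = profile.values[region.y0 - profile.y_start : region.y1 - profile.y_start]
    rows = np.array([a[0] for a in b.anchors])
    vals = np.array([a[1] for a in b.anchors])
    base = np.interp(ys, rows, vals)
    v = float(np.sum(p - base))
    if v < 0:
        log.warning(
            "negative measurement value %.6g on lane %d: baseline above signal",
            v, lane_index,
        )
    return RawMeasurement(v, lane_index=lane_index, measurement_type=measurement_type)
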