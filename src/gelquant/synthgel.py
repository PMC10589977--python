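"""Deterministic synthetic gel/membrane images with known ground truth.

Real membranes offer no ground truth: the amount of protein behind a band is
exactly what densitometry is trying to estimate. This module renders gel-like
images where the injected amount of every band is known by construction, so
the whole pipeline — background subtraction, curved-lane profile extraction,
bounded integration, reference normalization — can be tested end to end
against the truth.

A lane follows a parabolic center line ``x(y) = x0 + c * (y - H/2)^2``
(curvature ``c = 0`` gives a straight lane); each band is a 2-D Gaussian
whose horizontal center tracks the lane's curve, normalized so that its
pixel sum equals the injected amount ``A`` up to discretization (< 0.5 %
for sigmas >= 1 px). The background is a planar gradient plus an optional
broad Gaussian blob; noise is i.i.d. Gaussian, seeded, with a default
standard deviation of 1 % of the peak band intensity. The image is clamped
at zero. The same spec and seed always produce a bit-identical raster.

What this does *not* emulate: membrane texture, chemiluminescence
saturation, ladder bleed-through, dust. Passing tests show the geometry and
arithmetic of the pipeline are right, not that any stain behaves linearly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import ValidationError
from .imageproc import Raster
from .lanes import LanePath
from .normalization import LaneRecord
from .serialize import canonical_json


@dataclass(frozen=True)
class BandSpec:
    """One band: vertical center ``row_mu``, sigmas in px, injected amount A."""

    row_mu: float
    sigma_y: float
    sigma_x: float
    amount: float

    def __post_init__(self):
        if self.amount <= 0:
            raise ValidationError("band amount must be > 0")
        if self.sigma_y <= 0 or self.sigma_x <= 0:
            raise ValidationError("band sigmas must be > 0")


@dataclass(frozen=True)
class LaneSpec:
    """One lane: parabolic center ``x(y) = x0 + curvature*(y - H/2)^2``.

    ``protein`` and ``is_reference`` carry the sample metadata used when the
    lane is part of a reference panel; they do not affect rendering.
    """

    x0: float
    curvature: float = 0.0
    half_width: float = 6.0
    bands: tuple = ()
    sample_id: str = ""
    protein: float | None = None
    is_reference: bool = False

    def center_at(self, y, height: int):
        return self.x0 + self.curvature * (np.asarray(y, dtype=float) - height / 2.0) ** 2


@dataclass(frozen=True)
class SynthSpec:
    """Full description of a synthetic gel image."""

    height: int
    width: int
    lanes: tuple
    #: planar background ``b0 + by*y + bx*x``
    background_gradient: tuple = (0.0, 0.0, 0.0)
    #: amplitude of a broad centered Gaussian blob added to the background
    blob_amplitude: float = 0.0
    #: noise standard deviation; None = 1% of the peak band intensity
    noise_sigma: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValidationError("image must be at least 1x1")
        object.__setattr__(self, "lanes", tuple(self.lanes))


@dataclass
class GroundTruth:
    """Known truth for a rendered image."""

    band_amounts: list  # per lane: list of injected amounts A
    lane_totals: list  # per lane: sum of its band amounts
    background: np.ndarray  # noise-free background field

    def to_json(self) -> str:
        return canonical_json(
            {
                "band_amounts": self.band_amounts,
                "lane_totals": self.lane_totals,
            }
        )


def _validate(spec: SynthSpec) -> None:
    h, w = spec.height, spec.width
    ys = np.arange(h, dtype=float)
    for li, lane in enumerate(spec.lanes):
        for band in lane.bands:
            if not (3 * band.sigma_y <= band.row_mu <= h - 1 - 3 * band.sigma_y):
                raise ValidationError(
                    f"band at row {band.row_mu} (lane {li}) outside image at 3 sigma"
                )
            xc = lane.center_at(band.row_mu, h)
            if not (3 * band.sigma_x <= xc <= w - 1 - 3 * band.sigma_x):
                raise ValidationError(
                    f"band at column {xc:.1f} (lane {li}) outside image at 3 sigma"
                )
    # lanes must not overlap at 3 sigma horizontally
    for i in range(len(spec.lanes)):
        for j in range(i + 1, len(spec.lanes)):
            a, b = spec.lanes[i], spec.lanes[j]
            sa = max((bd.sigma_x for bd in a.bands), default=0.0)
            sb = max((bd.sigma_x for bd in b.bands), default=0.0)
            gap = np.min(np.abs(a.center_at(ys, h) - b.center_at(ys, h)))
            if gap <= 3 * (sa + sb):
                raise ValidationError(
                    f"lanes {i} and {j} overlap at 3 sigma (min center gap {gap:.1f} px)"
                )


def generate(spec: SynthSpec) -> tuple[Raster, GroundTruth]:
    """Render the image described by ``spec``.

    Returns the raster and its ground truth. Deterministic: the same spec
    (including seed) renders a bit-identical image.
    """
    _validate(spec)
    h, w = spec.height, spec.width
    yy = np.arange(h, dtype=float)[:, None]
    xx = np.arange(w, dtype=float)[None, :]

    signal = np.zeros((h, w))
    band_amounts, lane_totals = [], []
    for lane in spec.lanes:
        xc = lane.center_at(yy, h)  # column of the lane center at each row
        amounts = []
        for band in lane.bands:
            gy = np.exp(-0.5 * ((yy - band.row_mu) / band.sigma_y) ** 2)
            gx = np.exp(-0.5 * ((xx - xc) / band.sigma_x) ** 2)
            norm = 2.0 * math.pi * band.sigma_x * band.sigma_y
            signal += band.amount / norm * gy * gx
            amounts.append(band.amount)
        band_amounts.append(amounts)
        lane_totals.append(float(sum(amounts)))

    b0, by, bx = spec.background_gradient
    background = b0 + by * yy + bx * xx + np.zeros((h, w))
    if spec.blob_amplitude:
        sig = min(h, w) / 3.0
        background += spec.blob_amplitude * np.exp(
            -0.5 * (((yy - h / 2) ** 2 + (xx - w / 2) ** 2) / sig**2)
        )
    if np.any(background < 0):
        raise ValidationError("background field must be non-negative")

    noise_sigma = spec.noise_sigma
    if noise_sigma is None:
        peak = float(signal.max())
        noise_sigma = 0.01 * peak if peak > 0 else 0.0

    pixels = signal + background
    if noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        pixels = pixels + rng.normal(0.0, noise_sigma, size=(h, w))
    np.clip(pixels, 0.0, None, out=pixels)

    truth = GroundTruth(band_amounts, lane_totals, background)
    return Raster(pixels), truth


def lane_path_for(spec: SynthSpec, lane_index: int, n_nodes: int = 9) -> LanePath:
    """Lane path tracking the true (possibly curved) lane center.

    A parabola is not a polyline, so the path samples the center line at
    ``n_nodes`` rows; with the default 9 nodes the chord error is well below
    a pixel for realistic curvatures.
    """
    lane = spec.lanes[lane_index]
    ys = np.linspace(0, spec.height - 1, n_nodes)
    xs = lane.center_at(ys, spec.height)
    return LanePath([(y, x, lane.half_width) for y, x in zip(ys, xs)])


def render_reference_panel(spec: SynthSpec):
    """Render a panel whose lanes carry sample metadata for normalization tests.

    Uses the ``protein``/``is_reference`` fields of each :class:`LaneSpec`.
    Returns ``(raster, truth, lane_records, true_normalized)`` where
    ``true_normalized[j]`` is the normalized value an ideal pipeline would
    recover for lane j: ``(A_j/m_j) / mean over reference lanes of (A_i/m_i)``
    with ``A`` the lane's total injected amount.
    """
    refs = [lane for lane in spec.lanes if lane.is_reference]
    if not refs:
        raise ValidationError("reference panel needs at least one reference lane")
    if any(lane.protein is None for lane in spec.lanes):
        raise ValidationError("reference panel lanes all need a protein amount")

    raster, truth = generate(spec)
    records = [
        LaneRecord(
            lane_index=i,
            sample_id=lane.sample_id or f"S{i}",
            protein=lane.protein,
            is_reference=lane.is_reference,
        )
        for i, lane in enumerate(spec.lanes)
    ]
    per_protein = [t / lane.protein for t, lane in zip(truth.lane_totals, spec.lanes)]
    r_true = np.mean([per_protein[i] for i, lane in enumerate(spec.lanes) if lane.is_reference])
    true_w = [v / r_true for v in per_protein]
    return raster, truth, records, true_w


def write_fixture(raster: Raster, truth: GroundTruth, path) -> np.ndarray:
    """Write a 16-bit TIFF plus a canonical-JSON ground-truth sidecar.

    Intensities are rounded to uint16 (clipped at 65535); the written grid is
    returned so tests can assert bit-identical round trips. The sidecar is
    ``<path>.truth.json``.
    """
    path = Path(path)
    grid = np.clip(np.rint(raster.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, grid)
    Path(str(path) + ".truth.json").write_text(truth.to_json() + "\n")
    return grid
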