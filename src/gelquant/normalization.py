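"""Reference-lane normalization of raw lane measurements.

Raw integrated intensities v are comparable only within an image. To compare
samples across images and gels, each gel carries one or more *reference*
lanes loaded with a common sample. Per image, the reference value is the
average loading-corrected signal of the successful reference lanes,

    r = (1/R) * sum_i v_i / m_i ,

where m_i is the protein amount loaded in reference lane i and R counts only
reference lanes whose measurement is flagged successful (R may be 1). Every
successful lane j is then reported as the dimensionless normalized value

    w_j = (1/r) * (v_j / m_j) .

By construction the mean of w over the successful reference lanes is exactly
1, and w is invariant under any global rescaling of the image intensities
and under rescaling all protein amounts by a common factor.

Normalization is strictly per-image; cross-gel comparability comes from
physically sharing reference samples across gels, not from any additional
statistical model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import NoReferenceError, ValidationError
from .lanes import RawMeasurement

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LaneRecord:
    """Sample metadata attached to one gel lane.

    ``protein`` is the amount of sample loaded (in whatever mass unit the
    experiment uses, typically µg); ``is_reference`` marks the lane as a
    cross-gel reference sample.
    """

    lane_index: int
    sample_id: str = ""
    protein: float | None = None
    is_reference: bool = False

    def __post_init__(self):
        if self.protein is not None and self.protein <= 0:
            raise ValidationError(
                f"lane {self.lane_index}: protein amount must be > 0"
            )


@dataclass(frozen=True)
class ReferenceValue:
    """Per-image reference value ``r`` and the count ``R`` of lanes used."""

    r: float
    R: int


@dataclass(frozen=True)
class NormalizedValue:
    lane_index: int
    w: float


def _lane_map(lanes) -> dict[int, LaneRecord]:
    by_index: dict[int, LaneRecord] = {}
    for lane in lanes:
        if lane.lane_index in by_index:
            raise ValidationError(f"duplicate lane_index {lane.lane_index}")
        by_index[lane.lane_index] = lane
    return by_index


def reference_value(measurements, lanes) -> ReferenceValue:
    """Average loading-corrected signal over successful reference lanes.

    Lanes without a protein amount cannot participate and are skipped with
    a warning. Raises :class:`NoReferenceError` when no successful reference
    lane remains.
    """
    by_index = _lane_map(lanes)
    terms = []
    for m in measurements:
        lane = by_index.get(m.lane_index)
        if lane is None or not lane.is_reference or not m.success:
            continue
        if lane.protein is None:
            log.warning(
                "reference lane %d has no protein amount; excluded from the "
                "reference average", lane.lane_index,
            )
            continue
        terms.append(m.value / lane.protein)
    if not terms:
        raise NoReferenceError(
            "no reference: the image has no successful reference lane with a "
            "protein amount"
        )
    return ReferenceValue(r=sum(terms) / len(terms), R=len(terms))


def normalized_values(measurements, lanes, ref: ReferenceValue) -> list[NormalizedValue]:
    """Normalized value ``w = (v/m)/r`` for every successful measurement.

    Unsuccessful measurements and lanes without a protein amount are omitted
    (the latter with a warning). Raises on a degenerate (zero) reference.
    """
    if ref.r == 0:
        raise ValidationError("degenerate reference: r == 0")
    by_index = _lane_map(lanes)
    out = []
    for m in measurements:
        if not m.success:
            continue
        lane = by_index.get(m.lane_index)
        if lane is None:
            raise ValidationError(f"measurement for unknown lane {m.lane_index}")
        if lane.protein is None:
            log.warning(
                "lane %d has no protein amount; raw value not normalized",
                lane.lane_index,
            )
            continue
        out.append(
            NormalizedValue(lane_index=m.lane_index, w=(m.value / lane.protein) / ref.r)
        )
    return out
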