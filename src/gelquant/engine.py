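"""Drives a full image analysis and replays logged analyses.

An analysis is described declaratively by a parameter document::

    {
      "invert": false,              # polarity flip at read time
      "page": null,                 # page of a multi-page TIFF
      "crop": {"top": .., "left": .., "height": .., "width": ..} | null,
      "background": {"method": "rolling_ball", "radius": 50},
      "measurement_type": "GAPDH",
      "lanes": [
        {"lane_index": 0,
         "path": {"nodes": [[y, x, half_width], ...]},
         "baseline": {"anchors": [[y, b], ...]},      # optional, default 0
         "regions": [{"y0": .., "y1": ..}, ...]}
      ]
    }

    Instead of explicit anchors, a lane's baseline may be given as
    ``{"auto_rows": [y1, y2, ...], "halfspan": k}``: the engine anchors the
    baseline at those rows with the mean profile value over ``y +/- k`` rows
    (clamped at zero). This emulates the interactive gesture of pinning the
    baseline to band-free stretches of the profile. The *resolved* numeric
    anchors are what gets logged, so replay never depends on the resolution
    rule.

:func:`analyze_image` executes it, stores every resulting measurement, and
records each operation with its full parameters in the store's analysis log.
:func:`replay` re-executes the log from scratch against the stored source
image (whose content hash must still match) and checks that every recomputed
value equals the stored one bit for bit.
"""

from __future__ import annotations

import numpy as np

from . import imageproc, lanes
from .datastore import GelStore, file_hash
from .errors import ReplayMismatchError, StoreError
from .imageproc import BackgroundSpec, CropRect
from .lanes import Baseline, LanePath, MeasurementRegion


def _check_source(store: GelStore, image_id: int) -> dict:
    img = store.image_record(image_id)
    actual = file_hash(img["path"])
    if actual != img["content_hash"]:
        raise StoreError(
            f"source image changed: {img['path']} no longer matches the hash "
            "recorded at ingest"
        )
    return img


def _run_steps(img: dict, steps):
    """Execute analysis-log steps in order; yield recomputed measurements."""
    raster = None
    results = []
    for _idx, op, params in steps:
        if op == "read_image":
            raster = imageproc.read_image(
                img["path"], invert=bool(params.get("invert", False)),
                page=params.get("page"),
            )
        elif op == "crop":
            raster = imageproc.crop(raster, CropRect.from_params(params))
        elif op == "subtract_background":
            raster = imageproc.subtract_background(
                raster, BackgroundSpec.from_params(params)
            )
        elif op == "measure_lane":
            path = LanePath.from_params(params["path"])
            baseline = Baseline.from_params(params["baseline"])
            profile = lanes.lane_profile(raster, path)
            for reg in params["regions"]:
                region = MeasurementRegion.from_params(reg)
                m = lanes.measure(
                    profile, baseline, region,
                    lane_index=int(params["lane_index"]),
                    measurement_type=params["measurement_type"],
                )
                results.append(
                    {
                        "measurement_type": m.measurement_type,
                        "lane_index": m.lane_index,
                        "region_y0": region.y0,
                        "region_y1": region.y1,
                        "value": m.value,
                    }
                )
        else:  # pragma: no cover - record_step already rejects these
            raise StoreError(f"unknown operation {op!r} in analysis log")
    return results


def _resolve_baseline(baseline_params: dict, raster, path: LanePath) -> Baseline:
    """Turn a baseline description into concrete anchors.

    Explicit ``anchors`` pass through. ``auto_rows`` are resolved against the
    lane's profile on the background-subtracted raster: each anchor takes the
    mean profile value over ``row +/- halfspan`` rows (default 4), clamped at
    zero.
    """
    if "auto_rows" in baseline_params:
        halfspan = int(baseline_params.get("halfspan", 4))
        profile = lanes.lane_profile(raster, path)
        anchors = []
        for row in baseline_params["auto_rows"]:
            row = int(row)
            lo = max(row - halfspan, profile.y_start)
            hi = min(row + halfspan, profile.y_end - 1)
            vals = profile.values[lo - profile.y_start : hi + 1 - profile.y_start]
            anchors.append((float(row), max(float(np.mean(vals)), 0.0)))
        return Baseline(anchors)
    return Baseline.from_params(baseline_params)


def analyze_image(store: GelStore, image_id: int, params: dict):
    """Run the analysis described by ``params``, log it, store the results.

    Any previous analysis of the image is replaced (log and measurements).
    Returns the list of stored measurement dicts.
    """
    img = _check_source(store, image_id)
    mtype = params.get("measurement_type", "measurement")

    steps = [("read_image", {"invert": bool(params.get("invert", False)),
                             "page": params.get("page")})]
    raster = imageproc.read_image(img["path"], invert=bool(params.get("invert", False)),
                                  page=params.get("page"))
    if params.get("crop"):
        rect = CropRect.from_params(params["crop"])
        steps.append(("crop", rect.to_params()))
        raster = imageproc.crop(raster, rect)
    bg = BackgroundSpec.from_params(params.get("background", {"method": "none"}))
    steps.append(("subtract_background", bg.to_params()))
    raster = imageproc.subtract_background(raster, bg)

    for lane in params.get("lanes", []):
        path = LanePath.from_params(lane["path"])
        baseline = _resolve_baseline(
            lane.get("baseline", {"anchors": [[0.0, 0.0]]}), raster, path
        )
        regions = [MeasurementRegion.from_params(r).to_params() for r in lane["regions"]]
        steps.append(
            ("measure_lane", {
                "lane_index": int(lane["lane_index"]),
                "measurement_type": mtype,
                "path": path.to_params(),
                "baseline": baseline.to_params(),
                "regions": regions,
            })
        )

    # validate by executing first; only a successful run is logged
    results = _run_steps(img, [(i, op, p) for i, (op, p) in enumerate(steps)])

    store.clear_analysis(image_id)
    for op, p in steps:
        store.record_step(image_id, op, p)
    for res in results:
        store.store_measurement(
            image_id, res["measurement_type"], res["lane_index"],
            res["region_y0"], res["region_y1"], res["value"],
        )
    return results


def replay(store: GelStore, image_id: int):
    """Re-execute the image's analysis log and verify the stored values.

    Every recomputed measurement must equal its stored counterpart exactly
    (bit-identical float64); any difference, missing row, or extra row
    raises :class:`ReplayMismatchError`. An empty log returns no
    measurements. Returns the recomputed measurement dicts.
    """
    steps = store.steps(image_id)
    if not steps:
        store.image_record(image_id)  # still validate the image exists
        return []
    img = _check_source(store, image_id)
    results = _run_steps(img, steps)

    stored = store.measurements(image_id)
    stored_map = {
        (row.measurement_type, int(row.lane_index), int(row.region_y0),
         int(row.region_y1)): float(row.value)
        for row in stored.itertuples()
    }
    mismatches = []
    seen = set()
    for res in results:
        key = (res["measurement_type"], res["lane_index"],
               res["region_y0"], res["region_y1"])
        seen.add(key)
        if key not in stored_map:
            mismatches.append((key, None, res["value"]))
        elif stored_map[key] != res["value"]:
            mismatches.append((key, stored_map[key], res["value"]))
    for key, value in stored_map.items():
        if key not in seen:
            mismatches.append((key, value, None))
    if mismatches:
        raise ReplayMismatchError(
            f"replay of image {image_id} disagrees with {len(mismatches)} stored "
            "measurement(s)", mismatches,
        )
    return results
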