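"""Persist an analysis in the embedded store, replay it, and export tables.

Writes a synthetic fixture image, registers gel + lanes + image in a SQLite
store, runs a logged analysis, then (1) replays the analysis log and checks
the stored values bit-for-bit and (2) exports the raw and normalized result
tables. The replay succeeding is the package's reproducibility guarantee:
the store alone is sufficient to re-derive every number.
"""

import tempfile
from pathlib import Path

import pandas as pd

from gelquant import analyze_image, open_store, render_reference_panel, replay, write_fixture
from gelquant.cli import reference_panel_params, reference_panel_spec

tmp = Path(tempfile.mkdtemp())
spec = reference_panel_spec(seed=8)
raster, truth, lane_records, _ = render_reference_panel(spec)
write_fixture(raster, truth, tmp / "gel.tif")

store = open_store(tmp / "analysis.db")
gel_id = store.add_gel("demo gel", comment="synthetic 3-lane panel")
for rec in lane_records:
    store.set_lane(gel_id, rec)
image_id = store.add_image(gel_id, tmp / "gel.tif")

results = analyze_image(store, image_id, reference_panel_params(spec))
print(f"analyzed image {image_id}: {len(results)} measurements, "
      f"{len(store.steps(image_id))} logged steps")

verified = replay(store, image_id)
print(f"replay reproduced {len(verified)} stored values bit-identically")

files = store.export_spreadsheet(tmp / "results.csv")
norm = pd.read_csv(files[1])
print(norm[["gel", "lane", "sample_id", "m", "v", "r", "w"]].to_string(index=False))
# Each row links a sample to its raw integrated intensity v and its
# normalized value w = (v/m)/r; w near 1 means loading-equivalent signal.
# At the generator's 1% noise level, single-band w values scatter a few
# percent around their true value of 1 — note that an error in the
# reference lane shifts every w on the image by the same factor.
store.close()
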