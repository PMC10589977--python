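import numpy as np
import pytest

from gelquant import (
    BandSpec,
    LaneRecord,
    LaneSpec,
    Raster,
    SynthSpec,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


@pytest.fixture
def random_raster(rng):
    def make(h=50, w=50, scale=100.0):
        return Raster(rng.uniform(0, scale, size=(h, w)))

    return make


def single_band_spec(amount=20000.0, x0=30.0, curvature=0.0, row_mu=60.0,
                     sigma=2.5, half_width=8.0, background=(0.0, 0.0, 0.0),
                     noise_sigma=0.0, seed=0, height=120, width=60, **lane_kw):
    """One lane, one band; the workhorse fixture for measurement tests."""
    lane = LaneSpec(
        x0=x0, curvature=curvature, half_width=half_width,
        bands=(BandSpec(row_mu=row_mu, sigma_y=sigma, sigma_x=sigma,
                        amount=amount),),
        **lane_kw,
    )
    return SynthSpec(height=height, width=width, lanes=(lane,),
                     background_gradient=background, noise_sigma=noise_sigma,
                     seed=seed)


@pytest.fixture
def populated_store(tmp_path):
    """A store with one gel, three lanes and hand-set measurements.

    Reference lanes 0 and 1 carry (v=4, m=2) and (v=6, m=3), so the per-image
    reference value is r = 2; lane 2 has (v=4, m=1), hence w = 2.
    """
    from gelquant import open_store

    store = open_store(tmp_path / "store.db")
    gid = store.add_gel("G1")
    store.set_lane(gid, LaneRecord(0, "refA", 2.0, True))
    store.set_lane(gid, LaneRecord(1, "refB", 3.0, True))
    store.set_lane(gid, LaneRecord(2, "sample", 1.0, False))
    img_path = tmp_path / "img.tif"
    import tifffile

    tifffile.imwrite(img_path, np.zeros((4, 4), dtype=np.uint16))
    iid = store.add_image(gid, img_path)
    store.store_measurement(iid, "ab", 0, 0, 10, 4.0)
    store.store_measurement(iid, "ab", 1, 0, 10, 6.0)
    store.store_measurement(iid, "ab", 2, 0, 10, 4.0)
    yield store, gid, iid
    store.close()
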