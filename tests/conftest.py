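import numpy as np
import pytest

from broilervision import counting, scenes
from broilervision.zones import default_zone_geometry


@pytest.fixture(scope="session")
def geom():
    return default_zone_geometry(480, 360)


@pytest.fixture(scope="session")
def ref_area_d24():
    areas = scenes.sample_single_bird_areas(scenes.SceneConfig(day=24, seed=99), 100)
    return counting.estimate_reference_area(areas, 24)


@pytest.fixture(scope="session")
def trained_model(ref_area_d24):
    """BP counting model trained once on 1000 synthetic (area, count) pairs."""
    cfg = scenes.SceneConfig(day=24, seed=0)
    raw = scenes.generate_area_count_pairs(cfg, 1000)
    pairs = [(a / ref_area_d24.s, c) for a, c in raw]
    model, fit = counting.train_bp(pairs, seed=0)
    return model, fit


def region_from_pixels(xs, ys):
    """Build a Region directly from pixel coordinates (test helper)."""
    from broilervision.segmentation import Region

    xs = np.asarray(xs, dtype=np.int64)
    ys = np.asarray(ys, dtype=np.int64)
    return Region(
        region_id=0,
        xs=xs,
        ys=ys,
        area=len(xs),
        centroid=(float(xs.mean()), float(ys.mean())),
        bbox=(int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max())),
    )
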