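import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_convex_polygon(rng, n_points=12, scale=10.0, center=(0.0, 0.0)):
    """Convex hull of random points: a generic convex test polygon."""
    from scipy.spatial import ConvexHull

    pts = rng.normal(0.0, scale / 2.0, size=(n_points, 2)) + np.asarray(center)
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def raster_fraction(field, azimuth, bottom, top, step=0.01):
    """Occluded fraction of a vertical segment by dense point sampling.

    Independent oracle: walks the segment in `step`-degree increments and
    counts points covered by any scotoma polygon (shapely, boundary
    inclusive).
    """
    import shapely
    from shapely.ops import unary_union

    ys = np.arange(bottom, top + step / 2, step)
    if not field.polygons:
        return 0.0
    union = unary_union([p.to_shapely() for p in field.polygons])
    inside = shapely.intersects_xy(union, np.full(ys.shape, azimuth), ys)
    return float(inside.mean())
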