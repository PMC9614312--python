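import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import limbstitch as ls

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Desk-scale phantom used across the suite: proportions of a downsampled
# full-length study but small enough for exhaustive registration in tests.
SMALL = dict(canvas_height=420, canvas_width=160, bone_halfwidth=16.0)
SEARCH = ls.SearchWindow(dy_min=30, dy_max=126, dx_min=-12, dx_max=12)


def make_tiled_phantom(
    seed: int,
    vv: float = 0.0,
    ov12: int = 80,
    ov23: int = 60,
    dx12: int = 0,
    dx23: int = 0,
    tile_noise_sd: float = 0.0,
    **spec_kwargs,
):
    """One phantom study: full canvas, three tiles, ground truth."""
    kwargs = {**SMALL, **spec_kwargs}
    spec = ls.PhantomSpec.standard(varus_valgus_deg=vv, seed=seed, **kwargs)
    canvas, truth = ls.generate_phantom(spec)
    tiles, truth = ls.tile_phantom(canvas, truth, ov12, ov23, dx12, dx23)
    if tile_noise_sd > 0:
        tiles = tuple(
            ls.add_gaussian_noise(t, tile_noise_sd, seed * 10 + i)
            for i, t in enumerate(tiles)
        )
    return canvas, tiles, truth


def random_study(rng: np.random.Generator, seed: int, tile_noise_sd: float = 0.0):
    """Random study conditions: deviation in [-10, 10] deg, overlaps in
    [40, 120] rows, lateral shifts in [-10, 10] px."""
    vv = float(rng.uniform(-10, 10))
    ov12 = int(rng.integers(40, 121))
    ov23 = int(rng.integers(40, 121))
    dx12 = int(rng.integers(-10, 11))
    dx23 = int(rng.integers(-10, 11))
    canvas, tiles, truth = make_tiled_phantom(
        seed, vv=vv, ov12=ov12, ov23=ov23, dx12=dx12, dx23=dx23,
        tile_noise_sd=tile_noise_sd,
    )
    return canvas, tiles, truth


@pytest.fixture(scope="session")
def noiseless_study():
    """A fixed noiseless phantom study with nonzero shifts and deviation."""
    return make_tiled_phantom(seed=3, vv=6.0, ov12=80, ov23=60, dx12=4, dx23=-7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
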