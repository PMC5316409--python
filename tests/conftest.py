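import numpy as np
import pandas as pd
import pytest

from stressplate.layout import make_layout
from stressplate.synthetic import (
    DynamicClassSpec,
    PlateEffect,
    RenderParams,
    default_time_grid,
    generate_plate_images,
)


@pytest.fixture
def null_spec() -> DynamicClassSpec:
    return DynamicClassSpec("null", amplitude=1.0, noise_cv=0.0)


@pytest.fixture
def transient_spec() -> DynamicClassSpec:
    return DynamicClassSpec("transient_nuclear", 2.0, 8.0, 15.0, 3.0, 0.0)


@pytest.fixture
def small_layout() -> pd.DataFrame:
    return make_layout("P1", ["Nrf2"], ["CDDO"], n_replicates=2)


@pytest.fixture
def identity_effect() -> PlateEffect:
    return PlateEffect(1.0, 0.0, default_time_grid(24.0), 24.0)


@pytest.fixture
def disc_image() -> tuple[np.ndarray, np.ndarray]:
    """Ten well-separated blurred discs plus their planted centers."""
    from scipy import ndimage as ndi

    rng = np.random.default_rng(5)
    shape = (256, 256)
    centers = []
    while len(centers) < 10:
        r, c = rng.integers(20, 236, size=2)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= 40**2 for r0, c0 in centers):
            centers.append((int(r), int(c)))
    img = np.zeros(shape)
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    for r, c in centers:
        img[(rr - r) ** 2 + (cc - c) ** 2 <= 64] = 3000.0
    img = ndi.gaussian_filter(img, 1.5) + 100.0
    img += rng.normal(0, 5, shape)
    return img, np.array(centers)


@pytest.fixture
def rendered_well(small_layout, transient_spec, null_spec, identity_effect):
    """A small noiseless rendered plate (short grid for speed)."""
    effect = PlateEffect(1.0, 0.0, default_time_grid(24.0)[::4], 24.0)
    wells, truth = generate_plate_images(
        small_layout,
        {"CDDO": transient_spec, "DMSO": null_spec},
        effect,
        seed=3,
        render=RenderParams(n_cells=10),
        death_fraction=0.3,
    )
    return wells, truth
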