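import numpy as np
import pytest

from forestintegrity.grids import (
    GridSpec, RasterLayer, LayerStack, NODATA_BYTE, NODATA_FLOAT,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def spec30():
    """A small 30 m grid in a projected CRS."""
    return GridSpec(500_000.0, 8_000_000.0, 30.0, 8, 10, crs_id=32722)


@pytest.fixture
def random_stack(spec30, rng):
    """Aligned cover/height/loss layers with values spanning all classes."""
    cover = rng.uniform(0, 100, spec30.shape).astype(np.float32)
    height = rng.uniform(0, 35, spec30.shape).astype(np.float32)
    loss = rng.integers(0, 18, spec30.shape).astype(np.uint8)
    return LayerStack(
        cover=RasterLayer(spec30, cover, NODATA_FLOAT, "cover_pct"),
        height=RasterLayer(spec30, height, NODATA_FLOAT, "height_m"),
        loss=RasterLayer(spec30, loss, NODATA_BYTE, "loss_year_code"),
    )


def constant_stack(spec, cover, height, loss):
    return LayerStack(
        cover=RasterLayer(spec, np.full(spec.shape, cover, dtype=np.float32),
                          NODATA_FLOAT, "cover_pct"),
        height=RasterLayer(spec, np.full(spec.shape, height, dtype=np.float32),
                           NODATA_FLOAT, "height_m"),
        loss=RasterLayer(spec, np.full(spec.shape, loss, dtype=np.uint8),
                         NODATA_BYTE, "loss_year_code"),
    )
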