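import numpy as np
import pytest

from memratio import ImageMeta, SyntheticCellSpec


@pytest.fixture
def small_meta() -> ImageMeta:
    """160x160 frame: big enough for a 5-px rim cell, fast to render."""
    return ImageMeta(width=160, height=160)


@pytest.fixture
def noiseless_spec() -> SyntheticCellSpec:
    return SyntheticCellSpec(center=(80.0, 80.0), semi_axes=(36.0, 28.0),
                             noise_model="none")


@pytest.fixture
def poisson_spec() -> SyntheticCellSpec:
    return SyntheticCellSpec(center=(80.0, 80.0), semi_axes=(36.0, 28.0),
                             noise_model="poisson")


def compose_cells(images):
    """Merge single-cell images into one multi-cell frame (pixelwise max)."""
    out = images[0].pixels.copy()
    for img in images[1:]:
        np.maximum(out, img.pixels, out=out)
    from memratio import Image2D

    return Image2D(out, images[0].meta)
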