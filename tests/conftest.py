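import numpy as np
import pytest

from histolink.fixtures import SyntheticSlideSpec, make_slide
from histolink.registry import load_registry
from histolink.slides import SlideReader, SlideRef


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def slide_reader(tmp_path_factory):
    """A small synthetic slide with tissue blobs, shared across tests."""
    out = tmp_path_factory.mktemp("slides")
    return make_slide(
        SyntheticSlideSpec(seed=7, dimensions=(1024, 1024)), out, name="shared"
    )


def square_blob_reader(
    size: int = 2048,
    blob_origin: tuple[int, int] = (600, 700),
    blob_size: int = 512,
    mpp: float = 0.5,
    offset: tuple[int, int] = (0, 0),
) -> SlideReader:
    """In-memory slide with a single dark square blob at a known location."""
    image = np.full((size, size, 3), 240, dtype=np.uint8)
    bx, by = blob_origin
    image[by:by + blob_size, bx:bx + blob_size] = (150, 90, 130)
    ref = SlideRef(
        path="synthetic://square-blob",
        format="synthetic",
        mpp=mpp,
        dimensions=(size, size),
        bounds_offset=offset,
    )
    return SlideReader(ref, image)
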