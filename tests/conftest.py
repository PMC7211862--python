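import numpy as np
import pytest

from nmjmorph.binary_ops import BinaryMask


def disc_px(shape, center, radius):
    """Rasterized disc: pixel centres inside the closed analytic disc."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def mask_from_string(art, cal=1.0):
    """Build a BinaryMask from ASCII art ('#' = foreground)."""
    rows = [line for line in art.strip("\n").splitlines()]
    width = max(len(r) for r in rows)
    px = np.zeros((len(rows), width), dtype=bool)
    for i, row in enumerate(rows):
        for j, ch in enumerate(row):
            px[i, j] = ch == "#"
    return BinaryMask(px, cal)


def binary_mask(pixels, cal=1.0):
    return BinaryMask(np.asarray(pixels, dtype=bool), cal)


@pytest.fixture(scope="session")
def nominal_case():
    """One analysed nominal fixture shared across tests (expensive-ish)."""
    from nmjmorph import pipeline as pl
    from nmjmorph import synthetic as syn

    stack, truth = syn.generate_nmj(syn.nominal_spec(), seed=11)
    cfg = syn.fixture_config()
    rec = pl.analyze_image(stack, cfg, axon=truth.axon_input, image_id="nominal")
    return stack, truth, cfg, rec
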