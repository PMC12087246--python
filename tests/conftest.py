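import numpy as np
import pytest

from robustad.contact_io import ContactMap


@pytest.fixture
def random_map():
    """Factory for small symmetric random maps with optional missing bins."""

    def make(n=30, seed=0, missing=(), scale=1.0):
        rng = np.random.default_rng(seed)
        v = rng.random((n, n)) * scale
        v = (v + v.T) / 2
        for b in missing:
            v[b, :] = np.nan
            v[:, b] = np.nan
        return ContactMap(chrom="chrT", resolution=5000, values=v)

    return make


@pytest.fixture
def block_map():
    """Factory for maps with sharply enriched square blocks on the diagonal."""

    def make(n=80, blocks=((20, 50),), fold=4.0, seed=0, decay=1.0):
        rng = np.random.default_rng(seed)
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        base = (d + 1.0) ** (-decay)
        v = base * (0.8 + 0.4 * rng.random((n, n)))
        v = (v + v.T) / 2
        for a, b in blocks:
            v[a : b + 1, a : b + 1] *= fold
        return ContactMap(chrom="chrT", resolution=5000, values=v)

    return make
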