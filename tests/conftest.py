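import numpy as np
import pytest

from habscape.habitat import decay_factor
from habscape.params import default_sensitivity, default_threats
from habscape.raster import Raster

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def threats():
    return default_threats()


@pytest.fixture(scope="session")
def sens():
    return default_sensitivity()


@pytest.fixture
def make_landscape():
    """Factory for small random land-use rasters drawn from the known codes."""

    def _make(shape=(16, 16), cell_size=500.0, seed=0, codes=None):
        from habscape.landuse import CLASS_CODES

        rng = np.random.default_rng(seed)
        pool = list(codes) if codes is not None else sorted(CLASS_CODES.values())
        data = rng.choice(pool, size=shape).astype(np.int16)
        return Raster(data=data, cell_size=cell_size)

    return _make


def dense_degradation_oracle(lulc, threats, sens, normalize=True):
    """Independent degradation computation via a dense pairwise-distance matrix.

    Evaluates the decayed threat sums cell against cell with no convolution
    involved; used to cross-check the FFT path.
    """
    H, W = lulc.shape
    cs_km = lulc.cell_size / 1000.0
    rows, cols = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    pts = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    diff = pts[:, None, :] - pts[None, :, :]
    dist_km = np.sqrt((diff**2).sum(axis=2)) * cs_km
    codes = lulc.data.astype(int).ravel()
    total_w = sum(t.weight for t in threats)
    D = np.zeros(H * W)
    for spec in threats:
        kernel = decay_factor(dist_km, spec.d_rmax_km, spec.decay)
        presence = np.isin(codes, spec.source_codes).astype(float)
        num = kernel @ presence
        if normalize:
            den = kernel @ np.ones_like(presence)
            density = num / den
        else:
            density = num
        s = np.array([sens.sensitivity(int(c), spec.name) for c in codes])
        D += (spec.weight / total_w) * density * s
    return D.reshape(H, W)


def quadruple_loop_degradation(lulc, threats, sens):
    """Literal four-nested-loop evaluation of the degradation sum (tiny grids)."""
    H, W = lulc.shape
    cs_km = lulc.cell_size / 1000.0
    codes = lulc.data.astype(int)
    total_w = sum(t.weight for t in threats)
    D = np.zeros((H, W))
    for spec in threats:
        pres = np.isin(codes, spec.source_codes)
        for x in range(H):
            for y in range(W):
                num = 0.0
                den = 0.0
                for i in range(H):
                    for j in range(W):
                        d = np.hypot(x - i, y - j) * cs_km
                        if d > spec.d_rmax_km:
                            continue
                        f = decay_factor(d, spec.d_rmax_km, spec.decay)
                        den += f
                        if pres[i, j]:
                            num += f
                s = sens.sensitivity(int(codes[x, y]), spec.name)
                D[x, y] += (spec.weight / total_w) * (num / den) * s
    return D
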