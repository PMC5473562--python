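import numpy as np
import pytest

from contextcut4d import PhantomParams, generate_phantom, seeds_from_truth


SMALL_PHANTOM = dict(
    grid_shape=(16, 20, 20),
    spacing=(1.0, 1.0, 1.0),
    phase_count=3,
    tumor_semiaxes_mm=(3.0, 4.0, 4.0),
    tumor_center=(7.0, 10.0, 9.0),
    wall_x_start=16,
    motion_amplitude_mm=2.0,
    noise_sigma=0.02,
)


@pytest.fixture(scope="session")
def small_phantom():
    """A fast 3-phase phantom with wall and motion, for solver-level tests."""
    return generate_phantom(PhantomParams(rng_seed=7, **SMALL_PHANTOM))


@pytest.fixture(scope="session")
def small_seeds(small_phantom):
    return seeds_from_truth(small_phantom, n_object=40, n_background=300, rng_seed=7)


def random_mask(rng, shape=(10, 10, 10), p=0.2):
    """Random non-empty binary mask."""
    while True:
        m = rng.random(shape) < p
        if m.any():
            return m


def random_graphspec(rng, integer=False):
    """Random small multi-phase GraphSpec (random topology and weights)."""
    from contextcut4d.graph import GraphSpec

    shapes = [(2, 1, 1, 3), (2, 1, 2, 3), (3, 1, 1, 4), (3, 1, 2, 2), (2, 1, 2, 2)]
    k, Z, Y, X = shapes[rng.integers(len(shapes))]
    n = k * Z * Y * X
    idx = np.arange(n).reshape(k, Z, Y, X)

    def rand_w(size, scale):
        if integer:
            return rng.integers(0, 8, size).astype(float)
        return rng.random(size) * scale

    ns, nd = [], []
    for ax in (1, 2, 3):
        sa = [slice(None)] * 4
        sb = [slice(None)] * 4
        sa[ax] = slice(None, -1)
        sb[ax] = slice(1, None)
        ns.append(idx[tuple(sa)].ravel())
        nd.append(idx[tuple(sb)].ravel())
    ns, nd = np.concatenate(ns), np.concatenate(nd)
    keep = rng.random(len(ns)) < 0.75
    ns, nd = ns[keep], nd[keep]

    cs = np.concatenate([idx[i].ravel() for i in range(k - 1)])
    cd = np.concatenate([idx[i + 1].ravel() for i in range(k - 1)])
    keep = rng.random(len(cs)) < 0.75
    cs, cd = cs[keep], cd[keep]

    return GraphSpec((k, Z, Y, X), rand_w(n, 3.0), rand_w(n, 3.0),
                     ns, nd, rand_w(len(ns), 2.0),
                     cs, cd, rand_w(len(cs), 0.5))
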