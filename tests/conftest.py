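import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def separated_centers(rng, n, low, high, min_dist, max_tries=20000):
    """Rejection-sample n points in [low, high]^2 pairwise >= min_dist apart."""
    out = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place separated centers")
        c = rng.uniform(low, high, size=2)
        if all((c[0] - p[0]) ** 2 + (c[1] - p[1]) ** 2 >= min_dist**2 for p in out):
            out.append(c)
    return np.array(out)


@pytest.fixture
def spot_field(rng):
    """20 well-separated planted spots with mild noise (SNR ~ amplitude/noise)."""
    from palmpipe import simkit

    centers = separated_centers(rng, 20, 15.0, 240.0, 18.0)
    return simkit.SpotFieldTruth(
        shape=(256, 256),
        centers=centers,
        amplitudes=np.full(20, 50.0),
        widths=np.full(20, 1.5),
        background=5.0,
        noise_sd=1.0,
        seed=77,
    )
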