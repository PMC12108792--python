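import numpy as np
import pytest

import nucdamage as nd


@pytest.fixture(scope="session")
def duplex21():
    """21-bp ideal straight B-DNA duplex."""
    return nd.build_bdna("ACGTACGTACGTACGTACGTA")


@pytest.fixture(scope="session")
def nucleosome_wrap():
    """Synthetic 145-bp nucleosomal superhelix + its SHL map."""
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=145))
    wrap = nd.wrap_superhelix(nd.build_bdna(seq))
    smap = nd.shl_map(wrap, ("I", "J"))
    return wrap, smap


@pytest.fixture()
def ssb_duplex(duplex21):
    """SSB at the central nucleotide of the 21-bp duplex."""
    model, site = nd.make_ssb(duplex21.copy(), ("I", 11))
    return model, site


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def rigid_transform_model(model, rng):
    out = model.copy()
    Q = random_rotation(rng)
    t = rng.normal(scale=20.0, size=3)
    out.set_coords(model.coords() @ Q.T + t)
    return out
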