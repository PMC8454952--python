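import numpy as np
import pytest

import foldswitchlab as fsl


@pytest.fixture(scope="session")
def toy_pair():
    return fsl.make_toy_foldswitch_pair()


@pytest.fixture(scope="session")
def anchored_pair():
    return fsl.make_toy_foldswitch_pair(with_anchor=True)


@pytest.fixture(scope="session")
def qdiff_spec(toy_pair):
    return fsl.make_qdiff_spec(toy_pair.ref_a, toy_pair.ref_b)


@pytest.fixture(scope="session")
def coil(toy_pair):
    return fsl.sample_random_coil(toy_pair.sequence, seed=5,
                                  reference=toy_pair.ref_a)


@pytest.fixture(scope="session")
def helix18():
    return fsl.build_ideal_helix(18)


@pytest.fixture(scope="session")
def meander33():
    return fsl.build_beta_meander(33, 3)


def brute_force_distance_matrix(chain):
    ca = chain.ca_xyz
    n = len(ca)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sqrt(sum((ca[i, k] - ca[j, k]) ** 2
                                    for k in range(3)))
    return out
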