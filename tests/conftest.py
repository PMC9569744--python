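import numpy as np
import pytest

import virtual2de as v2


@pytest.fixture(scope="session")
def records():
    """Packaged plasma-protein fixtures keyed by accession."""
    return {r.accession: r for r in v2.load_plasma_fixtures()}


@pytest.fixture(scope="session")
def bjellqvist():
    return v2.load_pka_set("bjellqvist")


@pytest.fixture(scope="session")
def strip_axis():
    return v2.fit_pi_axis(((0.0, 3.0), (18.0, 11.0)))  # linear 3-11 over 18 cm


@pytest.fixture(scope="session")
def strip_scheme():
    return v2.strip36_scheme()


def random_peptides(n, rng=None, min_len=5, max_len=30):
    """Random canonical peptides guaranteed to contain an acid and a base."""
    rng = rng or np.random.default_rng(2024)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    out = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(aas, size=length))
        out.append(seq)
    return out
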