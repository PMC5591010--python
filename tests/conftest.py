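import numpy as np
import pytest

import isoppi as ip


@pytest.fixture(scope="session")
def egfr():
    return ip.case_study_fixture("EGFR")


@pytest.fixture(scope="session")
def casp9():
    return ip.case_study_fixture("CASP9")


@pytest.fixture(scope="session")
def egfr_isonet(egfr):
    dri = ip.annotate_edges_with_ddis(egfr.interactome, egfr.profiles, egfr.ddis)
    return dri, ip.build_isoform_interactome(dri, egfr.gmap, egfr.profiles)


@pytest.fixture(scope="session")
def casp9_isonet(casp9):
    dri = ip.annotate_edges_with_ddis(casp9.interactome, casp9.profiles, casp9.ddis)
    return dri, ip.build_isoform_interactome(dri, casp9.gmap, casp9.profiles)


def random_annotated_network(seed, n_proteins=15, n_edges=20, n_domains=10, n_ddis=8):
    """A random interactome with random (not planted) domains and DDIs, for
    comparing the annotation step against brute force."""
    rng = np.random.default_rng(seed)
    net = ip.generate_interactome(n_proteins, n_edges, seed)
    vocab = [f"D{j}" for j in range(n_domains)]
    profiles = ip.DomainProfileSet()
    for p in sorted(net.nodes):
        k = int(rng.integers(0, 4))
        profiles.set_profile(p, set(rng.choice(vocab, size=k, replace=False)) if k else set())
    ddis = ip.DDISet()
    for _ in range(n_ddis):
        d1, d2 = rng.choice(vocab, size=2)  # self-pairs possible
        ddis.add(str(d1), str(d2))
    return net, profiles, ddis
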