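import numpy as np
import pytest

from genofirst.functional_model import MissenseVariant, ProfileHMM
from genofirst.term_profiles import ProfileSite, TermProfile


def make_profile(dists, mafs=None, term_id="T"):
    """Term profile with given per-site functional distances."""
    mafs = mafs if mafs is not None else [0.1] * len(dists)
    sites = []
    for j, (d, m) in enumerate(zip(dists, mafs)):
        v = MissenseVariant(
            variant_id=f"v{j}", chrom="1", pos=(j + 1) * 10, ref="A", alt="G",
            protein_id="P0", residue_index=j + 1, ref_aa="A", alt_aa="V",
            maf=float(m),
        )
        sites.append(ProfileSite(v, "H0", j + 1, float(d)))
    return TermProfile(term_id, tuple(sites))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fixture_hmm(rng):
    """A small random profile HMM with pseudocounted emissions."""
    emis = rng.dirichlet(np.full(20, 0.5), size=12)
    return ProfileHMM.from_raw("HMMFIX", emis)


@pytest.fixture
def two_block_setup(rng):
    """40 genomes in two genotype blocks plus background noise sites.

    Returns (profile, genotypes, individuals, block_labels): the blocks are
    separated by two homozygous-opposite sites and carry i.i.d. noise at
    four low-distance sites.
    """
    profile = make_profile(
        [3.0, 3.0, 0.8, 0.7, 0.9, 0.6], [0.2, 0.2, 0.3, 0.3, 0.3, 0.3]
    )
    n = 40
    g = np.zeros((n, 6), dtype=np.int8)
    g[25:, :2] = 2
    for j in range(2, 6):
        g[:, j] = rng.choice(3, size=n, p=[0.49, 0.42, 0.09])
    labels = (np.arange(n) >= 25).astype(int)
    return profile, g, [f"i{i:02d}" for i in range(n)], labels
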