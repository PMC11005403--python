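import numpy as np
import pytest

from mfakit import GenomeDef, MFAProfile, SimParams
from mfakit.sim import expected_profile


@pytest.fixture
def tbar():
    """T. barophilus-like circular chromosome: 2.01 Mb, oriC at 1,671,000."""
    return GenomeDef(name="Tbar", length=2_010_000, ori_position=1_671_000)


@pytest.fixture
def small_genome():
    return GenomeDef(name="chr", length=20_000, ori_position=5_000)


def make_params(genome, f, r, n=2000, depth=10.0, bin_size=1000, seed=0):
    return SimParams(genome=genome, n_chromosomes=n, replicating_fraction=r,
                     ori_fraction=f, mean_depth_per_copy=depth,
                     bin_size=bin_size, seed=seed)


def noiseless_profile(genome, f, r, bin_size=1000):
    """Exact normalized MFA profile implied by the two-mode model."""
    params = make_params(genome, f, r, bin_size=bin_size)
    vals = expected_profile(params)
    return MFAProfile(genome=genome, bin_size=bin_size,
                      values=vals / vals.mean(), sigma=1.0)
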