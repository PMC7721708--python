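import numpy as np
import pytest

from bsrmap import SampleRoles, SimConfig, SnpRecord, simulate_f2_bulks

SAMPLES = ("8A", "R1", "SP", "RP")


def make_record(
    chrom="Chr01",
    pos=100,
    ref="A",
    alts=("G",),
    qual=200.0,
    depths=None,
):
    """Build a SnpRecord with per-sample {base: depth} maps.

    ``depths`` maps sample -> {base: depth}; unmentioned samples get 10 reads
    of the reference base, unmentioned bases 0.
    """
    depths = depths or {}
    depth_by_base = {}
    for s in SAMPLES:
        d = {b: 0 for b in "ACGT"}
        d.update(depths.get(s, {ref: 10}))
        depth_by_base[s] = d
    return SnpRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=tuple(alts),
        qual=qual,
        depth_by_base=depth_by_base,
    )


@pytest.fixture
def roles():
    return SampleRoles()


@pytest.fixture(scope="session")
def default_sim():
    """One seeded simulation at the default study design, shared read-only."""
    config = SimConfig(seed=11)
    records, truth = simulate_f2_bulks(config)
    return config, records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
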