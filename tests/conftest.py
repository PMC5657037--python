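import pytest

from snvensemble import GenomicSite, SimConfig, build_default_schema
from snvensemble.features import FeatureSchema


@pytest.fixture(scope="session")
def schema():
    return build_default_schema()


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down study design used where full size is not the point."""
    return SimConfig(seed=11, n_per_stratum=15, n_genome_only=15, n_germline=60, n_background=150)


def toy_schema(spec):
    """Build a tiny schema from {name: kind}; categorical gets KEEP/REJECT."""
    names = tuple(spec)
    kinds = dict(spec)
    categories = {n: ("KEEP", "REJECT") for n, k in spec.items() if k == "categorical"}
    return FeatureSchema(names, kinds, categories)


def site(pos, chrom="chr1", ref="A", alt="T"):
    return GenomicSite(chrom, pos, ref, alt)
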