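import pandas as pd
import pytest

from agingnet import (
    CountMatrix,
    NetSimConfig,
    SimConfig,
    write_fixture_bundle,
)

# the ten up-regulated immune genes reported to interact with the Ywhae hub
YWHAE_PARTNERS = [
    "Cybb", "Ifit1", "Ctss", "Ifitm3", "H2-Eb1",
    "Cd74", "C4b", "C3", "S100a8", "Zc3hav1",
]


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic fixture bundle: 1000 genes, 5% planted DE at
    fold 4, noise_cv 0.2, groups 8/6/3, planted hub with 10 partners."""
    directory = tmp_path_factory.mktemp("bundle")
    manifest = write_fixture_bundle(
        directory, SimConfig(seed=11), NetSimConfig(seed=11)
    )
    return directory, manifest


@pytest.fixture
def toy_counts() -> CountMatrix:
    counts = pd.DataFrame(
        {"s1": [10, 0, 5], "s2": [20, 1, 5]},
        index=["GeneA", "GeneB", "GeneC"],
    )
    return CountMatrix(
        counts=counts,
        gene_length_bp=pd.Series([2000, 1000, 500], index=counts.index),
        group_of={"s1": "young", "s2": "aged"},
    )
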