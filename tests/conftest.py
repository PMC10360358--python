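import numpy as np
import pandas as pd
import pytest

from cdkres.genome import default_genome
from cdkres.signatures import synthetic_reference_signatures


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture(scope="session")
def refs():
    return synthetic_reference_signatures()


@pytest.fixture(scope="session")
def refs4(refs):
    """A 4-signature reference panel for exhaustive-search comparisons."""
    return refs[["S1", "S3", "S13", "S20"]]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def variant_frame():
    """A small, well-formed variant table touching every consequence class."""
    rows = []
    consequences = [
        "missense", "missense", "missense", "synonymous", "synonymous", "intronic",
        "nonsense", "frameshift", "inframe_indel", "essential_splice_site", "stop_loss",
    ]
    for i, cons in enumerate(consequences):
        rows.append(
            {
                "sample": "A", "gene": f"GENE{i}", "chrom": "1", "pos": 1000 + i,
                "ref": "C", "alt": "T", "consequence": cons, "origin": "somatic",
                "clinvar": "",
            }
        )
    return pd.DataFrame(rows)
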