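import numpy as np
import pandas as pd
import pytest

from nomvote import CommunityProfile, OtuTable


@pytest.fixture
def small_table() -> OtuTable:
    """3 OTUs x 3 samples; s3 sits below a 5,000-read filter and is the
    only sample containing OTU_3."""
    return OtuTable(
        pd.DataFrame(
            {
                "s1": [4000, 1000, 0],
                "s2": [2500, 2500, 0],
                "s3": [4998, 0, 1],
            },
            index=["OTU_1", "OTU_2", "OTU_3"],
        )
    )


def profile_from(sample_id: str, shares: dict) -> CommunityProfile:
    """Profile over the union OTU namespace used in the occurrence tests."""
    otus = [f"OTU_{i}" for i in range(1, 11)]
    rel = pd.Series(0.0, index=otus)
    for k, v in shares.items():
        rel[k] = v
    return CommunityProfile.from_abundance(sample_id, rel)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
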