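import numpy as np
import pandas as pd
import pytest

from microagg.iotables import CountTable, SampleFrame, TaxonomyTable


@pytest.fixture
def tiny_counts():
    """3 samples x 4 ASVs with simple integers."""
    return CountTable(
        ("s1", "s2", "s3"), ("a1", "a2", "a3", "a4"),
        np.array([[8, 4, 3, 0],
                  [5, 0, 10, 5],
                  [1, 2, 0, 4]]),
    )


def make_sample_frame(rows):
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleFrame(df)


@pytest.fixture
def core_design():
    """One sampling point, two cores (4 aggregates + bulk each), one depth."""
    rows = []
    for c in ("c1", "c2"):
        x0 = 0.0 if c == "c1" else 0.05
        for i in range(4):
            rows.append(dict(sample_id=f"{c}-ag{i+1}", sample_type="aggregate",
                             depth_layer="top", plot_id="P1", point_id="P1a",
                             core_id=c, x=x0 + i * 1e-3, y=0.0))
        rows.append(dict(sample_id=f"{c}-bulk", sample_type="bulk",
                         depth_layer="top", plot_id="P1", point_id="P1a",
                         core_id=c, x=x0, y=0.0))
    return make_sample_frame(rows)


@pytest.fixture(scope="session")
def small_dataset():
    """Small full synthetic dataset shared by read-only tests."""
    from microagg.synthdata import CommunityParams, generate_dataset

    cp = CommunityParams(regional_richness=300)
    counts, env, om, latent = generate_dataset(community_params=cp, seed=7)
    return counts, env, om, latent


@pytest.fixture
def taxonomy_two_phyla():
    df = pd.DataFrame(
        {"phylum": ["PhyA", "PhyA", "PhyB", "PhyB"]},
        index=pd.Index(["a1", "a2", "a3", "a4"], name="asv_id"))
    return TaxonomyTable(df)
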