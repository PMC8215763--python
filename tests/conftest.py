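import numpy as np
import pandas as pd
import pytest

from rumennet import (
    ExpressionTable,
    GeneratorConfig,
    SampleDesign,
    simulate,
)


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def default_bundle(default_config):
    """Default synthetic bundle (3 cows x 5 timepoints + baseline)."""
    return simulate(default_config)


@pytest.fixture()
def toy_design() -> SampleDesign:
    rows = []
    for a in ("cow1", "cow2", "cow3"):
        for t in (1.0, 2.0, 4.0):
            rows.append({"sample_id": f"{a}_T{t:g}", "animal_id": a, "timepoint_h": t})
    return SampleDesign(table=pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture()
def toy_table(toy_design) -> ExpressionTable:
    """Two families x 3 genes, hand-sized counts."""
    genes = [f"g{i}" for i in range(1, 7)]
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(6, 9)),
        index=pd.Index(genes, name="gene_id"),
        columns=toy_design.sample_ids,
    )
    meta = pd.DataFrame(
        {
            "family": ["famA"] * 3 + ["famB"] * 3,
            "genus": ["gA"] * 3 + ["gB"] * 3,
            "functional_cluster": ["FC1", "FC2", "FC1", "FC1", "FC2", "FC2"],
            "enzyme_tag": ["GH5", "", "M24", "", "LuxS", "GH5"],
            "length_bp": [500, 1000, 1500, 600, 900, 1200],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return ExpressionTable(counts=counts, gene_meta=meta)
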