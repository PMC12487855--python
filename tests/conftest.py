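import numpy as np
import pandas as pd
import pytest

from screenstate import (
    CountTable,
    SgRNAElement,
    SgRNALibrary,
    synthetic_meta_modules,
)


@pytest.fixture
def toy_library() -> SgRNALibrary:
    """Two genes (3 and 2 elements) plus four non-targeting controls."""
    elements = (
        [SgRNAElement(f"GA_sg{i}", gene="GA") for i in (1, 2, 3)]
        + [SgRNAElement(f"GB_sg{i}", gene="GB") for i in (1, 2)]
        + [SgRNAElement(f"NTC_{i}", gene=None, is_ntc=True) for i in (1, 2, 3, 4)]
    )
    return SgRNALibrary(elements=elements, species="test")


@pytest.fixture
def toy_table(toy_library) -> CountTable:
    """Deterministic small counts with two replicates of each condition."""
    rng = np.random.default_rng(7)
    ids = toy_library.element_ids
    samples = ["T0_r1", "T0_r2", "vehicle_r1", "vehicle_r2", "drug_r1", "drug_r2"]
    counts = pd.DataFrame(
        rng.integers(50, 300, size=(len(ids), len(samples))),
        index=pd.Index(ids, name="element_id"),
        columns=samples,
    )
    meta = pd.DataFrame(
        {
            "condition": ["T0", "T0", "vehicle", "vehicle", "drug", "drug"],
            "replicate": ["r1", "r2", "r1", "r2", "r1", "r2"],
        },
        index=pd.Index(samples, name="sample"),
    )
    return CountTable(counts=counts, sample_meta=meta)


@pytest.fixture(scope="session")
def modules():
    return synthetic_meta_modules(genes_per_module=25)
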