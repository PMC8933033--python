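import numpy as np
import pandas as pd
import pytest

from cstkit import cst_core, synthetic
from cstkit.profiles_io import AbundanceTable, validate_metadata


@pytest.fixture
def tiny_table() -> AbundanceTable:
    return AbundanceTable(
        sample_ids=["s1", "s2", "s3"],
        taxon_ids=["Taxon a", "Taxon b"],
        values=np.array([[0.5, 0.5], [1.0, 0.0], [0.25, 0.25]]),
    )


@pytest.fixture
def tiny_meta() -> pd.DataFrame:
    return validate_metadata(
        pd.DataFrame(
            {
                "bioproject": ["P1", "P2", "P1"],
                "country": ["X", "Y", "X"],
                "sampling_method": ["nasal_lavage", "sputum", "biopsy"],
                "health_status": ["healthy", "diseased", "unknown"],
            },
            index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        )
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Default 13-CST synthetic dataset plus its clustering, shared by tests."""
    spec = synthetic.default_spec(seed=1)
    table, meta, ec, pw, truth = synthetic.generate_dataset(spec)
    dist = cst_core.pearson_distance(table)
    tree = cst_core.upgma_linkage(dist)
    assignment = cst_core.cut_dendrogram(tree, len(spec.cst_specs))
    catalog = cst_core.call_csts(table, meta, assignment)
    return {
        "spec": spec,
        "table": table,
        "meta": meta,
        "ec": ec,
        "pw": pw,
        "truth": truth,
        "dist": dist,
        "tree": tree,
        "assignment": assignment,
        "catalog": catalog,
    }


def random_abundance(rng: np.random.Generator, n: int, m: int) -> AbundanceTable:
    vals = rng.random((n, m))
    vals = vals / vals.sum(axis=1, keepdims=True) * rng.uniform(0.7, 1.0, size=(n, 1))
    return AbundanceTable(
        sample_ids=[f"s{i}" for i in range(n)],
        taxon_ids=[f"Taxon {j}" for j in range(m)],
        values=vals,
    )


def random_distance(rng: np.random.Generator, n: int) -> cst_core.DistanceMatrix:
    a = rng.random((n, n))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    return cst_core.DistanceMatrix(ids=[f"s{i}" for i in range(n)], values=d)
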