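import numpy as np
import pandas as pd
import pytest

from polyti import (
    AnalysisConfig,
    FractionCounts,
    GeneAnnotation,
    GeneratorParams,
    SampleManifest,
    simulate_dataset,
)


@pytest.fixture
def small_manifest():
    rows = []
    for strain in ("WT", "ul30bb"):
        for fraction in ("light", "heavy", "total"):
            for rep in (1, 2):
                rows.append(
                    (f"{strain}_untreated_{fraction}_{rep}", strain, "untreated",
                     fraction, rep)
                )
    return SampleManifest(
        pd.DataFrame(
            rows,
            columns=["sample_id", "strain", "condition", "fraction", "replicate"],
        )
    )


@pytest.fixture
def small_counts(small_manifest):
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(20)]
    mat = pd.DataFrame(
        rng.integers(1, 1000, size=(20, len(small_manifest.sample_ids))),
        index=pd.Index(genes, name="gene_id"),
        columns=small_manifest.sample_ids,
        dtype=np.int64,
    )
    return FractionCounts(mat, small_manifest)


@pytest.fixture
def small_annotation():
    rng = np.random.default_rng(11)
    genes = [f"g{i}" for i in range(20)]
    lengths = rng.integers(25, 2200, size=20) * 3
    bases = np.array(list("ACGT"))
    contexts = [
        "".join(bases[rng.integers(0, 4, 6)]) + "ATG" + "".join(bases[rng.integers(0, 4, 3)])
        for _ in genes
    ]
    return GeneAnnotation(
        pd.DataFrame(
            {
                "orf_length_nt": lengths,
                "start_context": contexts,
                "categories": [()] * 20,
            },
            index=pd.Index(genes, name="gene_id"),
        )
    )


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def default_simulation():
    """One moderately sized simulated dataset shared across tests."""
    params = GeneratorParams(n_genes=800, seed=42, conditions=("untreated",))
    return params, simulate_dataset(params)
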