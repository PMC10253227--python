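import numpy as np
import pandas as pd
import pytest

from svscreen import CountMatrix, SgRNALibrary, SimConfig, simulate_screen


def toy_library() -> SgRNALibrary:
    """Three genes with 5 / 4 / 3 guides."""
    guides, genes = [], []
    for gene, n in (("geneA", 5), ("geneB", 4), ("geneC", 3)):
        for i in range(1, n + 1):
            guides.append(f"{gene}_sg{i}")
            genes.append(gene)
    return SgRNALibrary(
        pd.DataFrame({"gene": genes}, index=pd.Index(guides, name="guide_id"))
    )


def toy_counts(library: SgRNALibrary) -> CountMatrix:
    """Worked filtering example: one geneA guide has a zero control count."""
    rng = np.random.default_rng(42)
    n = len(library)
    counts = pd.DataFrame(
        {
            "ctrl_1": rng.integers(50, 150, n),
            "ctrl_2": rng.integers(50, 150, n),
            "drugA_1": rng.integers(50, 150, n),
            "drugB_1": rng.integers(50, 150, n),
        },
        index=library.guides,
    ).astype(np.int64)
    counts.loc["geneA_sg3", "ctrl_2"] = 0
    samples = pd.DataFrame(
        {
            "condition": ["control", "control", "treated", "treated"],
            "dose": ["DMSO", "DMSO", "A", "B"],
            "timepoint": [1.0, 1.0, 1.0, 1.0],
            "replicate": [1, 2, 1, 1],
        },
        index=pd.Index(counts.columns, name="sample_id"),
    )
    return CountMatrix(counts, samples)


@pytest.fixture
def library():
    return toy_library()


@pytest.fixture
def counts(library):
    return toy_counts(library)


@pytest.fixture(scope="session")
def small_screen():
    """A fast simulated screen with signal, shared across tests."""
    cfg = SimConfig(
        n_genes=300,
        frac_essential=0.1,
        frac_synthetic_viable=0.05,
        sv_effect_treated=2.0,
        depth=300_000,
        timepoints=(0.5, 1.5),
        seed=7,
    )
    return simulate_screen(cfg)
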