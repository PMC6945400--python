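import numpy as np
import pandas as pd
import pytest

from dosage_de.synthetic_data import (
    CountMatrix,
    ExperimentDesign,
    Library,
    SAMPLE_DOSAGE,
    make_default_design,
    make_gene_params,
    make_spike_reference,
    simulate_counts,
)


def build_design(samples: list[str], depth: float = 5e5) -> ExperimentDesign:
    """Design with one library per entry of `samples` (repeats allowed)."""
    counts: dict[str, int] = {}
    libs = []
    for s in samples:
        counts[s] = counts.get(s, 0) + 1
        rep = counts[s]
        libs.append(
            Library(
                library_id=f"{s}_r{rep}",
                sample=s,
                dosage=SAMPLE_DOSAGE[s],
                replicate=rep,
                spike_mix="mix1" if rep % 2 == 1 else "mix2",
                depth=depth,
            )
        )
    return ExperimentDesign(libraries=tuple(libs))


def build_matrix(
    counts: np.ndarray,
    samples: list[str] | None = None,
    gene_ids: list[str] | None = None,
    n_spikes: int = 0,
) -> CountMatrix:
    """CountMatrix from a raw array; last `n_spikes` rows become spike rows."""
    counts = np.asarray(counts)
    n_genes, n_libs = counts.shape
    if samples is None:
        samples = ["Het"] * (n_libs // 2) + ["CorrWT"] * (n_libs - n_libs // 2)
    design = build_design(samples)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes - n_spikes)] + [
            f"spike{i}" for i in range(n_spikes)
        ]
    df = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"), columns=design.library_ids
    )
    is_spike = pd.Series(
        [False] * (n_genes - n_spikes) + [True] * n_spikes, index=df.index
    )
    return CountMatrix(counts=df, is_spike=is_spike, design=design)


@pytest.fixture(scope="session")
def default_design():
    return make_default_design(seed=1, depth_mean=5e5, depth_cv=0.1)


@pytest.fixture(scope="session")
def spike_reference():
    return make_spike_reference(seed=1)


@pytest.fixture(scope="session")
def small_simulation(default_design, spike_reference):
    """600-gene seeded simulation with planted effects, shared across tests."""
    genes = make_gene_params(
        n_genes=600, n_linear_up=10, n_linear_down=10, n_nonlinear=10, seed=2
    )
    matrix, truth = simulate_counts(
        default_design, genes, spike_reference, seed=3
    )
    return matrix, truth, genes
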