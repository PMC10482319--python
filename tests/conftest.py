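import numpy as np
import pandas as pd
import pytest

from growthcub.expr_prep import ExpressionMatrix
from growthcub.seq_cub import CodonWeightTable


def make_matrix(values: np.ndarray, growth, condition_ids=None, **meta_kwargs) -> ExpressionMatrix:
    """Small ExpressionMatrix builder for tests."""
    n_genes, n_cols = values.shape
    exp_ids = [f"e{i + 1}" for i in range(n_cols)]
    meta = pd.DataFrame(
        {
            "condition_id": condition_ids or exp_ids,
            "growth_rate": growth,
            "alignment_score": meta_kwargs.get("alignment_score", [100.0] * n_cols),
            "is_ale": meta_kwargs.get("is_ale", [False] * n_cols),
            "is_mutant_or_ko": meta_kwargs.get("is_mutant_or_ko", [False] * n_cols),
        },
        index=pd.Index(exp_ids, name="experiment_id"),
    )
    genes = [f"g{i + 1}" for i in range(n_genes)]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=exp_ids), meta, "log_tpm")


@pytest.fixture
def flat_weights() -> CodonWeightTable:
    """All sense codons at weight 1.0 (every score is exactly 1)."""
    from growthcub._codon_tables import SENSE_CODONS

    return CodonWeightTable("flat", {c: 1.0 for c in SENSE_CODONS})


@pytest.fixture
def example_table() -> CodonWeightTable:
    return CodonWeightTable.example()


@pytest.fixture(scope="session")
def default_dataset():
    """One generator-default dataset (3,000 genes x 50 conditions, seed 11)
    shared by the heavier recovery tests."""
    from growthcub import simulate

    conditions, _ = simulate.gen_conditions(seed=11)
    matrix, truth = simulate.gen_expression(conditions=conditions, seed=11)
    records = simulate.gen_sequences(truth)
    annotations = simulate.gen_annotations(truth)
    return matrix, truth, records, annotations
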