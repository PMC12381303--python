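from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pdotme.core import ExpressionMatrix, normalize_log1p

DATA_DIR = Path(__file__).resolve().parents[1] / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


def make_expr(counts: np.ndarray, chromosomes=None, starts=None, **cell_cols) -> ExpressionMatrix:
    """Small helper: dense counts -> ExpressionMatrix with simple annotation."""
    n_genes, n_cells = counts.shape
    gene_table = pd.DataFrame(
        {
            "gene_id": [f"G{i:04d}" for i in range(n_genes)],
            "symbol": [f"G{i:04d}" for i in range(n_genes)],
        }
    )
    if chromosomes is not None:
        gene_table["chromosome"] = chromosomes
        gene_table["start_bp"] = starts if starts is not None else np.arange(1, n_genes + 1) * 100
    cell_table = pd.DataFrame({"cell_id": [f"C{i:04d}" for i in range(n_cells)], **cell_cols})
    return ExpressionMatrix(sp.csr_matrix(counts), gene_table, cell_table)


@pytest.fixture()
def small_expr() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    counts = rng.poisson(2.0, size=(50, 30))
    counts[0] += 1  # guard against zero-count cells at this size
    expr = make_expr(counts, chromosomes=["chr1"] * 25 + ["chr2"] * 25)
    return normalize_log1p(expr)
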