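import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from mmlce.simulate import ScSimSpec, simulate_single_cell
from mmlce.types import CountMatrix, GeneAnnotation


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated sample shared by read-only tests."""
    spec = ScSimSpec(
        seed=101,
        n_cells={"LCE_MM": 300, "IGH_MM": 150, "T": 150, "B": 80, "NK": 80,
                 "monocyte": 100, "RBC": 50, "megakaryocyte": 30, "progenitor": 60},
    )
    cm, ann, truth = simulate_single_cell(spec)
    return cm, ann, truth


@pytest.fixture()
def tiny_counts():
    """Hand-built 4-gene x 3-cell matrix."""
    counts = sp.csr_matrix(np.array([
        [2, 0, 1],
        [0, 0, 4],
        [0, 5, 0],
        [1, 1, 1],
    ]))
    return CountMatrix(
        counts=counts,
        gene_ids=np.array(["g1", "g2", "g3", "MT-ND1"], dtype=object),
        barcodes=np.array(["c1", "c2", "c3"], dtype=object),
        cell_sample=np.array(["s", "s", "s"], dtype=object))


@pytest.fixture()
def tiny_annotation():
    return GeneAnnotation(table=pd.DataFrame({
        "gene_id": ["g1", "g2", "g3", "MT-ND1"],
        "chromosome": ["1", "1", "2", "MT"],
        "start_bp": [100, 200, 50, 1],
        "is_mitochondrial": [False, False, False, True],
    }))
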