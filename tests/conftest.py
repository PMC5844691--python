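import numpy as np
import pandas as pd
import pytest

from tcellsig.expression import ExpressionStudy
from tcellsig.methylome import MethylationStudy
from tcellsig.synthetic_data import StudySpec, make_study


def small_design(subsets=("A", "B"), n_donors=3):
    rows = [
        {"sample_id": f"{s}_D{d+1}", "subset": s, "donor": f"D{d+1}"}
        for s in subsets
        for d in range(n_donors)
    ]
    return pd.DataFrame(rows)


def toy_expression(values, subsets=("A", "B"), n_donors=None, genes=None):
    """Wrap a plain array into an ExpressionStudy with a paired design."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    if n_donors is None:
        n_donors = n_samples // len(subsets)
    design = small_design(subsets, n_donors)
    probes = [f"p{i}" for i in range(n_probes)]
    if genes is None:
        genes = [f"G{i}" for i in range(n_probes)]
    frame = pd.DataFrame(
        values, index=probes, columns=design["sample_id"].tolist()
    )
    return ExpressionStudy(
        values=frame,
        probe_to_gene=pd.Series(genes, index=probes),
        design=design,
    )


@pytest.fixture(scope="session")
def planted_study():
    """Default-condition synthetic study with planted signatures."""
    spec = StudySpec(
        n_probes_expr=800,
        n_probes_meth=2000,
        n_signature_genes=30,
        seed=11,
    )
    return make_study(spec)


@pytest.fixture(scope="session")
def null_study():
    """Same design, nothing planted."""
    spec = StudySpec(
        n_probes_expr=200,
        n_probes_meth=1500,
        n_signature_genes=5,
        expr_effect=0.0,
        meth_effect=0.0,
        seed=5,
    )
    return make_study(spec)
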