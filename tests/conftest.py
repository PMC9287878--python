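import numpy as np
import pandas as pd
import pytest

from metaexpr.expression_io import ExpressionCohort


def make_cohort(case, ctrl, genes=None, cohort_id="C1"):
    """Cohort from per-gene case/control value arrays (genes x samples)."""
    case = np.atleast_2d(np.asarray(case, dtype=float))
    ctrl = np.atleast_2d(np.asarray(ctrl, dtype=float))
    n1, n0 = case.shape[1], ctrl.shape[1]
    if genes is None:
        genes = [f"G{i}" for i in range(case.shape[0])]
    samples = [f"{cohort_id}_S{j}" for j in range(n1 + n0)]
    values = pd.DataFrame(
        np.hstack([case, ctrl]), index=pd.Index(genes, name="gene"), columns=samples
    )
    groups = pd.Series(["case"] * n1 + ["control"] * n0, index=samples)
    return ExpressionCohort(cohort_id=cohort_id, values=values, groups=groups)


@pytest.fixture
def tiny_cohort_files(tmp_path):
    """Minimal valid 2-gene x 6-sample TSV pair on disk."""
    matrix = tmp_path / "matrix.tsv"
    meta = tmp_path / "meta.tsv"
    matrix.write_text(
        "gene\tS1\tS2\tS3\tS4\tS5\tS6\n"
        "GA\t5.0\t6.0\t7.0\t1.0\t2.0\t3.0\n"
        "GB\t2.0\t2.5\t3.0\t2.1\t2.4\t2.9\n"
    )
    meta.write_text(
        "sample_id\tcohort_id\tgroup\n"
        + "".join(f"S{j}\tC1\t{'case' if j <= 3 else 'control'}\n" for j in range(1, 7))
    )
    return matrix, meta


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
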