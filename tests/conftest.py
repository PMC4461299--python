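import numpy as np
import pandas as pd
import pytest

from degbench.datatypes import ExpressionSet, GroundTruth
from degbench.simulate import generate, preset


@pytest.fixture(scope="session")
def dataset1():
    """One realized fully-separated benchmark dataset (2000 genes, 73 shifted)."""
    return generate(preset("dataset1", seed=7))


@pytest.fixture(scope="session")
def dataset2():
    """The subtler-shift variant (means 13.5 / 6.5)."""
    return generate(preset("dataset2", seed=7))


def make_expression(ctrl: np.ndarray, treat: np.ndarray) -> ExpressionSet:
    """Small two-group ExpressionSet from raw (genes, samples) arrays."""
    ctrl, treat = np.atleast_2d(ctrl), np.atleast_2d(treat)
    g = ctrl.shape[0]
    genes = [f"g{i:03d}" for i in range(g)]
    samples = [f"c{j}" for j in range(ctrl.shape[1])] + [
        f"t{j}" for j in range(treat.shape[1])
    ]
    values = pd.DataFrame(np.hstack([ctrl, treat]), index=pd.Index(genes, name="gene_id"),
                          columns=samples)
    groups = pd.Series(["control"] * ctrl.shape[1] + ["treatment"] * treat.shape[1],
                       index=samples)
    return ExpressionSet(values, groups, control="control")


def make_truth(expr: ExpressionSet, up=(), down=()) -> GroundTruth:
    labels = pd.Series("none", index=expr.gene_ids, name="label")
    labels.iloc[list(up)] = "up"
    labels.iloc[list(down)] = "down"
    return GroundTruth(labels)
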