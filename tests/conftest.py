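import numpy as np
import pandas as pd
import pytest

from nrf2modnet.io import EXPERIMENT_COLUMNS, FoldChangeMatrix
from nrf2modnet.network import GeneModule, ModuleSet
from nrf2modnet.synthetic import SyntheticDesign, planted_fold_change_matrix


def make_fcm(values: np.ndarray, genes=None, compounds=None) -> FoldChangeMatrix:
    """Wrap a raw experiments x genes array in a FoldChangeMatrix.

    Experiments are assigned one per compound unless ``compounds`` is given.
    """
    n_exp, n_genes = values.shape
    genes = genes or [f"G{i:04d}" for i in range(n_genes)]
    compounds = compounds or [f"CPD{i:03d}" for i in range(n_exp)]
    index = pd.MultiIndex.from_tuples(
        [(c, "high", 24) for c in compounds], names=EXPERIMENT_COLUMNS
    )
    return FoldChangeMatrix(pd.DataFrame(values, index=index, columns=genes))


def moduleset_from_truth(assignment: pd.Series) -> ModuleSet:
    """Build a ModuleSet straight from a ground-truth gene assignment."""
    mods = [
        GeneModule(module_id=mid, genes=list(assignment.index[assignment == mid]))
        for mid in sorted(assignment[assignment != ""].unique())
    ]
    return ModuleSet(modules=mods, unassigned=list(assignment.index[assignment == ""]))


@pytest.fixture(scope="session")
def small_design():
    return SyntheticDesign(
        seed=1,
        n_genes=300,
        n_compounds=20,
        module_sizes=[20, 15, 10, 8, 6],
        n_signal_modules=2,
    )


@pytest.fixture(scope="session")
def small_panel(small_design):
    """(fcm, vehicle_intensity, truth) for a 300-gene planted panel."""
    return planted_fold_change_matrix(small_design)


@pytest.fixture(scope="session")
def default_panel():
    """The default-scale stated world (2,000 genes, 540 experiments), seed 1."""
    return planted_fold_change_matrix(SyntheticDesign(seed=1))
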