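import numpy as np
import pytest

from noctule import enm, generate_landscape
from noctule.grids import RasterGrid


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic landscape shared by read-only tests."""
    return generate_landscape(
        seed=7, extent=(-10.0, 35.0, 10.0, 45.0), resolution=0.5, n_occurrences=80
    )


@pytest.fixture(scope="session")
def fitted_model(small_bundle):
    """A quick boosted-tree fit on the small landscape (read-only)."""
    b = small_bundle
    occ = b.occurrences
    pa = enm.sample_disk_pseudoabsences(occ, b.current_stack[0], n=200, seed=7)
    table = enm.build_training_table(occ, pa, b.current_stack, b.predictor_names)
    grid = enm.TuningGrid(
        shrinkage=(0.1,),
        interaction_depth=(3,),
        min_obs_in_node=(10,),
        bag_fraction=(0.8,),
        n_trees_max=120,
        cv_folds=3,
    )
    return enm.tune_and_fit(table, grid, seed=7)


@pytest.fixture()
def uniform_grid():
    def make(nrows, ncols, value=1.0, res=1.0):
        return RasterGrid(np.full((nrows, ncols), float(value)), 0.0, 0.0, res)

    return make
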