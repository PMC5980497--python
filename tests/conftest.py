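import numpy as np
import pytest

import nicheval as nv
from nicheval.geodata import BinaryMap, assign_cells
from nicheval.synthdata import FIXED_BINARY_THRESHOLD


@pytest.fixture(scope="session")
def scenario():
    """A default synthetic virtual-species scenario (seed 1)."""
    return nv.generate_scenario(1)


@pytest.fixture(scope="session")
def space_and_observed(scenario):
    """PCA background space and the observed-niche MVE for the scenario."""
    space = nv.build_pca(scenario.stack)
    assignment = assign_cells(
        scenario.all_occurrences(), space.geometry, scenario.stack.nodata_mask
    )
    observed = nv.observed_niche(space.scores_for_cells(assignment.unique_usable_cells()))
    return space, observed


def fixed_binary(raster, threshold=FIXED_BINARY_THRESHOLD):
    """Binarize a pseudo-model at the scenario's fixed absolute cut."""
    return BinaryMap(
        geometry=raster.geometry,
        suitable=np.where(np.isfinite(raster.values), raster.values >= threshold, False),
        nodata_mask=raster.nodata_mask,
        threshold_value=threshold,
        omission_tolerance=0.0,
    )


@pytest.fixture(scope="session")
def small_grid():
    return nv.GridGeometry(n_rows=10, n_cols=10, cell_size=0.5, origin_lon=-75.0, origin_lat=-45.0)
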