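import numpy as np
import pandas as pd
import pytest

from wgctraj.core_io import CohortTable, SurfaceMesh
from wgctraj.pipeline import run_replicate
from wgctraj.synthetic_data import make_mesh


def planar_grid_mesh(n: int = 41, spacing: float = 2.0) -> SurfaceMesh:
    """Regular triangulated grid in the z=0 plane (grid-like test surface)."""
    xs, ys = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    coords = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            tris += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
    return SurfaceMesh(vertex_coords=coords, triangles=np.asarray(tris))


@pytest.fixture(scope="session")
def grid_mesh() -> SurfaceMesh:
    return planar_grid_mesh()


@pytest.fixture(scope="session")
def sphere_mesh() -> SurfaceMesh:
    return make_mesh(300, seed=7)


@pytest.fixture(scope="session")
def small_study():
    """One full synthetic study replicate at desk scale, shared across tests."""
    return run_replicate(seed=11, n_vertices=300, n_perm=50, n_boot=100)


def toy_cohort(rows) -> CohortTable:
    """Cohort from (subject_id, dx, site, age) tuples, single timepoint."""
    return CohortTable(
        pd.DataFrame(
            [
                {
                    "subject_id": sid,
                    "dx": dx,
                    "site": site,
                    "scanner": "Siemens",
                    "sex": "M",
                    "timepoint": "single",
                    "age": age,
                }
                for sid, dx, site, age in rows
            ]
        )
    )
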