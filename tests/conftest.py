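import numpy as np
import pytest

from nozzleflow import DriveCondition, Material, NozzleGeometry, builtin_material
from nozzleflow import fvm, pipe


@pytest.fixture(scope="session")
def alginate() -> Material:
    return builtin_material("Alginate")


@pytest.fixture(scope="session")
def base_blunted() -> NozzleGeometry:
    """Catalogue-typical blunted nozzle (mm: Rs 0.2, Rb 3.5, Ll 6, Lu 4)."""
    return NozzleGeometry.from_mm("blunted", 0.2, 3.5, 6.0, 4.0)


@pytest.fixture(scope="session")
def base_conical() -> NozzleGeometry:
    return NozzleGeometry.from_mm("conical", 0.227, 3.5, 6.0, 4.0, r_middle=1.0)


@pytest.fixture(scope="session")
def tube_geom():
    """A straight tube expressed as a degenerate blunted nozzle."""
    R, L = 0.25e-3, 2e-3
    return NozzleGeometry.blunted(r_small=R, r_big=R * 1.0000001,
                                  l_lower=L, l_upper=1e-9)


@pytest.fixture(scope="session")
def tube_spec(tube_geom) -> pipe.PipeSpec:
    return pipe.PipeSpec(tube_geom.r_small, tube_geom.l_lower)


@pytest.fixture(scope="session")
def tube_mesh(tube_geom) -> fvm.Mesh2D:
    R, L = tube_geom.r_small, tube_geom.l_lower
    return fvm.build_mesh(
        tube_geom,
        options=fvm.MeshOptions(uniform=True, dr_fine=R / 50, dz_fine=L / 100),
    )


@pytest.fixture(scope="session")
def small_blunted_field(alginate):
    """A quick converged 2D solution of a scaled-down blunted nozzle."""
    geom = NozzleGeometry.from_mm("blunted", 0.1, 1.0, 2.0, 1.0)
    mesh = fvm.build_mesh(geom, dr=1e-5, dz=2e-5)
    field = fvm.solve_fvm(mesh, alginate, DriveCondition.pressure(100e3))
    return geom, mesh, field


@pytest.fixture(scope="session")
def campaign_blunted(alginate):
    """200-design blunted Alginate campaign with the quasi-1D solver."""
    from nozzleflow import doe

    designs = doe.lhs_design(200, seed=7, shape="blunted")
    resp = doe.run_campaign(designs, alginate)
    return designs, resp


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
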