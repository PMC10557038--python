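import numpy as np
import pytest

from headmc.phantom import PhantomSpec, build_phantom, reference_spec
from headmc.meshing import volume_to_mesh


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(head_semiaxes_mm=(30.0, 34.0, 26.0))


@pytest.fixture(scope="session")
def small_volume(small_spec):
    return build_phantom(small_spec, voxel_mm=1.0)


@pytest.fixture(scope="session")
def small_mesh(small_volume):
    return volume_to_mesh(small_volume, target_elem_size_mm=2.0)


@pytest.fixture(scope="session")
def reference_volume():
    return build_phantom(reference_spec(), voxel_mm=1.0)


@pytest.fixture(scope="session")
def reference_mesh(reference_volume):
    return volume_to_mesh(reference_volume, target_elem_size_mm=2.0)


@pytest.fixture(scope="session")
def reference_surface(reference_mesh):
    from headmc.surface import distribute_surface_locations

    return distribute_surface_locations(reference_mesh)


@pytest.fixture(scope="session")
def forehead_poi(reference_surface):
    from headmc.surface import forehead_index

    return reference_surface.points[forehead_index(reference_surface.points)]


@pytest.fixture(scope="session")
def icosphere():
    import trimesh

    sph = trimesh.creation.icosphere(subdivisions=4)

    class Surf:
        nodes = np.asarray(sph.vertices, dtype=float)
        scalp_faces = np.asarray(sph.faces, dtype=np.int32)

    return Surf()


# the homogeneous semi-infinite study condition shared by the MC-vs-analytic
# and parameter-recovery checks: mua 0.01/mm, musp' 1.0/mm, n 1.37,
# lambda 785 nm, alpha_Db 1e-6 mm^2/s, rho 15 mm, 1e6 photons
HOMOG = dict(mua=0.01, musp=1.0, n=1.37, wavelength_nm=785.0,
             alpha_Db=1e-6, rho_mm=15.0, n_photons=1_000_000, seed=1)


@pytest.fixture(scope="session")
def homogeneous_history():
    from headmc.forward_mc import (DetectorRing, LayeredMedium,
                                   simulate_histories)

    medium = LayeredMedium.homogeneous(mua=HOMOG["mua"], musp=HOMOG["musp"],
                                       n=HOMOG["n"])
    return simulate_histories(medium, [DetectorRing(HOMOG["rho_mm"], 1.0)],
                              HOMOG["n_photons"], seed=HOMOG["seed"])


@pytest.fixture(scope="session")
def homogeneous_optics():
    from headmc.optics import TissueOptics

    return TissueOptics(mua=[HOMOG["mua"]] * 5, mus=[HOMOG["musp"]] * 5,
                        g=[0.0] * 5, n=[HOMOG["n"]] * 5,
                        alpha_Db=[HOMOG["alpha_Db"]] * 5)
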