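"""Shared fixtures: the default phantom (computed once per session) and a
small optically realistic toy system for dense-oracle comparisons."""

import numpy as np
import pytest

from ccodot.forward_model import (Geometry, Grid, OptodeArray, coarsen_grid,
                                  load_tissue_optics, project_jacobian,
                                  project_to_grid)
from ccodot.multispectral_inversion import assemble
from ccodot.spectra import extinction_matrix
from ccodot.synthetic_data import (ActivationBlob, NoiseModel,
                                   compute_jacobians, default_phantom,
                                   default_wavelengths, simulate_experiment)

CHROM3 = ["HbO2", "HHb", "oxCCO"]
CHROM2 = ["HbO2", "HHb"]


@pytest.fixture(scope="session")
def phantom():
    return default_phantom()


@pytest.fixture(scope="session")
def wavelengths():
    return default_wavelengths()


@pytest.fixture(scope="session")
def jacobians(phantom, wavelengths):
    geometry, props, array = phantom
    return compute_jacobians(geometry, props, array, wavelengths)


@pytest.fixture(scope="session")
def recon_grid(jacobians):
    return coarsen_grid(jacobians[0].grid, 3.0)


@pytest.fixture(scope="session")
def recon_jacobians(jacobians, recon_grid):
    return [project_jacobian(j, recon_grid) for j in jacobians]


@pytest.fixture(scope="session")
def system3(recon_jacobians, wavelengths):
    return assemble(recon_jacobians, extinction_matrix(CHROM3, wavelengths),
                    CHROM3)


@pytest.fixture(scope="session")
def system2(recon_jacobians, wavelengths):
    return assemble(recon_jacobians, extinction_matrix(CHROM2, wavelengths),
                    CHROM2)


@pytest.fixture(scope="session")
def blob():
    return ActivationBlob()


@pytest.fixture(scope="session")
def noiseless_sim(phantom, wavelengths, jacobians, blob):
    geometry, props, array = phantom
    return simulate_experiment(geometry, props, array, blob,
                               wavelengths=wavelengths,
                               noise=NoiseModel(sd_od=0.0),
                               jacobians=jacobians)


@pytest.fixture(scope="session")
def truth_on_recon(phantom, blob, jacobians, recon_grid):
    """Ground-truth chromophore images projected onto the recon grid."""
    geometry, _, _ = phantom
    timg = blob.truth_image(geometry)
    fine = jacobians[0].grid
    return np.stack([
        project_to_grid(timg.data[i], fine, recon_grid) for i in range(3)
    ])


# ---------------------------------------------------------------------------
# toy system: 5 wavelengths, 8 channels, 100 voxels — small enough for dense
# oracles but built from the real diffusion solver and spectra

@pytest.fixture(scope="session")
def toy():
    grid = Grid((5, 5, 4), 4.0)
    geometry = Geometry(grid, np.full(grid.shape, 1, dtype=int), {1: "brain"})
    props = load_tissue_optics()
    src = np.array([[6.0, 10.0, 0.0], [14.0, 10.0, 0.0]])
    det = np.array([[4.0, 4.0, 0.0], [16.0, 4.0, 0.0],
                    [4.0, 16.0, 0.0], [16.0, 16.0, 0.0]])
    channels = [(s, d) for s in range(2) for d in range(4)]
    array = OptodeArray(src, det, channels, source_sigma=2.0)
    wl = np.array([740.0, 780.0, 820.0, 860.0, 900.0])
    jacs = compute_jacobians(geometry, props, array, wl)
    return {"geometry": geometry, "props": props, "array": array,
            "wavelengths": wl, "jacobians": jacs}


@pytest.fixture(scope="session")
def toy_system3(toy):
    return assemble(toy["jacobians"],
                    extinction_matrix(CHROM3, toy["wavelengths"]), CHROM3)


@pytest.fixture(scope="session")
def toy_system2(toy):
    return assemble(toy["jacobians"],
                    extinction_matrix(CHROM2, toy["wavelengths"]), CHROM2)
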