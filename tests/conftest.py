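import numpy as np
import pytest

import persicell as pc


def graph_from_dense(density, connectivity=6, mask=None, spacing=(1.0, 1.0, 1.0)):
    """Build a VoxelGraph from a dense 3D density array (helper)."""
    density = np.asarray(density, dtype=float)
    if mask is None:
        mask = np.ones(density.shape, bool)
    return pc.build_voxel_graph(pc.BinaryVolume(mask, spacing), density, connectivity)


@pytest.fixture
def line_graph():
    """The five-voxel 1D ridge with densities [0, 2, 1, 3, 0]."""
    return graph_from_dense(np.array([[[0.0, 2.0, 1.0, 3.0, 0.0]]]))


@pytest.fixture(scope="session")
def touching_scene_clean():
    """Two physically touching cells, no blur, no noise."""
    params = pc.SynthParams(
        seed=3, n_cells=2, touching_pair_fraction=1.0, gaussian_sd=0.0, psf_sigma_um=0.0
    )
    return pc.generate_scene(params)


@pytest.fixture(scope="session")
def default_scene():
    """A four-cell scene with one touching pair at default blur/noise."""
    params = pc.SynthParams(seed=11, n_cells=4, touching_pair_fraction=0.5)
    return pc.generate_scene(params)


@pytest.fixture(scope="session")
def default_scene_segmented(default_scene):
    return pc.segment_stack(
        default_scene.stack,
        pc.PBCParams(delta=30.0),
        nuclei_labels=default_scene.gt_nuclei,
    )
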