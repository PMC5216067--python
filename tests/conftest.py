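import numpy as np
import pytest

from pcsassign.simulate import (
    SimulationConfig,
    make_bundle,
    simulate_datasets,
    write_bundle_pdb,
)
from pcsassign.structure import extract_methyls, load_structure
from pcsassign.tensor import ChiTensor


@pytest.fixture(scope="session")
def bundle_structure(tmp_path_factory):
    """Small idealized four-helix bundle parsed back from PDB."""
    cfg = SimulationConfig(seed=0)
    atoms, _ = make_bundle(cfg)
    path = tmp_path_factory.mktemp("bundle") / "bundle.pdb"
    write_bundle_pdb(atoms, path)
    return load_structure(path)


@pytest.fixture(scope="session")
def bundle_methyls(bundle_structure):
    return extract_methyls(bundle_structure)


@pytest.fixture()
def dy_tensor():
    """A Dy-scale tensor with a non-trivial orientation."""
    rng = np.random.default_rng(7)
    from scipy.spatial.transform import Rotation

    axes = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return ChiTensor(-26.9, -5.4, np.array([10.6, 58.5, 10.4]), axes, "Dy", "A:166")


@pytest.fixture(scope="session")
def sim_run():
    """One full simulated experiment set (structure, datasets, ground truth)."""
    cfg = SimulationConfig(seed=11)
    atoms, _ = make_bundle(cfg)
    import tempfile, os

    fd, path = tempfile.mkstemp(suffix=".pdb")
    os.close(fd)
    write_bundle_pdb(atoms, path)
    structure = load_structure(path)
    os.unlink(path)
    return simulate_datasets(structure, cfg)


def true_methyl_of(run, subunit, master_peak):
    """Ground-truth methyl id for a master peak, via its base shifts."""
    for (sub, mid), (h, c) in run.base_shifts.items():
        if sub == subunit and abs(h - master_peak.h_ppm) < 1e-9 and abs(c - master_peak.c_ppm) < 1e-9:
            return mid
    return None
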