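import numpy as np
import pytest

from tcrmech import synthetic
from tcrmech.trajio import StructureModel, Trajectory


@pytest.fixture(scope="session")
def template():
    return synthetic.make_domain_template(n_contact_pairs=10)


@pytest.fixture
def static_trajectory(template):
    """A 100-frame trajectory with no motion and no noise."""
    cfg = synthetic.SyntheticConfig(seed=0, n_frames=100, noise_sigma=0.0)
    traj, truth = synthetic.generate_trajectory(cfg, template)
    return traj, truth


def toy_structure(coords, names=None, elements=None, chain="A",
                  charges=None, donor=None, acceptor=None):
    """Minimal structure: one residue per atom, for geometric toys."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    s = StructureModel(
        names=np.array(names if names is not None else ["CA"] * n),
        elements=np.array(elements if elements is not None else ["C"] * n),
        chain_ids=np.array([chain] * n),
        res_index=np.arange(1, n + 1),
        res_names=np.array(["GLY"] * n),
        orig_res_num=np.arange(1, n + 1),
        coords=coords,
        charges=None if charges is None else np.asarray(charges, float),
    )
    if donor is not None:
        s.is_donor = np.asarray(donor, bool)
    if acceptor is not None:
        s.is_acceptor = np.asarray(acceptor, bool)
    return s


def toy_trajectory(frames, structure, dt_save=0.02):
    return Trajectory(np.asarray(frames, dtype=float), dt_save, structure)
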