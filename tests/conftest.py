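import numpy as np
import pytest

from hopscotch.cluster import kmedoids
from hopscotch.structures import ETRegion, pairwise_rmsd
from hopscotch.synthetic import EnsembleSpec, gen_ensemble

FULL_ENSEMBLE_SEED = 7
N_LOCAL = 2000  # snapshots in the clustered local-sampling window
N_LATE = 3  # nonlocal snapshots appended after the window


def region_of(traj) -> ETRegion:
    """ET-region selector covering every residue of a trajectory."""
    residues = tuple(sorted({
        (c, int(r)) for c, r in zip(traj.chain_ids, traj.res_ids)
    }))
    return ETRegion(residues=residues)


@pytest.fixture(scope="session")
def full_ensemble():
    """Study-scale ensemble: 2000 clusterable snapshots + 3 late ones."""
    spec = EnsembleSpec(n_snapshots=N_LOCAL + N_LATE, seed=FULL_ENSEMBLE_SEED)
    return gen_ensemble(spec)


@pytest.fixture(scope="session")
def full_rmsd(full_ensemble):
    """Pairwise ET-region RMSD over the 2000-snapshot local window."""
    traj = full_ensemble
    window = type(traj)(
        chain_ids=traj.chain_ids, res_ids=traj.res_ids,
        res_names=traj.res_names, atom_names=traj.atom_names,
        elements=traj.elements, coords=traj.coords[:N_LOCAL],
        cluster_labels=traj.cluster_labels[:N_LOCAL],
    )
    return window, pairwise_rmsd(window, region_of(window))


@pytest.fixture(scope="session")
def full_clustering(full_rmsd):
    window, dm = full_rmsd
    return window, dm, kmedoids(dm, 10)
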