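import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crossbeta import builder as B

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def strand():
    return B.build_strand("FYFCFYF")


@pytest.fixture(scope="session")
def st10_sh4():
    return B.build_assembly(B.spec_st10_sh4())


@pytest.fixture(scope="session")
def st10_sh4_ss():
    return B.build_assembly(B.spec_st10_sh4(disulfide=True))


@pytest.fixture(scope="session")
def st50_sh2():
    return B.build_assembly(B.spec_st50_sh2())


def toy_assembly(xyz, names=None, elements=None, sheets=None, strands=None,
                 resids=None, resnames=None):
    """Minimal hand-made Assembly for oracle tests."""
    xyz = np.asarray(xyz, float)
    n = len(xyz)
    return B.Assembly(
        names=np.array(names or ["CA"] * n, dtype=object),
        elements=np.array(elements or ["C"] * n, dtype=object),
        resids=np.array(resids if resids is not None else np.arange(1, n + 1)),
        resnames=np.array(resnames or ["ALA"] * n, dtype=object),
        strand_index=np.array(strands if strands is not None else np.zeros(n, int)),
        sheet_index=np.array(sheets if sheets is not None else np.zeros(n, int)),
        xyz=xyz,
    )


def min_nonbonded_distance(asm):
    """Minimum distance between atoms not in the same or adjacent residues."""
    from scipy.spatial import cKDTree
    tree = cKDTree(asm.xyz)
    pairs = tree.query_pairs(4.0, output_type="ndarray")
    key = ((asm.sheet_index.astype(np.int64) << 40)
           | (asm.strand_index.astype(np.int64) << 20) | asm.resids)
    same = key[pairs[:, 0]] == key[pairs[:, 1]]
    sk = (asm.sheet_index.astype(np.int64) << 20) | asm.strand_index
    consec = ((sk[pairs[:, 0]] == sk[pairs[:, 1]])
              & (np.abs(asm.resids[pairs[:, 0]] - asm.resids[pairs[:, 1]]) == 1))
    keep = ~(same | consec)
    d = np.linalg.norm(asm.xyz[pairs[keep, 0]] - asm.xyz[pairs[keep, 1]], axis=1)
    return float(d.min())


def random_rigid_transform(rng):
    """A uniformly random proper rotation and a translation."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    t = rng.normal(scale=20.0, size=3)
    return R.as_matrix(), t
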