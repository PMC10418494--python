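import numpy as np
import pytest

from abaffinity.structure import partition_complex
from abaffinity.synthetic import ToyComplexSpec, make_toy_complex


@pytest.fixture
def contact_pair_factory():
    """Two single-residue chains whose minimum heavy-atom distance is exact."""

    def factory(distance, res_a="A", res_b="A"):
        spec = ToyComplexSpec(
            residues_a=[res_a], residues_b=[res_b],
            contacts=[(0, 0, distance)], cutoff=max(6.0, distance),
        )
        structure, _ = make_toy_complex(spec)
        return structure

    return factory


@pytest.fixture
def six_residue_complex():
    """Two chains x three residues with one known cross contact."""
    spec = ToyComplexSpec(
        residues_a=["E", "S", "L"], residues_b=["K", "T", "V"],
        contacts=[(0, 0, 5.0)],
    )
    structure, truth = make_toy_complex(spec)
    return structure, truth


@pytest.fixture
def random_rigid_motion():
    def factory(seed):
        rng = np.random.default_rng(seed)
        # rotation via QR of a random matrix, sign-fixed to det +1
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.uniform(-50, 50, size=3)
        return q, t

    return factory


def partition_ab(structure):
    return partition_complex(structure, ["A"], ["B"])
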