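import numpy as np
import pytest
from hypothesis import settings

from hetbench.core import GERMLINE, PhylogenyTruth, Subclone

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_truth(purity=0.8, structure=None, snvs_per_clone=2):
    """Small truth tree helper.

    ``structure``: list of (id, parent, cp) tuples; defaults to a 3-clone
    branching tree (clonal with two subclonal children).
    """
    if structure is None:
        structure = [(1, GERMLINE, purity), (2, 1, 0.4), (3, 1, 0.3)]
    assignment = {}
    snv = 1
    counts = {}
    for cid, _, _ in structure:
        for _ in range(snvs_per_clone):
            assignment[snv] = cid
            snv += 1
        counts[cid] = snvs_per_clone
    subclones = [Subclone(cid, parent, cp, counts[cid]) for cid, parent, cp in structure]
    return PhylogenyTruth(purity=purity, subclones=subclones, assignment=assignment)


@pytest.fixture
def branching_truth():
    """3-clone branching tree, 2 SNVs per clone."""
    return make_truth()


@pytest.fixture
def chain_truth():
    """Linear chain clone1 -> clone2, one SNV each."""
    return make_truth(
        structure=[(1, GERMLINE, 0.8), (2, 1, 0.4)], snvs_per_clone=1
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
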