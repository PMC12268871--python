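"""Shared builders for small test systems."""

import numpy as np
import pytest

from regcg.cgmodel import CGTopology, NonbondedParams, PairEntry
from regcg.fixtures import FixtureSpec, make_dimer_reference


def two_bead_system(
    charge=(1.0, -1.0),
    A=41.84,
    R_rep=0.7,
    C=-5.0,
    R_att=1.0,
    trainable=True,
    spring=None,
    same_monomer=False,
):
    """A two-bead toy: one type pair, optionally bonded instead."""
    topo = CGTopology(
        monomer_id=np.array([0, 0 if same_monomer else 1]),
        bead_type=["X", "Y"],
        charge=np.array(charge, dtype=float),
        mass=np.array([350.0, 350.0]),
    )
    if spring is not None:
        k, r0 = spring
        topo = topo.with_springs([0], [1], [k], [r0])
    params = NonbondedParams(
        pairs={
            ("X", "Y"): PairEntry(A=A, R_rep=R_rep, C=C, R_att=R_att, trainable=trainable)
        }
    )
    return topo, params


def place(R):
    """Two beads separated by R along x."""
    return np.array([[0.0, 0.0, 0.0], [R, 0.0, 0.0]])


@pytest.fixture(scope="session")
def dimer():
    """Small bound-dimer reference shared across tests (read-only)."""
    return make_dimer_reference(FixtureSpec(kind="dimer", n_frames=400, seed=7))
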