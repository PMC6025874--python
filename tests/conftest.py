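"""Shared fixtures: synthetic nucleosome fixture and small helpers."""

import numpy as np
import pytest

from nucstress import SuperhelixSpec, build_superhelix
from nucstress.structures import Atom, Structure
from nucstress.constants import ATOMIC_MASSES


@pytest.fixture(scope="session")
def superhelix():
    """Default 187-bp superhelical duplex with pseudo-histone core."""
    return build_superhelix(SuperhelixSpec())


@pytest.fixture(scope="session")
def superhelix_structure(superhelix):
    return superhelix[0]


def make_duplex_from_centerline(points, radius=0.9, u_dirs=None):
    """Minimal two-chain duplex with P atoms straddling given centerline points.

    The per-pair P midpoint is exactly the centerline point, so the recomputed
    neutral axis can be compared against analytic curves.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if u_dirs is None:
        u_dirs = np.tile([1.0, 0.0, 0.0], (n, 1))
    atoms = []
    serial = 0
    for chain, sign in (("I", 1.0), ("J", -1.0)):
        for k in range(n):
            resid = k + 1 if chain == "I" else n - k
            serial += 1
            atoms.append(Atom(serial, "P", "P", "DA", resid, chain,
                              ATOMIC_MASSES["P"],
                              points[k] + sign * radius * u_dirs[k]))
    return Structure(atoms, title="test duplex")
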