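"""Shared fixtures: generated toy networks with prepared bases and graphs."""

from __future__ import annotations

import numpy as np
import pytest

import redflux as rf


class Prepared:
    """A fixture network with its basis, polytope, EMU graph and samples."""

    def __init__(self, manifest, n_samples=10, seed=1234):
        self.manifest = manifest
        self.model = manifest.model
        self.catalogue = manifest.catalogue
        self.S, self.balanced = rf.build_stoichiometry(self.model)
        self.basis = rf.free_flux_basis(self.S, self.model)
        self.polytope = rf.build_polytope(self.basis, self.model)
        self.graph = rf.emu_decompose(self.model)
        self.samples = rf.hit_and_run(self.polytope, n_samples, seed=seed)

    def states(self, k=None):
        Z = self.samples.Z if k is None else self.samples.Z[:k]
        return [self.basis.flux_state(z) for z in Z]

    def random_mixtures(self, n, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            fractions = {}
            for sub, species in self.catalogue.items():
                x = rng.dirichlet(np.ones(len(species)))
                x = x / x.sum()
                fractions[sub] = tuple(x)
            out.append(rf.Mixture.from_dict(fractions).validate())
        return out


@pytest.fixture(scope="session")
def chain():
    return Prepared(rf.fixtures.make_chain())


@pytest.fixture(scope="session")
def branch():
    return Prepared(rf.fixtures.make_branch_cycle())


@pytest.fixture(scope="session")
def analog():
    return Prepared(rf.fixtures.make_clavam_analog())


@pytest.fixture(scope="session")
def all_networks(chain, branch, analog):
    return [chain, branch, analog]
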