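"""Stoichiometric system, free-flux selection, and polytope construction."""

import numpy as np
import pytest

import redflux as rf
from redflux.model import (
    ErrorModel,
    LinearConstraint,
    MeasurementGroup,
    MeasurementSpec,
    Metabolite,
    NetworkModel,
    Normalization,
    Reaction,
)
from redflux.stoichiometry import DegeneratePolytopeError, InfeasibleError


def _simple_model(mets, reactions, net_constraints=(), normalization=None,
                  net_bounds=(-100.0, 100.0)):
    return NetworkModel(
        metabolites=tuple(mets),
        reactions=tuple(reactions),
        net_constraints=tuple(net_constraints),
        xch_constraints=(),
        net_bounds=net_bounds,
        xch_bounds=(0.0, 200.0),
        measurement=MeasurementSpec(
            groups=(), error_model=ErrorModel(), rates=()
        ),
        normalization=normalization or Normalization(reactions[0].id, 100.0, False),
    ).validate()


def _rxn(rid, educt, product, carbons=1, bidirectional=False):
    atoms = "a" * 0 + "".join(chr(ord("a") + i) for i in range(carbons))
    return Reaction(rid, ((educt, atoms),), ((product, atoms),),
                    bidirectional=bidirectional)


@pytest.fixture(scope="module")
def diamond():
    """A -> {B, C} -> D with an upstream uptake pinned to 100."""
    mets = [
        Metabolite("X", 1, "input"), Metabolite("A", 1), Metabolite("B", 1),
        Metabolite("C", 1), Metabolite("D", 1, "output"),
    ]
    reactions = [
        _rxn("upt", "X", "A"), _rxn("r1", "A", "B"), _rxn("r2", "A", "C"),
        _rxn("r3", "B", "D"), _rxn("r4", "C", "D"),
    ]
    return _simple_model(
        mets, reactions, normalization=Normalization("upt", 100.0, True),
        net_bounds=(0.0, 100.0),
    )


class TestBuildStoichiometry:
    def test_two_step_chain_single_balance(self):
        mets = [Metabolite("A", 1, "input"), Metabolite("B", 1),
                Metabolite("C", 1, "output")]
        model = _simple_model(mets, [_rxn("r1", "A", "B"), _rxn("r2", "B", "C")])
        S, balanced = rf.build_stoichiometry(model)
        assert balanced == ["B"]
        assert S.tolist() == [[1.0, -1.0]]

    def test_diamond_rank(self, diamond):
        S, balanced = rf.build_stoichiometry(diamond)
        assert balanced == ["A", "B", "C"]
        assert np.linalg.matrix_rank(S) == 3

    def test_no_balanced_metabolites(self):
        mets = [Metabolite("A", 1, "input"), Metabolite("B", 1, "output")]
        model = _simple_model(mets, [_rxn("r1", "A", "B")])
        S, balanced = rf.build_stoichiometry(model)
        assert S.shape == (0, 1)
        basis = rf.free_flux_basis(S, model)
        assert basis.free_net_ids == ("r1",)


class TestFreeFluxBasis:
    def test_counts_match_rank_deficit(self, all_networks):
        for prep in all_networks:
            n = len(prep.model.reactions)
            n_eq = np.linalg.matrix_rank(prep.S) + (
                1 if prep.model.normalization.fixed else 0
            )
            assert len(prep.basis.free_net_ids) == n - n_eq
            assert len(prep.basis.free_xch_ids) == len(
                prep.model.bidirectional_reactions
            )

    def test_chain_has_one_free_net_flux(self, chain):
        assert len(chain.basis.free_net_ids) == 1
        assert chain.basis.free_xch_ids == ()

    def test_bidirectional_step_adds_exchange_coordinate(self, branch):
        assert branch.basis.free_xch_ids == ("cond",)

    def test_diamond_free_fluxes(self, diamond):
        S, _ = rf.build_stoichiometry(diamond)
        basis = rf.free_flux_basis(S, diamond)
        # 5 reactions, rank 3, uptake pinned -> 1 free net flux
        assert len(basis.free_net_ids) == 1

    def test_affine_map_satisfies_balances(self, all_networks):
        rng = np.random.default_rng(0)
        for prep in all_networks:
            k = len(prep.basis.free_net_ids)
            for _ in range(20):
                z = rng.normal(scale=50.0, size=k)
                v = prep.basis.net_fluxes(z)
                assert np.abs(prep.S @ v).max() < 1e-9

    def test_inconsistent_fixed_rates_raise(self):
        mets = [Metabolite("A", 1, "input"), Metabolite("B", 1),
                Metabolite("C", 1, "output")]
        model = _simple_model(
            mets, [_rxn("r1", "A", "B"), _rxn("r2", "B", "C")],
            net_constraints=[LinearConstraint((("r2", 1.0),), "eq", 50.0)],
            normalization=Normalization("r1", 100.0, True),
        )
        S, _ = rf.build_stoichiometry(model)
        with pytest.raises(InfeasibleError):
            rf.free_flux_basis(S, model)


class TestPolytope:
    def test_chain_interval(self, chain):
        box = chain.polytope.bounding_box()
        assert box.shape == (1, 2)
        assert box[0] == pytest.approx([1.0, 100.0])

    def test_contradictory_bounds_infeasible(self):
        mets = [Metabolite("A", 1, "input"), Metabolite("B", 1, "output")]
        model = _simple_model(
            mets, [_rxn("r1", "A", "B")],
            net_constraints=[
                LinearConstraint((("r1", 1.0),), "ge", 10.0),
                LinearConstraint((("r1", 1.0),), "le", 5.0),
            ],
        )
        S, _ = rf.build_stoichiometry(model)
        basis = rf.free_flux_basis(S, model)
        with pytest.raises((InfeasibleError, DegeneratePolytopeError)):
            rf.build_polytope(basis, model)

    def test_diamond_interval_endpoints(self, diamond):
        """After elimination the diamond reduces to a 1-D interval [0, 100].

        Oracle: brute-force vertex enumeration on the 2-D (r1, r2) pre-image
        with r1 + r2 = 100 and box bounds.
        """
        S, _ = rf.build_stoichiometry(diamond)
        basis = rf.free_flux_basis(S, diamond)
        poly = rf.build_polytope(basis, diamond)
        assert poly.dim == 1
        box = poly.bounding_box()
        # vertices of {r1, r2 >= 0, r1 <= 100, r2 <= 100, r1 + r2 = 100}
        vertices = [(0.0, 100.0), (100.0, 0.0)]
        free = basis.free_net_ids[0]
        j = {"r1": 0, "r2": 1}.get(free)
        if j is not None:
            expected = sorted(v[j] for v in vertices)
            assert box[0] == pytest.approx(expected)
        assert box[0][1] - box[0][0] == pytest.approx(100.0)

    def test_membership_matches_original_constraints(self, branch):
        """Polytope membership agrees with evaluating every raw constraint."""
        model, basis, poly = branch.model, branch.basis, branch.polytope
        rng = np.random.default_rng(5)
        box = poly.bounding_box()
        span = box[:, 1] - box[:, 0]
        bidir = {r.id for r in model.bidirectional_reactions}
        n_net = len(basis.free_net_ids)
        for _ in range(300):
            z = box[:, 0] - 0.25 * span + rng.random(poly.dim) * 1.5 * span
            state = basis.flux_state(z)
            ok = True
            lo, hi = model.net_bounds
            for j, rid in enumerate(basis.reaction_ids):
                lo_j = lo if rid in bidir else max(lo, 0.0)
                if not (lo_j - 1e-9 <= state.net[j] <= hi + 1e-9):
                    ok = False
            for con in model.net_constraints:
                c = con.as_le()
                if con.relation == "eq":
                    continue
                total = sum(coeff * state.net_of(f) for f, coeff in c.coeffs)
                if total > c.rhs + 1e-9:
                    ok = False
            for k, rid in enumerate(basis.free_xch_ids):
                x = z[n_net + k]
                if not (-1e-9 <= x <= model.xch_bounds[1] + 1e-9):
                    ok = False
            assert poly.contains(z) == ok

    def test_random_points_satisfy_steady_state(self, all_networks):
        for prep in all_networks:
            samples = rf.hit_and_run(prep.polytope, 1000, seed=42)
            k = len(prep.basis.free_net_ids)
            V = prep.basis.v0[:, None] + prep.basis.K @ samples.Z[:, :k].T
            assert np.abs(prep.S @ V).max() < 1e-9
            for z in samples.Z:
                assert prep.polytope.contains(z)

    def test_csv_export(self, chain, tmp_path):
        path = tmp_path / "poly.csv"
        chain.polytope.to_csv(path)
        header = path.read_text().splitlines()[0].split(",")
        assert header == list(chain.polytope.labels) + ["b"]
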