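"""Labeling simulation: EMU decomposition, cascade, cumomer oracle, error model."""

import dataclasses

import numpy as np
import pytest

import redflux as rf
from redflux.labeling import UnreachableFragmentError
from redflux.model import (
    ErrorModel,
    MeasurementGroup,
    MeasurementSpec,
    Metabolite,
    NetworkModel,
    Normalization,
    RateMeasurement,
    Reaction,
)


def _condensation_model():
    """C(2) = A(1) + B(1): the minimal convolution case."""
    mets = (
        Metabolite("A", 1, "input"), Metabolite("B", 1, "input"),
        Metabolite("C", 2), Metabolite("P", 2, "output"),
    )
    reactions = (
        Reaction("cond", (("A", "a"), ("B", "b")), (("C", "ab"),)),
        Reaction("out", (("C", "ab"),), (("P", "ab"),)),
    )
    return NetworkModel(
        metabolites=mets, reactions=reactions,
        net_constraints=(), xch_constraints=(),
        net_bounds=(0.0, 100.0), xch_bounds=(0.0, 200.0),
        measurement=MeasurementSpec(
            groups=(MeasurementGroup("ms_C", "C", (0, 1), (0, 1, 2)),),
            error_model=ErrorModel(),
            rates=(RateMeasurement("cond", 100.0, 5.0),),
        ),
        normalization=Normalization("cond", 100.0, False),
    ).validate()


def _state(model, values):
    S, _ = rf.build_stoichiometry(model)
    basis = rf.free_flux_basis(S, model)
    return basis.flux_state(np.asarray(values, dtype=float))


class TestEmuDecompose:
    def test_chain_has_no_convolutions(self, chain):
        graph = chain.graph
        assert graph.sizes == [2]
        for terms in graph.terms.values():
            for _, srcs in terms:
                assert len(srcs) == 1

    def test_condensation_introduces_convolution(self):
        model = _condensation_model()
        graph = rf.emu_decompose(model)
        node = ("C", frozenset({0, 1}))
        (term,) = graph.terms[node]
        _, srcs = term
        assert srcs == (("A", frozenset({0})), ("B", frozenset({0})))

    def test_unreachable_fragment_flagged(self):
        model = _condensation_model()
        # measure a pool that nothing produces
        mets = model.metabolites + (Metabolite("Z", 1),)
        bad = dataclasses.replace(
            model,
            metabolites=mets,
            reactions=model.reactions + (
                Reaction("zout", (("Z", "a"),), (("Q", "a"),)),
            ),
        )
        bad = dataclasses.replace(
            bad,
            metabolites=mets + (Metabolite("Q", 1, "output"),),
            measurement=MeasurementSpec(
                groups=bad.measurement.groups
                + (MeasurementGroup("ms_Z", "Z", (0,), (0, 1)),),
                error_model=ErrorModel(),
                rates=bad.measurement.rates,
            ),
        ).validate()
        with pytest.raises(UnreachableFragmentError):
            rf.emu_decompose(bad)


class TestSimulateLabeling:
    def test_unlabeled_substrates_give_m0(self, branch):
        mix = rf.Mixture.from_dict(branch.manifest.facts["singular_mixture"])
        y = rf.simulate_labeling(
            branch.model, branch.graph, branch.states(1)[0], mix, branch.catalogue
        )
        for gid in ("ms_P", "ms_R", "ms_Q"):
            mid = y.group_values(gid)
            assert mid[0] == pytest.approx(1.0, abs=1e-12)
            assert np.abs(mid[1:]).max() < 1e-12

    def test_passthrough_fully_labeled(self, chain):
        mix = rf.Mixture.from_dict({"S": (1.0, 0.0, 0.0)})
        y = rf.simulate_labeling(
            chain.model, chain.graph, chain.states(1)[0], mix, chain.catalogue
        )
        mid = y.group_values("ms_P")
        assert mid[-1] == pytest.approx(1.0, abs=1e-12)

    def test_passthrough_fifty_fifty(self, chain):
        mix = rf.Mixture.from_dict({"S": (0.5, 0.0, 0.5)})
        y = rf.simulate_labeling(
            chain.model, chain.graph, chain.states(1)[0], mix, chain.catalogue
        )
        mid = y.group_values("ms_P")
        assert mid[0] == pytest.approx(0.5, abs=1e-12)
        assert mid[-1] == pytest.approx(0.5, abs=1e-12)
        assert np.abs(mid[1:-1]).max() < 1e-12

    def test_condensation_convolves_inputs(self):
        model = _condensation_model()
        graph = rf.emu_decompose(model)
        catalogue = {
            "A": [rf.TracerSpecies("A", "U", (1,), 100.0, 1.0),
                  rf.TracerSpecies("A", "12C", (0,), 100.0, 1.0)],
            "B": [rf.TracerSpecies("B", "U", (1,), 100.0, 1.0),
                  rf.TracerSpecies("B", "12C", (0,), 100.0, 1.0)],
        }
        mix = rf.Mixture.from_dict({"A": (0.5, 0.5), "B": (1.0, 0.0)})
        y = rf.simulate_labeling(model, graph, _state(model, [50.0]), mix, catalogue)
        # conv((0.5, 0.5), (0, 1)) = (0, 0.5, 0.5)
        assert y.group_values("ms_C") == pytest.approx([0.0, 0.5, 0.5], abs=1e-12)

    def test_mid_normalization_property(self, branch):
        for state in branch.states(5):
            for mix in branch.random_mixtures(3, seed=17):
                y = rf.simulate_labeling(
                    branch.model, branch.graph, state, mix, branch.catalogue
                )
                for grp in branch.model.measurement.groups:
                    assert y.group_values(grp.id).sum() == pytest.approx(
                        1.0, abs=1e-9
                    )

    def test_flux_scale_invariance(self, branch):
        """Multiplying all fluxes by lambda > 0 leaves the labeling unchanged."""
        model = dataclasses.replace(
            branch.model,
            normalization=dataclasses.replace(
                branch.model.normalization, fixed=False
            ),
            net_constraints=(),
        ).validate()
        S, _ = rf.build_stoichiometry(model)
        basis = rf.free_flux_basis(S, model)
        graph = rf.emu_decompose(model)
        mix = branch.random_mixtures(1, seed=23)[0]
        # re-express a feasible sample of the pinned model in the unpinned
        # basis: free coordinates are named reaction fluxes, so copy them over
        feasible = branch.states(1)[0]
        rid_index = {r: j for j, r in enumerate(basis.reaction_ids)}
        z = np.concatenate([
            [feasible.net[rid_index[f]] for f in basis.free_net_ids],
            [feasible.xch_of(f) for f in basis.free_xch_ids],
        ])
        st = basis.flux_state(z)
        assert np.abs(st.net - feasible.net).max() < 1e-9
        y1 = rf.simulate_labeling(model, graph, st, mix, branch.catalogue)
        for lam in (0.5, 3.0):
            y2 = rf.simulate_labeling(
                model, graph, basis.flux_state(lam * z), mix, branch.catalogue
            )
            assert np.abs(y1.values - y2.values).max() < 1e-12

    def test_affine_in_single_substrate_mixture(self, chain):
        """y is affine in one substrate's fractions on a pass-through pathway."""
        m1 = rf.Mixture.from_dict({"S": (1.0, 0.0, 0.0)})
        m2 = rf.Mixture.from_dict({"S": (0.0, 0.4, 0.6)})
        state = chain.states(1)[0]

        def sim(mix):
            return rf.simulate_labeling(
                chain.model, chain.graph, state, mix, chain.catalogue
            ).values

        for alpha in (0.25, 0.5, 0.9):
            blend = rf.Mixture.from_dict(
                {"S": tuple(alpha * a + (1 - alpha) * b
                            for a, b in zip((1.0, 0.0, 0.0), (0.0, 0.4, 0.6)))}
            )
            expected = alpha * sim(m1) + (1 - alpha) * sim(m2)
            assert np.abs(sim(blend) - expected).max() < 1e-12


class TestCumomerOracle:
    def test_agrees_with_emu_on_all_fixtures(self, all_networks):
        for prep in all_networks:
            mixes = prep.random_mixtures(2, seed=31)
            for state in prep.states(3):
                for mix in mixes:
                    y_emu = rf.simulate_labeling(
                        prep.model, prep.graph, state, mix, prep.catalogue
                    )
                    y_cum = rf.cumomer_simulate(
                        prep.model, state, mix, prep.catalogue
                    )
                    assert np.abs(y_emu.values - y_cum.values).max() < 1e-8

    def test_condensation_example(self):
        model = _condensation_model()
        catalogue = {
            "A": [rf.TracerSpecies("A", "U", (1,), 99.0, 1.0)],
            "B": [rf.TracerSpecies("B", "12C", (0,), 99.0, 1.0)],
        }
        mix = rf.Mixture.from_dict({"A": (1.0,), "B": (1.0,)})
        y = rf.cumomer_simulate(model, _state(model, [50.0]), mix, catalogue)
        assert y.group_values("ms_C") == pytest.approx([0.01, 0.99, 0.0], abs=1e-12)


class TestErrorModel:
    @pytest.mark.parametrize(
        "y, sigma",
        [(0.0, 6.655e-3), (1.0, 4.7855e-2), (0.5, 2.7255e-2)],
    )
    def test_affine_sigma(self, y, sigma):
        assert rf.error_sigma(y) == pytest.approx(sigma, abs=1e-15)

    def test_covariance_stacks_labeling_and_rates(self, branch):
        mix = branch.random_mixtures(1, seed=3)[0]
        y = rf.simulate_labeling(
            branch.model, branch.graph, branch.states(1)[0], mix, branch.catalogue
        )
        diag = rf.measurement_covariance(branch.model, y)
        n_rates = len(branch.model.measurement.rates)
        assert len(diag) == len(y) + n_rates
        assert diag[: len(y)] == pytest.approx(rf.error_sigma(y.values) ** 2)
        assert diag[-n_rates:] == pytest.approx(
            [r.stddev**2 for r in branch.model.measurement.rates]
        )
        assert (diag > 0).all()
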