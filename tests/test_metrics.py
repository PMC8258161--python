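"""Fisher information, active-flux selection, D-criterion and cost metrics."""

import math

import numpy as np
import pytest

import redflux as rf
from redflux.metrics import (
    IdentifiabilityThresholds,
    exhaustive_best_subset,
    greedy_elimination_path,
)


class TestFisherInformation:
    def test_identity(self):
        fim = rf.fisher_information(np.eye(2), np.ones(2))
        assert fim.matrix == pytest.approx(np.eye(2))

    def test_scalar(self):
        fim = rf.fisher_information(np.array([[2.0]]), np.array([4.0]))
        assert fim.matrix == pytest.approx(np.array([[1.0]]))

    def test_zero_column_gives_zero_row_and_col(self):
        J = np.array([[1.0, 0.0], [2.0, 0.0], [0.5, 0.0]])
        fim = rf.fisher_information(J, np.ones(3))
        assert np.abs(fim.matrix[1]).max() == 0.0
        assert np.abs(fim.matrix[:, 1]).max() == 0.0

    def test_psd_and_symmetric_on_pipeline_fims(self, branch):
        from redflux.labeling import measurement_covariance

        mix = branch.random_mixtures(1, seed=8)[0]
        for state in branch.states(3):
            rec = rf.jacobian(branch.model, branch.graph, state, mix,
                              branch.catalogue)
            sigma = measurement_covariance(branch.model, rec.labeling)
            fim = rf.fisher_information(rec.J, sigma)
            assert np.abs(fim.matrix - fim.matrix.T).max() < 1e-10
            assert np.linalg.eigvalsh(fim.matrix).min() > -1e-10

    def test_dimension_mismatch(self):
        with pytest.raises(rf.ModelError):
            rf.fisher_information(np.eye(2), np.ones(3))


class TestActiveFluxSelection:
    def test_extreme_diagonal_keeps_strong_flux(self):
        fim = rf.fisher_information(
            np.diag([1e3, 1e-8]), np.ones(2), labels=("a", "b")
        )
        sel = rf.select_active_fluxes(fim)
        assert sel.n_act == 1
        assert sel.labels == ("a",)
        assert sel.removed == (1,)

    def test_identity_keeps_everything(self):
        fim = rf.fisher_information(np.eye(4), np.ones(4))
        sel = rf.select_active_fluxes(fim)
        assert sel.n_act == 4
        assert sel.removed == ()

    def test_zero_fim_degenerates(self):
        fim = rf.fisher_information(np.zeros((3, 3)), np.ones(3))
        sel = rf.select_active_fluxes(fim)
        assert sel.degenerate
        assert sel.n_act == 0
        assert sel.cov is None

    def test_maximality_on_rank_deficient_fims(self):
        """The returned maximal set cannot be grown by any removed flux."""
        thresholds = IdentifiabilityThresholds()
        rng = np.random.default_rng(99)
        for trial in range(20):
            n = int(rng.integers(3, 7))
            r = int(rng.integers(1, n))
            J = rng.normal(size=(r, n))
            fim = rf.fisher_information(J, np.ones(r))
            sel = rf.select_active_fluxes(fim, thresholds=thresholds)
            assert sel.n_act <= r
            for j in sel.removed:
                grown = sorted(sel.active + (j,))
                sub = fim.matrix[np.ix_(grown, grown)]
                assert not thresholds.admissible(sub, fim.norm)

    def test_greedy_matches_exhaustive_on_small_fims(self):
        rng = np.random.default_rng(7)
        agree = 0
        for trial in range(30):
            n = int(rng.integers(2, 7))
            r = int(rng.integers(1, n + 1))
            J = rng.normal(size=(r + 2, n)) @ np.diag(rng.uniform(0.1, 2.0, n))
            if r < n:  # degrade rank
                U, s, Vt = np.linalg.svd(J, full_matrices=False)
                s[r:] = 0.0
                J = U @ np.diag(s) @ Vt
            fim = rf.fisher_information(J, np.ones(J.shape[0]))
            sel = rf.select_active_fluxes(fim, verify=True)
            if sel.degenerate:
                continue
            assert sel.matches_exhaustive is not None
            agree += bool(sel.matches_exhaustive)
        assert agree >= 20  # the heuristic should usually find the optimum

    def test_elimination_path_covers_all_sizes(self):
        fim = rf.fisher_information(np.eye(5), np.ones(5))
        path = greedy_elimination_path(fim)
        assert sorted(path) == [1, 2, 3, 4, 5]
        for size, (subset, ok) in path.items():
            assert len(subset) == size
            assert ok


class TestCovariance:
    def test_diagonal_inverse(self):
        cov = rf.covariance(np.diag([4.0, 25.0]))
        assert cov == pytest.approx(np.diag([0.25, 0.04]))

    def test_stddevs_from_cov_diagonal(self):
        fim = rf.fisher_information(np.diag([2.0, 5.0]), np.ones(2))
        sel = rf.select_active_fluxes(fim)
        assert sel.stddevs() == pytest.approx([1 / 2.0, 1 / 5.0])

    def test_inverse_property_random_spd(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            A = rng.normal(size=(5, 5))
            spd = A @ A.T + 5 * np.eye(5)
            cov = rf.covariance(spd)
            assert np.abs(cov @ spd - np.eye(5)).max() < 1e-8

    def test_threshold_violation_raises(self):
        with pytest.raises(rf.ModelError):
            rf.covariance(np.diag([1.0, 1e-30]))


class TestDCriterion:
    def test_reference_vs_itself_is_one(self):
        cov = np.diag([2.0, 3.0])
        assert rf.d_criterion(cov, cov, 2) == pytest.approx(1.0)

    def test_closed_form_improvement(self):
        assert rf.d_criterion(np.eye(2), np.diag([4.0, 4.0]), 2) == pytest.approx(2.0)

    @pytest.mark.parametrize("n", [1, 2, 5])
    def test_scaled_covariance(self, n):
        rng = np.random.default_rng(n)
        A = rng.normal(size=(n, n))
        ref = A @ A.T + np.eye(n)
        assert rf.d_criterion(4.0 * ref, ref, n) == pytest.approx(0.5)

    def test_full_exponent_convention(self):
        assert rf.d_criterion(
            np.eye(2), np.diag([4.0, 4.0]), 2, exponent="full"
        ) == pytest.approx(4.0)

    def test_sigma_scaling_scales_criterion(self):
        """Shrinking every sigma by alpha scales Phi_D by alpha (ref fixed)."""
        rng = np.random.default_rng(3)
        J = rng.normal(size=(8, 3))
        sigma = rng.uniform(0.5, 1.5, 8)
        ref = np.linalg.inv(rf.fisher_information(J, sigma**2).matrix)
        for alpha in (2.0, 10.0):
            cand = np.linalg.inv(
                rf.fisher_information(J, (sigma / alpha) ** 2).matrix
            )
            phi = rf.d_criterion(cand, ref, 3)
            assert phi == pytest.approx(alpha, rel=1e-10)

    def test_nonpositive_determinant_rejected(self):
        with pytest.raises(rf.ModelError):
            rf.d_criterion(np.diag([1.0, -1.0]), np.eye(2), 2)


class TestTracerCost:
    def test_single_expensive_species(self):
        catalogue = {"ARG": [rf.TracerSpecies("ARG", "U", (1,) * 5, 99.0, 3449.0)]}
        mix = rf.Mixture.from_dict({"ARG": (1.0,)})
        assert rf.tracer_cost(catalogue, mix, {"ARG": 1.0}) == pytest.approx(3449.0)

    def test_unlabeled_bulk(self):
        catalogue = {"GLYC": [rf.TracerSpecies("GLYC", "12C", (0, 0, 0), 99.0, 0.36)]}
        mix = rf.Mixture.from_dict({"GLYC": (1.0,)})
        assert rf.tracer_cost(catalogue, mix, {"GLYC": 25.0}) == pytest.approx(9.0)

    def test_zero_amount_costs_nothing(self):
        catalogue = {"S": [rf.TracerSpecies("S", "U", (1,), 99.0, 100.0)]}
        mix = rf.Mixture.from_dict({"S": (1.0,)})
        assert rf.tracer_cost(catalogue, mix, {"S": 0.0}) == 0.0

    def test_missing_amount_raises(self):
        catalogue = {"S": [rf.TracerSpecies("S", "U", (1,), 99.0, 100.0)]}
        mix = rf.Mixture.from_dict({"S": (1.0,)})
        with pytest.raises(rf.ModelError):
            rf.tracer_cost(catalogue, mix, {})

    def test_chemostat_amounts(self):
        amounts = rf.substrate_amounts(
            {"GLYC": 20.0, "ARG": 0.17}, dilution_rate=0.03, volume=0.25,
            residence_times=5.0,
        )
        assert amounts["GLYC"] == pytest.approx(25.0)
        assert amounts["ARG"] == pytest.approx(0.2125)
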