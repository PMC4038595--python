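import math

import numpy as np
import pytest
from scipy import stats

from conftest import make_network
from coexpredict.data_model import SourceValues
from coexpredict.perturbation import (
    BufferModel,
    PerturbationSpec,
    apply_perturbations,
    buffer_sweep,
    classify_affected,
    fit_quadratic_response,
    predict_perturbation,
)
from coexpredict.predictor import (
    PathEnumerationPolicy,
    predict_single_pass,
)
from coexpredict.synthetic import (
    fit_network_on_truth,
    network_from_truth,
    simulate_chain_network,
)


class TestApplyPerturbations:
    def test_all_ratios_one_unchanged(self):
        bg = SourceValues({"a": 5.0, "b": 7.0})
        out = apply_perturbations(bg, PerturbationSpec({"a": 1.0, "b": 1.0}))
        assert dict(out.items()) == {"a": 5.0, "b": 7.0}

    def test_ratio_scaling(self):
        out = apply_perturbations(
            SourceValues({"g": 10.0}), PerturbationSpec({"g": 1.8})
        )
        assert out["g"] == pytest.approx(18.0)

    def test_example_ratio_pair(self):
        bg = SourceValues({"A": 10.0, "B": 5.0, "C": 2.0})
        out = apply_perturbations(bg, PerturbationSpec({"A": 1.8, "B": 0.4}))
        assert out["A"] == pytest.approx(18.0)
        assert out["B"] == pytest.approx(2.0)
        assert out["C"] == 2.0

    def test_unknown_gene_errors(self):
        with pytest.raises(KeyError):
            apply_perturbations(SourceValues({"a": 1.0}), PerturbationSpec({"x": 2.0}))

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            PerturbationSpec({"a": -0.5})

    def test_knockout_ratio_zero_allowed(self):
        out = apply_perturbations(SourceValues({"a": 9.0}), PerturbationSpec({"a": 0.0}))
        assert out["a"] == 0.0


class TestPredictPerturbation:
    def test_null_perturbation_identical_passes(self):
        matrix, truth = simulate_chain_network([1, 2, 2, 1], 40, noise_sd=0.3, seed=3)
        net = fit_network_on_truth(matrix, truth)
        bg = SourceValues({g: float(matrix.row(g)[0]) for g in matrix.row_ids})
        result = predict_perturbation(net, bg, PerturbationSpec({"L0N00": 1.0}))
        for gene in result.baseline:
            assert result.baseline[gene].mean == result.perturbed[gene].mean
        assert result.affected == set()

    def test_knockout_single_edge_arithmetic(self):
        net = make_network([("A", "B", 2.0, 1.0)])
        bg = SourceValues({"A": 5.0})
        result = predict_perturbation(net, bg, PerturbationSpec({"A": 0.0}))
        assert result.baseline["B"].mean == pytest.approx(11.0)
        assert result.perturbed["B"].mean == pytest.approx(1.0)

    def test_reachable_is_union_of_jump_neighborhoods(self):
        net = make_network([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"),
                            ("E", "F"), ("X", "Y")])
        bg = SourceValues({g: 1.0 for g in net.nodes})
        result = predict_perturbation(
            net, bg, PerturbationSpec({"A": 2.0}),
            policy=PathEnumerationPolicy(max_len=4),
        )
        assert result.reachable == {"B", "C", "D", "E"}

    def test_matches_two_independent_predictor_runs(self):
        matrix, truth = simulate_chain_network([2, 2, 2], 50, noise_sd=0.4, seed=7)
        net = fit_network_on_truth(matrix, truth)
        bg = SourceValues({g: float(matrix.row(g)[2]) for g in matrix.row_ids})
        spec = PerturbationSpec({"L0N00": 1.8, "L0N01": 0.4})
        policy = PathEnumerationPolicy(max_len=4)
        result = predict_perturbation(net, bg, spec, policy=policy)
        base_oracle = predict_single_pass(
            net, SourceValues({g: bg[g] for g in spec.ratios}), policy
        )
        pert_oracle = predict_single_pass(
            net,
            SourceValues({g: bg[g] * r for g, r in spec.ratios.items()}),
            policy,
        )
        assert result.baseline == base_oracle
        assert result.perturbed == pert_oracle

    def test_affected_subset_of_reachable(self):
        matrix, truth = simulate_chain_network([1, 2, 2, 1], 40, noise_sd=0.3, seed=9)
        net = fit_network_on_truth(matrix, truth)
        bg = SourceValues({g: float(matrix.row(g)[0]) for g in matrix.row_ids})
        result = predict_perturbation(net, bg, PerturbationSpec({"L0N00": 0.0}))
        assert result.affected <= result.reachable

    def test_perturbed_gene_must_be_in_network(self):
        net = make_network([("A", "B")])
        with pytest.raises(Exception):
            predict_perturbation(net, SourceValues({"Z": 1.0}),
                                 PerturbationSpec({"Z": 2.0}))


class TestClassifyAffected:
    @staticmethod
    def _result_with(jumps, base_mean, base_sd, base_n, post_mean, post_sd, post_n):
        from coexpredict.perturbation import PerturbationResult
        from coexpredict.predictor import PredictionResult

        base = {"g": PredictionResult("g", base_mean, base_sd, base_n, jumps, ["s"],
                                      adjacent=jumps == 1)}
        post = {"g": PredictionResult("g", post_mean, post_sd, post_n, jumps, ["s"],
                                      adjacent=jumps == 1)}
        return PerturbationResult(PerturbationSpec({"s": 2.0}), "single", base, post)

    def test_identical_passes_empty(self):
        result = self._result_with(2, 5.0, 1.0, 10, 5.0, 1.0, 10)
        assert classify_affected(result) == set()

    def test_one_jump_fold_rule(self):
        result = self._result_with(1, 2.0, None, 1, 7.0, None, 1)
        affected = classify_affected(result, fold_threshold=3.0)
        assert affected == {"g"}
        assert result.calls["g"].statistic == pytest.approx(3.5)
        assert result.calls["g"].statistic_type == "fold"

    def test_one_jump_below_fold_not_affected(self):
        result = self._result_with(1, 2.0, None, 1, 5.0, None, 1)
        assert classify_affected(result, fold_threshold=3.0) == set()

    def test_z_decision_matches_hand_computation(self):
        # z = (post - base) / sqrt(s1^2/n1 + s2^2/n2); Bonferroni m = 1 here
        base_mean, base_sd, n1 = 10.0, 1.5, 40
        post_mean, post_sd, n2 = 9.0, 1.2, 40
        result = self._result_with(3, base_mean, base_sd, n1, post_mean, post_sd, n2)
        classify_affected(result, alpha=0.05)
        z_hand = (post_mean - base_mean) / math.sqrt(
            base_sd**2 / n1 + post_sd**2 / n2
        )
        p_hand = 2 * stats.norm.sf(abs(z_hand))
        call = result.calls["g"]
        assert call.statistic == pytest.approx(z_hand, rel=1e-12)
        assert call.p_value == pytest.approx(p_hand, rel=1e-12)
        assert call.affected == (p_hand < 0.05)

    def test_bonferroni_over_z_tested_genes(self):
        from coexpredict.perturbation import PerturbationResult
        from coexpredict.predictor import PredictionResult

        # 3 z-tested genes -> each raw p multiplied by 3
        base, post = {}, {}
        for i, shift in enumerate([0.0, 0.5, 3.0]):
            g = f"g{i}"
            base[g] = PredictionResult(g, 10.0, 1.0, 30, 2, ["s"])
            post[g] = PredictionResult(g, 10.0 + shift, 1.0, 30, 2, ["s"])
        result = PerturbationResult(PerturbationSpec({"s": 2.0}), "single", base, post)
        classify_affected(result, alpha=0.05)
        for i, shift in enumerate([0.0, 0.5, 3.0]):
            z = shift / math.sqrt(2.0 / 30.0)
            expected_p = min(1.0, 3 * 2 * stats.norm.sf(abs(z)))
            assert result.calls[f"g{i}"].p_value == pytest.approx(expected_p, rel=1e-9)

    def test_zero_sd_mean_shift_is_affected(self):
        result = self._result_with(2, 5.0, 0.0, 4, 6.0, 0.0, 4)
        assert classify_affected(result) == {"g"}
        assert result.calls["g"].p_value == 0.0


class TestFitQuadraticResponse:
    def test_exact_quadratic_roots(self):
        grid = [0.5, 0.75, 1.0, 1.25, 1.5]
        responses = [400 * (x - 1) ** 2 - 4 for x in grid]
        coeffs, roots, diag = fit_quadratic_response(grid, responses)
        assert diag == ""
        assert roots[0] == pytest.approx(0.9, abs=1e-9)
        assert roots[1] == pytest.approx(1.1, abs=1e-9)
        a, b, c = coeffs
        assert a == pytest.approx(400.0, rel=1e-9)

    def test_flat_response_degenerate(self):
        coeffs, roots, diag = fit_quadratic_response([0.5, 1.0, 1.5], [0.0, 0.0, 0.0])
        assert roots is None
        assert "degenerate" in diag

    def test_negative_discriminant_no_roots(self):
        grid = [0.5, 1.0, 1.5]
        responses = [(x - 1) ** 2 + 5 for x in grid]
        _, roots, diag = fit_quadratic_response(grid, responses)
        assert roots is None
        assert "discriminant" in diag

    def test_grid_refinement_invariance_on_exact_quadratic(self):
        # adding grid points to an exactly quadratic response leaves the
        # fitted coefficients unchanged
        f = lambda x: 250 * (x - 1) ** 2 - 10  # noqa: E731
        grid5 = [0.0, 0.5, 1.0, 1.5, 2.0]
        grid21 = [round(0.1 * i, 10) for i in range(21)]
        c5, r5, _ = fit_quadratic_response(grid5, [f(x) for x in grid5])
        c21, r21, _ = fit_quadratic_response(grid21, [f(x) for x in grid21])
        assert c5 == pytest.approx(c21, rel=1e-8)
        assert r5 == pytest.approx(r21, rel=1e-8)

    def test_noisy_quadratic_roots_recovered(self):
        # generator ground truth: roots 0.8 and 1.2
        rng = np.random.default_rng(0)
        grid = [round(0.1 * i, 10) for i in range(21)]
        true = lambda x: 500 * (x - 1) ** 2 - 20  # noqa: E731
        for _ in range(5):
            noisy = [true(x) + rng.normal(0, 2.0) for x in grid]
            _, roots, _ = fit_quadratic_response(grid, noisy)
            assert roots[0] == pytest.approx(0.8, rel=0.05)
            assert roots[1] == pytest.approx(1.2, rel=0.05)

    def test_too_few_distinct_ratios(self):
        coeffs, roots, diag = fit_quadratic_response([1.0, 1.0, 2.0], [1, 1, 2])
        assert coeffs is None and roots is None


class TestBufferSweep:
    @staticmethod
    def _setup(noise=0.35, seed=5):
        matrix, truth = simulate_chain_network(
            [1, 3, 3, 2], 60, noise_sd=noise, seed=seed
        )
        net = fit_network_on_truth(matrix, truth)
        bg = SourceValues({g: float(matrix.row(g)[0]) for g in matrix.row_ids})
        return net, bg

    def test_sweep_shape_and_ratio_one_zero_affected(self):
        net, bg = self._setup()
        grid = [round(0.2 * i, 10) for i in range(11)]
        model = buffer_sweep(net, bg, "L0N00", grid,
                             policy=PathEnumerationPolicy(max_len=4))
        assert model.ratios == grid
        assert len(model.counts) == len(grid)
        at_one = grid.index(1.0)
        assert model.counts[at_one] == 0
        # response grows away from ratio 1 (weakly, at the endpoints)
        assert model.counts[0] >= model.counts[at_one]
        assert model.counts[-1] >= model.counts[at_one]

    def test_buffer_interval_brackets_one_when_found(self):
        net, bg = self._setup()
        grid = [round(0.1 * i, 10) for i in range(21)]
        model = buffer_sweep(net, bg, "L0N00", grid,
                             policy=PathEnumerationPolicy(max_len=4))
        if model.buffer_interval is not None:
            lo, hi = model.buffer_interval
            assert lo < 1.0 < hi
            assert lo >= min(grid) and hi <= max(grid)

    def test_all_zero_response_degenerate(self):
        # star topology: every reachable gene is 1 jump away, so only the
        # fold rule applies; a huge fold threshold keeps all responses at 0
        net = make_network([("S", f"x{i}") for i in range(4)])
        bg = SourceValues({g: 8.0 for g in net.nodes})
        grid = [0.8, 0.9, 1.0, 1.1, 1.2]
        model = buffer_sweep(net, bg, "S", grid,
                             policy=PathEnumerationPolicy(max_len=4),
                             fold_threshold=1e6)
        assert model.counts == [0] * len(grid)
        assert model.degenerate
        assert model.buffer_interval is None

    def test_count_and_pct_responses_consistent(self):
        net, bg = self._setup()
        grid = [0.0, 0.5, 1.0, 1.5, 2.0]
        m_pct = buffer_sweep(net, bg, "L0N00", grid, response="pct")
        m_cnt = buffer_sweep(net, bg, "L0N00", grid, response="count")
        assert m_pct.counts == m_cnt.counts
        n_reach = len(m_pct.percentages)
        for count, pct in zip(m_pct.counts, m_pct.percentages):
            assert pct == pytest.approx(100.0 * count / 8.0)  # 8 reachable genes

    def test_grid_must_have_three_distinct(self):
        net, bg = self._setup()
        with pytest.raises(ValueError):
            buffer_sweep(net, bg, "L0N00", [1.0, 1.0, 1.0])
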