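"""PCM probabilities, simulation, JMLE calibration, ability estimation."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmunit.rasch_sim import (
    MISSING,
    CalibrationConfig,
    PCMItem,
    PersonSample,
    ResponseMatrix,
    calibrate_item_difficulties,
    estimate_person_ability,
    generate_difficulty_dataset,
    pcm_category_probabilities,
    read_response_matrix,
    rescale_logits,
    simulate_responses,
    write_response_matrix,
)
from gmunit.spec_equation import predict_table


class TestPCMProbabilities:
    def test_dichotomous_symmetry_at_difficulty(self):
        item = PCMItem(difficulty=0.7, thresholds=(0.0,))
        assert pcm_category_probabilities(0.7, item) == pytest.approx([0.5, 0.5])

    def test_matches_direct_enumeration(self):
        # theta = 0, delta = 0, tau = (-1, 0, 1): unnormalized terms are
        # exp(0), exp(1), exp(1), exp(0)
        item = PCMItem(difficulty=0.0, thresholds=(-1.0, 0.0, 1.0))
        raw = np.array([1.0, np.e, np.e, 1.0])
        assert pcm_category_probabilities(0.0, item) == pytest.approx(raw / raw.sum())

    @given(
        st.floats(min_value=-5, max_value=5),
        st.floats(min_value=-3, max_value=3),
        st.lists(st.floats(min_value=-2, max_value=2), min_size=1, max_size=5),
    )
    @settings(derandomize=True, max_examples=150)
    def test_normalization_over_random_parameters(self, theta, delta, raw_taus):
        taus = np.asarray(raw_taus) - np.mean(raw_taus)
        item = PCMItem(difficulty=delta, thresholds=tuple(taus))
        p = pcm_category_probabilities(theta, item)
        assert p.sum() == pytest.approx(1.0)
        assert np.all(p >= 0) and np.all(p <= 1)
        assert len(p) == item.n_categories

    def test_uncentred_thresholds_rejected(self):
        with pytest.raises(ValueError, match="sum to zero"):
            PCMItem(difficulty=0.0, thresholds=(1.0, 1.0))

    def test_from_steps_centres(self):
        item = PCMItem.from_steps([0.5, 1.5])
        assert item.difficulty == pytest.approx(1.0)
        assert item.thresholds == pytest.approx((-0.5, 0.5))


class TestSimulateResponses:
    def test_same_seed_identical_matrices(self):
        items = [PCMItem(0.0, (-0.5, 0.0, 0.5)), PCMItem(1.0, (0.0,))]
        persons = PersonSample.normal(50, seed=3)
        a = simulate_responses(items, persons, seed=11)
        b = simulate_responses(items, persons, seed=11)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, simulate_responses(items, persons, seed=12).data)

    def test_extreme_ability_hits_top_category(self):
        items = [PCMItem(0.0, (-0.5, 0.0, 0.5))] * 5
        persons = PersonSample(np.full(200, 10.0))
        m = simulate_responses(items, persons, seed=0)
        assert (m.data == 3).mean() > 0.99

    def test_pass_rate_within_binomial_bound(self):
        # 2000 persons at theta=0 on one dichotomous item at delta=0:
        # pass rate within 3 binomial SEs of 0.5
        persons = PersonSample(np.zeros(2000))
        m = simulate_responses([PCMItem(0.0, (0.0,))], persons, seed=5)
        se = 0.5 / np.sqrt(2000)
        assert abs(m.data.mean() - 0.5) < 3 * se


class TestCalibration:
    def test_two_item_recovery_and_symmetry(self):
        items = [PCMItem(-1.0, (0.0,)), PCMItem(1.0, (0.0,))]
        persons = PersonSample.normal(4000, 0.0, 1.5, seed=7)
        result = calibrate_item_difficulties(simulate_responses(items, persons, seed=8))
        assert result.converged
        assert result.difficulties.sum() == pytest.approx(0.0, abs=1e-9)
        assert result.difficulties[0] == pytest.approx(-result.difficulties[1])
        assert result.difficulties == pytest.approx([-1.0, 1.0], abs=0.15)

    def test_constant_item_flagged_inestimable(self):
        items = [PCMItem(-0.5, (0.0,)), PCMItem(0.5, (0.0,)), PCMItem(0.0, (0.0,))]
        persons = PersonSample.normal(300, 0.0, 1.5, seed=1)
        m = simulate_responses(items, persons, seed=2)
        data = m.data.copy()
        data[:, 2] = 0  # degenerate: single observed category
        with pytest.warns(UserWarning, match="inestimable"):
            result = calibrate_item_difficulties(
                ResponseMatrix(data=data, n_categories=m.n_categories)
            )
        assert result.excluded_items == (2,)
        assert np.isnan(result.difficulties[2])
        assert np.isfinite(result.difficulties[:2]).all()

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            calibrate_item_difficulties(
                ResponseMatrix(data=np.empty((0, 2), dtype=int), n_categories=(2, 2))
            )

    def test_missing_responses_are_skipped(self):
        items = [PCMItem(float(d), (0.0,)) for d in (-1.0, 0.0, 1.0)]
        persons = PersonSample.normal(2000, 0.0, 1.5, seed=4)
        m = simulate_responses(items, persons, seed=5)
        data = m.data.copy()
        rng = np.random.default_rng(6)
        mask = rng.random(data.shape) < 0.15
        data[mask] = MISSING
        result = calibrate_item_difficulties(
            ResponseMatrix(data=data, n_categories=m.n_categories)
        )
        assert result.converged
        assert result.difficulties == pytest.approx([-1.0, 0.0, 1.0], abs=0.2)

    def test_unconverged_flag_when_iterations_exhausted(self):
        items = [PCMItem(float(d), (0.0,)) for d in (-1.0, 1.0)]
        persons = PersonSample.normal(500, 0.0, 1.5, seed=9)
        m = simulate_responses(items, persons, seed=9)
        result = calibrate_item_difficulties(m, CalibrationConfig(tol=1e-12, max_iter=2))
        assert not result.converged
        assert result.iterations == 2


class TestPersonAbility:
    def test_single_item_pass_is_extreme(self):
        est = estimate_person_ability([1], [PCMItem(0.0, (0.0,))])
        assert est.extreme and est.bound == "max"
        assert est.theta == float("inf")

    def test_single_item_fail_is_extreme(self):
        est = estimate_person_ability([0], [PCMItem(0.0, (0.0,))])
        assert est.extreme and est.bound == "min"

    def test_symmetric_pattern_gives_zero(self):
        items = [PCMItem(-1.0, (0.0,)), PCMItem(1.0, (0.0,))]
        est = estimate_person_ability([1, 0], items)
        assert not est.extreme
        assert est.theta == pytest.approx(0.0, abs=1e-8)

    def test_recovery_over_fifty_items(self):
        items = [PCMItem(float(d), (-0.5, 0.0, 0.5)) for d in np.linspace(-2, 2, 50)]
        m = simulate_responses(items, PersonSample(np.array([1.0])), seed=13)
        est = estimate_person_ability(m.data[0], items)
        assert not est.extreme
        assert est.theta == pytest.approx(1.0, abs=0.5)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="non-missing"):
            estimate_person_ability([MISSING, MISSING], [PCMItem(0.0, (0.0,))] * 2)


class TestRescaleLogits:
    def test_affine_endpoints(self):
        assert rescale_logits([-2.0, 0.0, 2.0], 0, 100) == pytest.approx([0.0, 50.0, 100.0])
        assert rescale_logits([-1.0, 3.0], 10, 20) == pytest.approx([10.0, 20.0])

    def test_order_preserved(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=30)
        out = rescale_logits(d, 0, 100)
        assert np.array_equal(np.argsort(d), np.argsort(out))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rescale_logits([1.0, 1.0, 1.0], 0, 100)


class TestDifficultyDataset:
    def test_noiseless_reproduces_predictions_exactly(self, gmfm_table, equation):
        values = generate_difficulty_dataset(equation, gmfm_table, 0.0, seed=0)
        assert np.array_equal(values, predict_table(equation, gmfm_table))
        by_item = dict(zip(gmfm_table.item_numbers, values))
        assert by_item[2] == pytest.approx(14.13)
        assert by_item[69] == pytest.approx(61.88)

    def test_replicate_mean_converges_to_prediction(self, gmfm_table, equation):
        draws = np.array(
            [generate_difficulty_dataset(equation, gmfm_table, 6.09, seed=s) for s in range(400)]
        )
        mc_se = 6.09 / np.sqrt(400)
        assert np.all(np.abs(draws.mean(axis=0) - predict_table(equation, gmfm_table)) < 4 * mc_se)

    def test_seed_reproducible(self, gmfm_table, equation):
        a = generate_difficulty_dataset(equation, gmfm_table, 6.09, seed=42)
        b = generate_difficulty_dataset(equation, gmfm_table, 6.09, seed=42)
        assert np.array_equal(a, b)

    def test_negative_noise_rejected(self, gmfm_table, equation):
        with pytest.raises(ValueError, match="non-negative"):
            generate_difficulty_dataset(equation, gmfm_table, -1.0, seed=0)


class TestResponseMatrixIO:
    def test_csv_roundtrip_with_missing(self):
        data = np.array([[0, 2, MISSING], [3, MISSING, 1], [1, 0, 0]])
        matrix = ResponseMatrix(data=data, n_categories=(4, 3, 2))
        buffer = io.StringIO()
        write_response_matrix(matrix, buffer)
        buffer.seek(0)
        back = read_response_matrix(buffer, n_categories=(4, 3, 2))
        assert np.array_equal(back.data, matrix.data)

    def test_illegal_category_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ResponseMatrix(data=np.array([[0, 5]]), n_categories=(2, 4))


class TestCalibrationDuality:
    def test_calibrate_rescale_regress_recovers_equation_direction(self, gmfm_table, equation):
        """Simulating responses whose item difficulties follow the reference
        equation, calibrating, rescaling onto the difficulty metric, and
        refitting yields coefficients positively correlated with (and close
        in direction to) the generating ones."""
        from gmunit.spec_equation import forward_stepwise_fit

        preds = predict_table(equation, gmfm_table)
        deltas = rescale_logits(preds, -3.0, 3.0)
        deltas -= deltas.mean()
        items = [PCMItem(float(d), (-0.5, 0.0, 0.5)) for d in deltas]
        persons = PersonSample.normal(500, 0.0, 2.0, seed=11)
        result = calibrate_item_difficulties(simulate_responses(items, persons, seed=12))
        assert result.converged
        observed = rescale_logits(result.difficulties, preds.min(), preds.max())
        fitted, report = forward_stepwise_fit(observed, gmfm_table)
        generating = np.array(
            [equation.coef_body_position, equation.coef_movement, equation.coef_support]
        )
        recovered = np.array(
            [fitted.coef_body_position, fitted.coef_movement, fitted.coef_support]
        )
        assert np.all(recovered > 0)
        assert np.corrcoef(generating, recovered)[0, 1] > 0.9
        assert report.adjusted_r2 > 0.9
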