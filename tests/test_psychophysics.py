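"""3AFC decision rule, simulated experiment, and factorial analysis."""

import numpy as np
import pandas as pd
import pytest

from fgseg.config import ChoiceParams
from fgseg.errors import AnalysisError
from fgseg.psychophysics import (CONDITIONS, anova_2x3, calibrate_choice_params,
                                 choice_probabilities, response_frequencies,
                                 simulate_experiment)


def test_zero_margin_is_symmetric():
    p = choice_probabilities(0.0)
    assert abs(p[0] - p[1]) < 1e-12
    assert abs(sum(p) - 1.0) < 1e-12


def test_large_margin_saturates_front():
    p = choice_probabilities(1.0, gain=8.0, lapse=0.0, u_same=-1.0)
    assert p[0] > 0.99
    assert p[1] < 1e-3


def test_lapse_mixes_toward_uniform():
    p = choice_probabilities(1.0, gain=8.0, lapse=0.3, u_same=-1.0)
    assert min(p) >= 0.1 - 1e-12


@pytest.mark.parametrize("kwargs", [
    {"gain": -1.0}, {"gain": 0.0}, {"lapse": 1.0}, {"lapse": -0.1},
])
def test_invalid_choice_parameters_rejected(kwargs):
    with pytest.raises(ValueError):
        choice_probabilities(0.5, **{"gain": 2.0, "lapse": 0.0, **kwargs})


def test_default_calibration_reproduces_response_ordering():
    """With the fitted decision rule, a positive model margin yields the
    observed ordering p_front >> p_same > p_behind."""
    p = choice_probabilities(5 / 7)
    assert p[0] > 0.75
    assert p[0] > 4 * p[2] > 4 * p[1]


def test_calibration_fits_the_observed_triples():
    cp = calibrate_choice_params({"inward": 5 / 7, "outward": -5 / 7})
    p_in = choice_probabilities(5 / 7, params=cp)
    assert abs(p_in[0] - 0.83) < 0.06
    assert abs(p_in[1] - 0.07) < 0.06


def test_degenerate_probabilities_give_one_response():
    probs = {c: (1.0, 0.0, 0.0) for c in CONDITIONS}
    trials = simulate_experiment(probs, seed=3)
    assert (trials["response"] == "in_front").all()


def test_experiment_is_reproducible_and_balanced():
    probs = {c: (0.5, 0.3, 0.2) for c in CONDITIONS}
    a = simulate_experiment(probs, n_subjects=10, n_reps=4, seed=7)
    b = simulate_experiment(probs, n_subjects=10, n_reps=4, seed=7)
    pd.testing.assert_frame_equal(a, b)
    assert len(a) == 10 * 6 * 4
    counts = a.groupby(["subject_id", "edge_direction",
                        "polarity_scheme"]).size()
    assert (counts == 4).all()


def test_invalid_simplex_rejected():
    probs = {c: (0.5, 0.3, 0.1) for c in CONDITIONS}
    with pytest.raises(ValueError):
        simulate_experiment(probs)


def test_response_frequency_summary():
    probs = {c: (1.0, 0.0, 0.0) for c in CONDITIONS}
    trials = simulate_experiment(probs, seed=1)
    table = response_frequencies(trials)
    assert (table.means["rf_in_front"] == 1.0).all()
    assert (table.sems["rf_in_front"] == 0.0).all()
    row_sums = table.means[["rf_in_front", "rf_behind", "rf_same_plane"]].sum(axis=1)
    assert np.allclose(row_sums, 1.0)


def test_unbalanced_design_rejected():
    probs = {c: (0.5, 0.3, 0.2) for c in CONDITIONS}
    trials = simulate_experiment(probs, seed=2)
    with pytest.raises(AnalysisError):
        response_frequencies(trials.iloc[:-3])


def test_frequencies_recover_generating_probabilities():
    """Across many seeds, recovered mean RFs stay within 3 binomial SEs."""
    target = (0.8, 0.1, 0.1)
    probs = {c: target for c in CONDITIONS}
    errs = []
    for seed in range(100):
        trials = simulate_experiment(probs, seed=seed)
        table = response_frequencies(trials)
        errs.append(table.means["rf_in_front"].mean() - target[0])
    n_draws = 10 * 4  # per condition, pooled over subjects
    se = np.sqrt(target[0] * (1 - target[0]) / n_draws)
    assert np.abs(np.mean(errs)) < 3 * se / np.sqrt(len(errs))


def test_estimator_consistency_in_reps():
    """RF estimation error shrinks roughly like 1/sqrt(n_reps)."""
    target = (0.6, 0.3, 0.1)
    probs = {c: target for c in CONDITIONS}

    def mean_abs_err(n_reps):
        errs = []
        for seed in range(40):
            trials = simulate_experiment(probs, n_reps=n_reps, seed=seed)
            table = response_frequencies(trials)
            errs.append(abs(table.means["rf_in_front"].mean() - target[0]))
        return np.mean(errs)

    assert mean_abs_err(32) < 0.5 * mean_abs_err(2)


def test_anova_requires_full_design_and_variance():
    probs = {c: (0.5, 0.3, 0.2) for c in CONDITIONS}
    trials = simulate_experiment(probs, seed=0)
    table = response_frequencies(trials)
    with pytest.raises(AnalysisError):
        anova_2x3(table.per_subject[
            table.per_subject["edge_direction"] == "inward"])
    degenerate = table.per_subject.copy()
    degenerate["rf_in_front"] = 0.5
    with pytest.raises(AnalysisError):
        anova_2x3(degenerate)


def test_strong_direction_effect_is_detected():
    """Power: a 0.8-vs-0.1 in-front split is significant at alpha = 0.001 in
    nearly every simulated experiment."""
    probs = {("inward", s): (0.8, 0.1, 0.1) for s in
             ("all_negative", "all_positive", "mixed")}
    probs.update({("outward", s): (0.1, 0.8, 0.1) for s in
                  ("all_negative", "all_positive", "mixed")})
    hits = 0
    n = 100
    for seed in range(n):
        trials = simulate_experiment(probs, seed=seed)
        stats = anova_2x3(response_frequencies(trials).per_subject)
        if stats["in_front"]["direction"]["p"] < 0.001:
            hits += 1
    assert hits >= 0.99 * n


def test_polarity_effect_is_absent_under_invariant_generation():
    """When the generator ignores polarity, the polarity factor is
    non-significant at alpha = 0.05 in about 95% of experiments."""
    probs = {("inward", s): (0.8, 0.1, 0.1) for s in
             ("all_negative", "all_positive", "mixed")}
    probs.update({("outward", s): (0.1, 0.8, 0.1) for s in
                  ("all_negative", "all_positive", "mixed")})
    nonsig = 0
    n = 200
    for seed in range(n):
        trials = simulate_experiment(probs, seed=seed)
        stats = anova_2x3(response_frequencies(trials).per_subject)
        if stats["in_front"]["polarity"]["p"] >= 0.05:
            nonsig += 1
    assert 0.90 <= nonsig / n <= 1.0
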