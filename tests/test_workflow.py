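"""Sequential campaign: screening, fixing, refinement, optimum prediction."""
import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import seqdoe as sq
from seqdoe.errors import (
    EnumerationCapError,
    FewerSignificantFactorsError,
    IncompleteCellsError,
    InsufficientDataError,
)
from seqdoe.model import ModelTerm


@pytest.fixture(scope="module")
def noise_free_screening(res4_design, truth):
    noise_free = replace(truth, noise_cv=0.0)
    data = sq.simulate_response(noise_free, res4_design, 3, seed=0).responses
    config = sq.default_round1_config()
    return sq.run_screening_round(config, data, design=res4_design)


# ---------------------------------------------------------------------------
# screening


def test_noise_free_screening_recovers_truth_exactly(noise_free_screening, truth):
    sc = noise_free_screening
    # ME estimates equal the true main effects (res IV keeps them clean)
    for name in truth.factor_names:
        assert sc.me_fit.coef(name) == pytest.approx(
            truth.main_effects.get(name, 0.0), abs=1e-9
        )
    # the ME+2FI model interpolates the noiseless data perfectly
    assert sc.tfi_fit.mae == pytest.approx(0.0, abs=1e-9)
    assert sc.tfi_fit.r_squared == pytest.approx(1.0)


def test_noise_free_top3_are_palc4h_ph_phe(noise_free_screening):
    top3 = list(noise_free_screening.significant_mes["factor"].head(3))
    assert top3 == ["PAL-C4H", "pH", "Phe"]


def test_noise_free_28_run_interaction_model_still_interpolates(res4_design, truth):
    """After dropping the four infeasible runs the ME+2FI model still fits
    the noiseless responses exactly (dropped collinear representatives are
    spanned by the kept columns), even though the ME-only fit is no longer
    orthogonal to the omitted interactions."""
    noise_free = replace(truth, noise_cv=0.0)
    executed, _ = sq.remove_runs(res4_design, sq.pca_infeasible)
    data = sq.simulate_response(noise_free, executed, 3, seed=0).responses
    sc = sq.run_screening_round(
        sq.default_round1_config(), data, design=res4_design
    )
    assert sc.tfi_fit.mae == pytest.approx(0.0, abs=1e-8)
    top3 = list(sc.significant_mes["factor"].head(3))
    assert top3 == ["PAL-C4H", "pH", "Phe"]


def test_noisy_screening_flags_dominant_factors(res4_design, truth):
    executed, _ = sq.remove_runs(res4_design, sq.pca_infeasible)
    data = sq.simulate_response(truth, executed, 3, seed=0).responses
    sc = sq.run_screening_round(sq.default_round1_config(), data, design=res4_design)
    sig = dict(zip(sc.significant_mes["factor"], sc.significant_mes["coefficient"]))
    assert sig["PAL-C4H"] > 0 and sig["pH"] < 0 and sig["Phe"] > 0
    assert sc.any_significant_tfi, "confounded interaction signal is visible"


def test_screening_rejects_sparse_data(res4_design, truth):
    data = sq.simulate_response(truth, res4_design, 1, seed=0).responses
    thin = data.iloc[: res4_design.n_runs // 2]
    with pytest.raises(InsufficientDataError):
        sq.run_screening_round(sq.default_round1_config(), thin, design=res4_design)


def test_zero_effect_truth_rarely_flags_anything(res4_design):
    """Bonferroni keeps the family-wise false-flag rate at or below alpha."""
    rate = sq.familywise_error_rate(
        sq.zero_effect_truth(), res4_design, replicates=3, n_sims=150, seed=3
    )
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 150)


# ---------------------------------------------------------------------------
# fixing factors


def test_fix_factors_pins_favorable_levels(noise_free_screening):
    config2 = sq.fix_factors(noise_free_screening, k_fix=3)
    assert config2.fixed == {"PAL-C4H": 1, "pH": -1, "Phe": 1}
    assert len(config2.active) == 8
    assert config2.resolution == "V"


def test_fix_factors_zero_keeps_all_active(noise_free_screening):
    config2 = sq.fix_factors(noise_free_screening, k_fix=0)
    assert config2.fixed == {}
    assert set(config2.active) == {f.name for f in config2.factors}


def test_fix_factors_refuses_when_too_few_significant(res4_design):
    data = sq.simulate_response(
        sq.zero_effect_truth(), res4_design, 3, seed=10
    ).responses
    sc = sq.run_screening_round(sq.default_round1_config(), data, design=res4_design)
    with pytest.raises(FewerSignificantFactorsError) as err:
        sq.fix_factors(sc, k_fix=3)
    assert err.value.available == len(sc.significant_mes)


def test_fix_factors_sign_rule_negative_dominant():
    """A dominant negative main effect is pinned at -1."""
    design = sq.generate_design(sq.spec_from_names(["A", "B", "C", "D"]))
    truth = sq.GroundTruth(
        ("A", "B", "C", "D"), beta0=100.0, main_effects={"A": -30.0},
        noise_cv=0.05,
    )
    data = sq.simulate_response(truth, design, 3, seed=4).responses
    config = sq.RoundConfig(
        factors=tuple(sq.Factor(n, "process", "lo", "hi") for n in "ABCD"),
        active=("A", "B", "C", "D"),
        resolution="full",
        replicates=3,
    )
    sc = sq.run_screening_round(config, data, design=design)
    config2 = sq.fix_factors(sc, k_fix=1)
    assert config2.fixed == {"A": -1}


# ---------------------------------------------------------------------------
# enumeration and optimum


def test_enumerate_single_positive_me():
    design = sq.generate_design(sq.spec_from_names(["A", "B"]))
    y = 10.0 + 3.0 * design.column("A")
    data = pd.DataFrame(
        {"run_id": design.run_ids, "replicate": 1, "response_mg_per_L": y}
    )
    fit, _ = sq.fit_design(design, data, include_tfi=False)
    opt = sq.enumerate_and_predict(fit, design.factor_names)
    assert opt.best_settings["A"] == 1
    assert len(opt.table) == 4
    # B does not matter; the tie breaks toward the lexicographically
    # smallest settings, i.e. B = -1
    assert opt.best_settings["B"] == -1


def test_enumerate_counts_and_cap(res5_design, conditional_truth):
    data = sq.simulate_response(conditional_truth, res5_design, 2, seed=1).responses
    fit, _ = sq.fit_design(res5_design, data, include_tfi=True)
    opt = sq.enumerate_and_predict(fit, res5_design.factor_names)
    assert len(opt.table) == 256
    assert opt.predicted_response == opt.table["predicted_mg_per_L"].max()
    with pytest.raises(EnumerationCapError):
        sq.enumerate_and_predict(fit, [f"X{i}" for i in range(21)])


def test_noise_free_refinement_finds_truth_argmax(res5_design, conditional_truth):
    noise_free = replace(conditional_truth, noise_cv=0.0)
    data = sq.simulate_response(noise_free, res5_design, 2, seed=0).responses
    fit, _ = sq.fit_design(res5_design, data, include_tfi=True)
    opt = sq.enumerate_and_predict(fit, res5_design.factor_names)
    best_true, value_true = conditional_truth.argmax()
    assert opt.best_settings == best_true
    assert opt.predicted_response == pytest.approx(value_true)


# ---------------------------------------------------------------------------
# leave-out validation


def _oriented_design_with_optimum(res5_design, conditional_truth):
    best, _ = conditional_truth.argmax()
    oriented = sq.orient_fraction_towards(res5_design, best)
    target = tuple(best[n] for n in oriented.factor_names)
    rows = [tuple(int(v) for v in r) for r in oriented.runs]
    return oriented, oriented.run_ids[rows.index(target)]


def test_leave_out_noise_free_prediction_equals_truth(res5_design, conditional_truth):
    noise_free = replace(conditional_truth, noise_cv=0.0)
    design, opt_run = _oriented_design_with_optimum(res5_design, conditional_truth)
    data = sq.simulate_response(noise_free, design, 2, seed=0).responses
    v = sq.leave_out_validation(design, data, opt_run)
    mu = noise_free.linear_predictor(
        design.runs[design.run_ids.index(opt_run)][None, :].astype(float),
        design.factor_names,
    )
    assert v.prediction == pytest.approx(float(mu[0]))
    assert v.still_optimal


def test_leave_out_top_producer_usually_stays_optimal(res5_design, conditional_truth):
    """Excluding the top run and refitting still ranks its settings first in
    at least 90% of simulation replicates."""
    design, opt_run = _oriented_design_with_optimum(res5_design, conditional_truth)
    wins = 0
    n_reps = 200
    for s in range(n_reps):
        data = sq.simulate_response(conditional_truth, design, 2, seed=30_000 + s).responses
        wins += sq.leave_out_validation(design, data, opt_run).still_optimal
    assert wins / n_reps >= 0.90


def test_excluding_nothing_equals_plain_fit(res5_design, conditional_truth):
    data = sq.simulate_response(conditional_truth, res5_design, 2, seed=9).responses
    plain, _ = sq.fit_design(res5_design, data, include_tfi=True)
    v = sq.leave_out_validation(res5_design, data, res5_design.run_ids[0])
    with_all = data  # excluding a run then adding it back is the identity
    refit, _ = sq.fit_design(
        res5_design, with_all[with_all["run_id"] != res5_design.run_ids[0]],
        include_tfi=True,
    )
    assert np.allclose(v.fit.coefficients, refit.coefficients)
    assert not np.allclose(v.fit.coefficients, plain.coefficients)


# ---------------------------------------------------------------------------
# perturbation analysis


def test_perturbation_single_me():
    design = sq.generate_design(sq.spec_from_names(["A", "B"]))
    y = 10.0 + 3.0 * design.column("A")
    data = pd.DataFrame(
        {"run_id": design.run_ids, "replicate": 1, "response_mg_per_L": y}
    )
    fit, _ = sq.fit_design(design, data, include_tfi=False)
    opt = sq.enumerate_and_predict(fit, design.factor_names)
    pert = sq.one_factor_perturbation(fit, opt).set_index("factor")
    assert pert.loc["A", "delta_mg_per_L"] == pytest.approx(-6.0)
    assert pert.loc["B", "delta_mg_per_L"] == pytest.approx(0.0, abs=1e-12)


def test_perturbation_deltas_never_positive(res5_design, conditional_truth):
    data = sq.simulate_response(conditional_truth, res5_design, 2, seed=13).responses
    fit, _ = sq.fit_design(res5_design, data, include_tfi=True)
    opt = sq.enumerate_and_predict(fit, res5_design.factor_names)
    pert = sq.one_factor_perturbation(fit, opt)
    assert np.all(pert["delta_mg_per_L"] <= 1e-9)


def test_perturbation_aro4_penalty_driven_by_temperature_interaction(
    res5_design, conditional_truth
):
    """Flipping ARO4 up at 20C costs both its main effect and the T:ARO4
    interaction, computed from the truth coefficients."""
    noise_free = replace(conditional_truth, noise_cv=0.0)
    data = sq.simulate_response(noise_free, res5_design, 2, seed=0).responses
    fit, _ = sq.fit_design(res5_design, data, include_tfi=True)
    opt = sq.enumerate_and_predict(fit, res5_design.factor_names)
    pert = sq.one_factor_perturbation(fit, opt).set_index("factor")
    me = conditional_truth.main_effects["ARO4"]
    t_aro4 = conditional_truth.interactions[("ARO4", "T")]
    arol_aro4 = conditional_truth.interactions[("ARO4", "AROL")]
    # at the optimum T = -1 and AROL = -1, so flipping ARO4 from -1 to +1
    # costs 2*(|me| + t_aro4 + arol_aro4)
    expected = -2 * (abs(me) + t_aro4 + arol_aro4)
    assert pert.loc["ARO4", "delta_mg_per_L"] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# interaction cell means


def test_cell_means_full_22(interpolation_case):
    design, responses = interpolation_case
    cells = sq.interaction_cell_means(design, responses, ("A", "B"))
    assert cells.means.loc[-1, -1] == 1.0
    assert cells.means.loc[1, 1] == 7.0
    assert cells.contrast == pytest.approx(0.0)
    assert cells.counts.to_numpy().sum() == 4


def test_cell_contrast_equals_fitted_2fi_exhaustive():
    """On balanced full factorials the cell-mean contrast reproduces the
    fitted interaction coefficient (k <= 4, every factor pair)."""
    rng = np.random.default_rng(17)
    for k in (2, 3, 4):
        design = sq.generate_design(
            sq.spec_from_names([f"F{i}" for i in range(k)])
        )
        y = rng.normal(100, 20, size=design.n_runs)
        data = pd.DataFrame(
            {"run_id": design.run_ids, "replicate": 1, "response_mg_per_L": y}
        )
        fit, _ = sq.fit_design(design, data, include_tfi=True)
        for i in range(k):
            for j in range(i + 1, k):
                pair = (f"F{i}", f"F{j}")
                cells = sq.interaction_cell_means(design, data, pair)
                assert cells.contrast == pytest.approx(
                    fit.coef(":".join(pair))
                )


def test_cell_means_show_t_aro4_pattern(res5_design, conditional_truth):
    """Low ARO4 expression helps at 20C but matters little at 30C."""
    noise_free = replace(conditional_truth, noise_cv=0.0)
    data = sq.simulate_response(noise_free, res5_design, 2, seed=0).responses
    cells = sq.interaction_cell_means(res5_design, data, ("T", "ARO4"))
    low_t_gain = cells.means.loc[-1, -1] - cells.means.loc[-1, 1]
    high_t_gain = cells.means.loc[1, -1] - cells.means.loc[1, 1]
    assert low_t_gain > high_t_gain
    assert low_t_gain > 0


def test_cell_means_constant_response(interpolation_case):
    design, responses = interpolation_case
    responses = responses.assign(response_mg_per_L=5.0)
    cells = sq.interaction_cell_means(design, responses, ("A", "B"))
    assert np.allclose(cells.means.to_numpy(), 5.0)
    assert cells.contrast == pytest.approx(0.0)


def test_cell_means_missing_cell_errors(interpolation_case):
    design, responses = interpolation_case
    partial = responses.iloc[:2]
    with pytest.raises(IncompleteCellsError):
        sq.interaction_cell_means(design, partial, ("A", "B"))


# ---------------------------------------------------------------------------
# end-to-end campaign


def test_campaign_single_run_recovers_argmax(truth):
    result = sq.run_campaign(truth, seed=1)
    best_true, _ = truth.argmax()
    assert result.final_settings == best_true
    assert np.all(result.perturbation["delta_mg_per_L"] <= 1e-9)
    assert result.optimum.predicted_response >= (
        result.optimum.table["predicted_mg_per_L"].max() - 1e-9
    )


def test_campaign_predicted_optimum_dominates_executed_runs(truth):
    result = sq.run_campaign(truth, seed=2)
    fit = result.refine_fit
    for i in range(result.refine_design.n_runs):
        settings = result.refine_design.settings(i)
        assert sq.predict(fit, settings) <= result.predicted_response + 1e-9
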