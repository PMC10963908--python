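"""Sequential two-round optimization campaign.

Round 1 screens all factors with a resolution IV fraction: main effects are
estimated cleanly, and significance of any confounded 2FI representative
signals that a higher-resolution follow-up is warranted. The strongest
significant main effects are then *fixed* at their favorable level, and the
remaining factors enter a resolution V fraction whose ME+2FI model is
enumerated over the whole remaining candidate space to predict the optimum.
Leave-out refits, one-factor perturbations and interaction cell means probe
the robustness and interpretation of that prediction.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import CodedDesign, alias_groups, generate_design, remove_runs
from .errors import (
    DomainError,
    EnumerationCapError,
    FewerSignificantFactorsError,
    IncompleteCellsError,
    InsufficientDataError,
    InvalidSpecError,
    UnknownFactorError,
)
from .factors import DesignSpec, Factor, pca_factors, pca_infeasible
from .model import (
    FitResult,
    fit_design,
    model_terms,
    predict,
    predict_frame,
    validate_response_table,
)
from .synthetic import GroundTruth, simulate_response

SIGNIFICANCE = 0.05
_ENUM_CAP = 20


@dataclass(frozen=True)
class RoundConfig:
    """One round of the campaign: which factors move, which are pinned."""

    factors: tuple[Factor, ...]
    active: tuple[str, ...]
    fixed: Mapping[str, int] = field(default_factory=dict)
    resolution: str = "IV"
    replicates: int = 3
    infeasible: Callable[[dict], bool] | None = None

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "active", tuple(self.active))
        object.__setattr__(self, "fixed", dict(self.fixed))
        names = {f.name for f in self.factors}
        overlap = set(self.active) & set(self.fixed)
        if overlap:
            raise InvalidSpecError(f"factors both active and fixed: {sorted(overlap)}")
        if set(self.active) | set(self.fixed) != names:
            raise InvalidSpecError("active + fixed must cover all factors")
        if any(v not in (-1, 1) for v in self.fixed.values()):
            raise InvalidSpecError("fixed levels must be coded -1/+1")

    def active_factors(self) -> tuple[Factor, ...]:
        return tuple(f for f in self.factors if f.name in self.active)

    def design_spec(self) -> DesignSpec:
        return DesignSpec(self.active_factors(), resolution_request=self.resolution)


@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of one screening round.

    ``significant_mes`` ranks significant main effects by |coefficient|;
    ``any_significant_tfi`` reports whether some confounded 2FI
    representative is significant — the design resolution decides whether
    that can be attributed to a specific interaction.
    """

    config: RoundConfig
    design: CodedDesign
    me_fit: FitResult
    tfi_fit: FitResult
    dropped_tfi_terms: tuple
    significant_mes: pd.DataFrame
    any_significant_tfi: bool


@dataclass(frozen=True)
class OptimumPrediction:
    """Ranked candidate table and its argmax."""

    best_settings: dict
    predicted_response: float
    table: pd.DataFrame


@dataclass(frozen=True)
class ValidationResult:
    """Leave-out refit: prediction for the excluded run and its rank."""

    excluded_run: str
    prediction: float
    rank: int
    still_optimal: bool
    fit: FitResult


@dataclass(frozen=True)
class InteractionCells:
    """2x2 cell means of a factor pair, with the interaction contrast."""

    pair: tuple[str, str]
    means: pd.DataFrame
    counts: pd.DataFrame
    contrast: float


def run_screening_round(
    config: RoundConfig,
    data: pd.DataFrame,
    design: CodedDesign | None = None,
) -> ScreeningResult:
    """Fit ME-only and ME+2FI models for one round and flag significance.

    ``design`` defaults to a fresh design generated from the config. Runs
    without response rows are treated as not executed (at most 25% may be
    missing); interaction representatives that the executed subset cannot
    identify are dropped from the 2FI model and recorded.
    """
    if design is None:
        design = generate_design(config.design_spec())
    validate_response_table(data, design)
    executed = set(data["run_id"])
    missing = 1.0 - len(executed & set(design.run_ids)) / design.n_runs
    if missing > 0.25:
        raise InsufficientDataError(
            f"responses missing for {missing:.0%} of runs (max 25%)"
        )
    table = alias_groups(design)
    me_fit, _ = fit_design(design, data, include_tfi=False)
    tfi_fit, dropped = fit_design(
        design, data, include_tfi=True, alias_table=table, drop_collinear=True
    )
    # Significance of each ME is judged on the ME+2FI model (its residual
    # is not inflated by unmodelled interaction signal).
    rows = []
    for term, coef, padj in zip(
        tfi_fit.terms, tfi_fit.coefficients, tfi_fit.p_adjusted
    ):
        if term.kind == "ME" and np.isfinite(padj) and padj <= SIGNIFICANCE:
            rows.append({"factor": term.label, "coefficient": coef, "p_adj": padj})
    sig = pd.DataFrame(rows, columns=["factor", "coefficient", "p_adj"])
    sig = sig.reindex(
        sig["coefficient"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
    any_tfi = any(
        t.kind == "2FI" and np.isfinite(p) and p <= SIGNIFICANCE
        for t, p in zip(tfi_fit.terms, tfi_fit.p_adjusted)
    )
    return ScreeningResult(
        config=config,
        design=design,
        me_fit=me_fit,
        tfi_fit=tfi_fit,
        dropped_tfi_terms=dropped,
        significant_mes=sig,
        any_significant_tfi=any_tfi,
    )


def fix_factors(
    screening: ScreeningResult,
    k_fix: int,
    resolution: str = "V",
    replicates: int = 2,
) -> RoundConfig:
    """Pin the ``k_fix`` strongest significant MEs at their favorable level.

    The favorable level is the sign of the coefficient (the response is
    maximized). With ``k_fix=0`` the config passes through unchanged apart
    from the next round's resolution and replication.
    """
    config = screening.config
    if k_fix < 0:
        raise DomainError("k_fix must be non-negative")
    sig = screening.significant_mes
    if len(sig) < k_fix:
        raise FewerSignificantFactorsError(len(sig))
    newly_fixed = {
        row["factor"]: 1 if row["coefficient"] > 0 else -1
        for _, row in sig.head(k_fix).iterrows()
    }
    return RoundConfig(
        factors=config.factors,
        active=tuple(n for n in config.active if n not in newly_fixed),
        fixed={**config.fixed, **newly_fixed},
        resolution=resolution,
        replicates=replicates,
        infeasible=config.infeasible,
    )


def enumerate_and_predict(
    fit: FitResult, active_factors: Sequence[str]
) -> OptimumPrediction:
    """Evaluate the fitted model on every coded combination of the actives.

    Ties in predicted response break deterministically toward the
    lexicographically smallest settings (-1 before +1).
    """
    active = list(active_factors)
    if len(active) > _ENUM_CAP:
        raise EnumerationCapError(
            f"2^{len(active)} candidates exceed the 2^{_ENUM_CAP} cap"
        )
    grid = pd.DataFrame(
        list(itertools.product((-1, 1), repeat=len(active))), columns=active
    )
    preds = predict_frame(fit, grid)
    order = sorted(
        range(len(grid)),
        key=lambda i: (-preds[i], tuple(grid.iloc[i])),
    )
    table = grid.iloc[order].copy()
    table["predicted_mg_per_L"] = preds[order]
    table = table.reset_index(drop=True)
    best = {n: int(table.iloc[0][n]) for n in active}
    return OptimumPrediction(
        best_settings=best,
        predicted_response=float(table.iloc[0]["predicted_mg_per_L"]),
        table=table,
    )


def leave_out_validation(
    design: CodedDesign,
    data: pd.DataFrame,
    run_to_exclude: str,
    include_tfi: bool = True,
) -> ValidationResult:
    """Refit without one run and ask where its settings rank.

    Guards the optimum prediction against being an artifact of the
    top-producing experiment's own data: if the excluded settings still rank
    first in the refit's candidate table, the prediction does not hinge on
    that run.
    """
    if run_to_exclude not in design.run_ids:
        raise UnknownFactorError(f"run {run_to_exclude!r} not in design")
    remaining = data[data["run_id"] != run_to_exclude]
    if len(remaining) == len(data):
        raise InsufficientDataError(
            f"no responses for run {run_to_exclude!r} to exclude"
        )
    fit, _ = fit_design(design, remaining, include_tfi=include_tfi,
                        drop_collinear=True)
    settings = design.settings_for(run_to_exclude)
    prediction = predict(fit, settings)
    optimum = enumerate_and_predict(fit, design.factor_names)
    target = tuple(settings[n] for n in design.factor_names)
    ranked = optimum.table[list(design.factor_names)].to_numpy()
    rank = 1 + int(np.nonzero((ranked == target).all(axis=1))[0][0])
    return ValidationResult(
        excluded_run=run_to_exclude,
        prediction=prediction,
        rank=rank,
        still_optimal=rank == 1,
        fit=fit,
    )


def one_factor_perturbation(
    fit: FitResult, optimum: OptimumPrediction
) -> pd.DataFrame:
    """Flip each factor of the optimum to its sub-optimal level, one at a time.

    Because the optimum is the argmax of the same fitted model, every delta
    is <= 0 (a zero delta means the factor does not matter at the optimum).
    """
    rows = []
    for name, level in optimum.best_settings.items():
        flipped = dict(optimum.best_settings)
        flipped[name] = -level
        pred = predict(fit, flipped)
        rows.append(
            {
                "factor": name,
                "flipped_level": -level,
                "predicted_mg_per_L": pred,
                "delta_mg_per_L": pred - optimum.predicted_response,
            }
        )
    return pd.DataFrame(rows)


def interaction_cell_means(
    design: CodedDesign, data: pd.DataFrame, factor_pair: Sequence[str]
) -> InteractionCells:
    """Mean response in the four cells of a factor pair.

    The interaction contrast (mean[++] + mean[--] - mean[+-] - mean[-+]) / 4
    equals the fitted 2FI coefficient on a balanced orthogonal design.
    """
    a, b = factor_pair
    validate_response_table(data, design)
    settings = design.to_frame()[[a, b]]
    merged = data.merge(
        settings, left_on="run_id", right_index=True, how="left"
    )
    grouped = merged.groupby([a, b])["response_mg_per_L"]
    means = grouped.mean()
    counts = grouped.size()
    cells = list(itertools.product((-1, 1), repeat=2))
    missing = [c for c in cells if c not in means.index]
    if missing:
        raise IncompleteCellsError(missing)
    mean_tbl = means.unstack(b)
    count_tbl = counts.unstack(b).astype(int)
    contrast = (
        means[(1, 1)] + means[(-1, -1)] - means[(1, -1)] - means[(-1, 1)]
    ) / 4.0
    return InteractionCells(
        pair=(a, b), means=mean_tbl, counts=count_tbl, contrast=float(contrast)
    )


# ---------------------------------------------------------------------------
# end-to-end campaign on a synthetic truth


@dataclass(frozen=True)
class CampaignResult:
    """Everything the two-round synthetic campaign produced."""

    screening: ScreeningResult
    refine_config: RoundConfig
    refine_design: CodedDesign
    refine_fit: FitResult
    optimum: OptimumPrediction
    perturbation: pd.DataFrame
    final_settings: dict
    predicted_response: float


def default_round1_config(replicates: int = 3) -> RoundConfig:
    """All eleven study factors active, resolution IV, triplicates, with the
    two unconstructable genotypes marked infeasible."""
    factors = pca_factors()
    return RoundConfig(
        factors=factors,
        active=tuple(f.name for f in factors),
        fixed={},
        resolution="IV",
        replicates=replicates,
        infeasible=pca_infeasible,
    )


def run_campaign(
    truth: GroundTruth,
    seed: int,
    config: RoundConfig | None = None,
    k_fix: int = 3,
    refine_replicates: int = 2,
) -> CampaignResult:
    """Screen, fix, refine and predict the optimum on a synthetic truth.

    Round 1 generates the screening design (with the genetic factors, when
    there are exactly four of them, assigned columns that project onto a
    full strain factorial), drops infeasible runs rather than imputing them,
    simulates replicate titres, and screens. The ``k_fix`` strongest
    significant MEs are fixed favorably; round 2 refines the remaining
    factors at resolution V and enumerates the whole candidate space.
    """
    from .design import assign_columns  # local to avoid cycle at import time

    if config is None:
        config = default_round1_config()
    seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    spec = config.design_spec()
    design = generate_design(spec)
    genetic = [f.name for f in config.active_factors() if f.category == "genetic"]
    if len(genetic) == 4:
        design, _ = assign_columns(spec, design, genetic)
    if config.infeasible is not None:
        executed, _ = remove_runs(design, config.infeasible)
    else:
        executed = design
    data1 = simulate_response(
        truth, executed, config.replicates, int(seeds[0])
    ).responses
    screening = run_screening_round(config, data1, design=design)
    config2 = fix_factors(
        screening, k_fix, resolution="V", replicates=refine_replicates
    )
    truth2 = truth.conditional(config2.fixed)
    design2 = generate_design(config2.design_spec())
    data2 = simulate_response(
        truth2, design2, config2.replicates, int(seeds[1])
    ).responses
    fit2, _ = fit_design(design2, data2, include_tfi=True)
    optimum = enumerate_and_predict(fit2, design2.factor_names)
    perturbation = one_factor_perturbation(fit2, optimum)
    final = {**config2.fixed, **optimum.best_settings}
    return CampaignResult(
        screening=screening,
        refine_config=config2,
        refine_design=design2,
        refine_fit=fit2,
        optimum=optimum,
        perturbation=perturbation,
        final_settings=final,
        predicted_response=optimum.predicted_response,
    )
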