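"""Effect models: OLS fits of intercept + MEs (+ 2FI representatives).

The response (a titre in mg/L) is modelled as

    y = b0 + sum_i ME_i * F_i + sum_{i<j} 2FI_ij * F_i * F_j + e

with F in {-1, +1}. On a fractional design only one term per alias class may
enter; :func:`model_terms` picks the lexicographically smallest pair of each
interaction-only alias class as its representative. Fitting is delegated to
statsmodels OLS (orthogonal-decomposition least squares via pseudo-inverse);
rank is decided at 1e-10 times the largest singular value, and rank-deficient
matrices are rejected before fitting, naming the dependent columns.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import AliasTable, CodedDesign, alias_groups
from .errors import (
    DomainError,
    IncompleteSettingsError,
    NotRegularError,
    ReferentialError,
    SchemaError,
    SingularModelError,
    UndefinedMetricError,
)

RESPONSE_COLUMNS = ("run_id", "replicate", "response_mg_per_L")

_RANK_TOL = 1e-10


@dataclass(frozen=True)
class ModelTerm:
    """Intercept (no factors), main effect (one) or 2FI (two factors)."""

    factors: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        if len(self.factors) > 2:
            raise DomainError("terms beyond two-factor interactions unsupported")
        if len(set(self.factors)) != len(self.factors):
            raise DomainError("repeated factor in a term")

    @classmethod
    def intercept(cls) -> "ModelTerm":
        return cls(())

    @classmethod
    def main(cls, name: str) -> "ModelTerm":
        return cls((name,))

    @classmethod
    def interaction(cls, a: str, b: str) -> "ModelTerm":
        return cls(tuple(sorted((a, b))))

    @property
    def kind(self) -> str:
        return ("intercept", "ME", "2FI")[len(self.factors)]

    @property
    def label(self) -> str:
        return ":".join(self.factors) if self.factors else "Intercept"


def model_terms(
    design: CodedDesign,
    include_tfi: bool = False,
    alias_table: AliasTable | None = None,
) -> list[ModelTerm]:
    """Intercept + all MEs, optionally + one 2FI per interaction alias class."""
    terms = [ModelTerm.intercept()]
    terms += [ModelTerm.main(n) for n in design.factor_names]
    if include_tfi:
        table = alias_table if alias_table is not None else alias_groups(design)
        terms += [ModelTerm.interaction(*pair) for pair in table.tfi_representatives()]
    return terms


@dataclass(frozen=True)
class FitResult:
    """Coefficients and inference for one OLS fit.

    ``p_adjusted`` is Bonferroni over the m non-intercept terms (the
    intercept is not part of the tested family and carries NaN there).
    """

    terms: tuple[ModelTerm, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    p_adjusted: np.ndarray
    adj_r_squared: float
    r_squared: float
    mae: float
    n_obs: int
    n_terms: int

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.terms)

    def coef(self, term: "ModelTerm | str") -> float:
        label = term.label if isinstance(term, ModelTerm) else term
        return float(self.coefficients[self.labels.index(label)])

    def summary_frame(self) -> pd.DataFrame:
        def stars(p):
            if not np.isfinite(p):
                return ""
            return "***" if p <= 0.001 else "**" if p <= 0.01 else "*" if p <= 0.05 else ""

        return pd.DataFrame(
            {
                "term": self.labels,
                "estimate": self.coefficients,
                "se": self.standard_errors,
                "t": self.t_statistics,
                "p": self.p_values,
                "p_adj": self.p_adjusted,
                "stars": [stars(p) for p in self.p_adjusted],
            }
        )


def validate_response_table(
    responses: pd.DataFrame, design: CodedDesign | None = None
) -> pd.DataFrame:
    """Check the (run_id, replicate, response_mg_per_L) contract."""
    missing = set(RESPONSE_COLUMNS) - set(responses.columns)
    if missing:
        raise SchemaError(f"response table lacks columns {sorted(missing)}")
    values = responses["response_mg_per_L"].to_numpy(dtype=float)
    if np.any(values < 0):
        bad = responses.loc[values < 0, "run_id"].iloc[0]
        raise DomainError(f"negative titre for run {bad!r}")
    if design is not None:
        orphans = set(responses["run_id"]) - set(design.run_ids)
        if orphans:
            raise ReferentialError(
                f"response run_ids absent from design: {sorted(orphans)}"
            )
    return responses


def _term_columns(design: CodedDesign, terms: Sequence[ModelTerm]) -> np.ndarray:
    cols = []
    for t in terms:
        if not t.factors:
            cols.append(np.ones(design.n_runs))
        else:
            cols.append(design.effect_column(t.factors).astype(float))
    return np.column_stack(cols)


def _reject_duplicate_alias_classes(design, terms, run_cols):
    """Raise before fitting if two terms share an alias class on the design."""
    for (i, a), (j, b) in itertools.combinations(enumerate(terms), 2):
        ca, cb = run_cols[:, i], run_cols[:, j]
        if np.array_equal(ca, cb) or np.array_equal(ca, -cb):
            raise SingularModelError(
                f"terms {a.label} and {b.label} are aliased on this design "
                "(identical columns up to sign)",
                columns=(a.label, b.label),
            )


def build_model_matrix(
    design: CodedDesign,
    terms: Sequence[ModelTerm],
    responses: pd.DataFrame,
):
    """Replicate-level model matrix and aligned response vector.

    Every response row becomes one observation; its model-matrix row is the
    term columns evaluated at that run's coded settings.
    """
    responses = validate_response_table(responses, design)
    terms = list(terms)
    run_cols = _term_columns(design, terms)
    _reject_duplicate_alias_classes(design, terms, run_cols)
    row_of = {rid: i for i, rid in enumerate(design.run_ids)}
    rows = responses["run_id"].map(row_of).to_numpy()
    X = run_cols[rows]
    y = responses["response_mg_per_L"].to_numpy(dtype=float)
    return X, y


def _dependent_columns(X: np.ndarray, labels: Sequence[str]) -> list[str]:
    """Labels of columns that do not increase the rank (greedy, in order)."""
    dependent = []
    kept = np.empty((X.shape[0], 0))
    rank = 0
    for j in range(X.shape[1]):
        trial = np.column_stack([kept, X[:, j]])
        s = np.linalg.svd(trial, compute_uv=False)
        r = int(np.sum(s > _RANK_TOL * s[0]))
        if r > rank:
            kept, rank = trial, r
        else:
            dependent.append(labels[j])
    return dependent


def fit_ols(
    X: np.ndarray, y: np.ndarray, terms: Sequence[ModelTerm]
) -> FitResult:
    """Ordinary least squares with t-test inference and Bonferroni control."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    terms = tuple(terms)
    n, p = X.shape
    if n < p:
        raise SingularModelError(f"{n} observations cannot identify {p} terms")
    svals = np.linalg.svd(X, compute_uv=False)
    if np.sum(svals > _RANK_TOL * svals[0]) < p:
        deps = _dependent_columns(X, [t.label for t in terms])
        raise SingularModelError(
            f"model matrix is rank deficient; dependent columns: {deps}",
            columns=deps,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-residual fits
        res = sm.OLS(y, X).fit()
    fitted = X @ res.params
    m = sum(1 for t in terms if t.factors)
    p_adj = np.full(p, np.nan)
    tested = [i for i, t in enumerate(terms) if t.factors]
    if tested:
        pvals = np.asarray(res.pvalues, dtype=float)[tested]
        finite = np.isfinite(pvals)
        adj = np.where(finite, np.minimum(1.0, m * pvals), pvals)
        p_adj[tested] = adj
    mae = float(np.mean(np.abs(y - fitted)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = np.nan if ss_tot == 0 else 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot
    try:
        adj_r2, _ = fit_metrics(y, fitted, m)
    except (UndefinedMetricError, DomainError):
        # constant response or saturated model: adj R^2 undefined
        adj_r2 = np.nan
    return FitResult(
        terms=terms,
        coefficients=np.asarray(res.params, dtype=float),
        standard_errors=np.asarray(res.bse, dtype=float),
        t_statistics=np.asarray(res.tvalues, dtype=float),
        p_values=np.asarray(res.pvalues, dtype=float),
        p_adjusted=p_adj,
        adj_r_squared=float(adj_r2),
        r_squared=float(r2),
        mae=float(mae),
        n_obs=n,
        n_terms=p,
    )


def fit_design(
    design: CodedDesign,
    responses: pd.DataFrame,
    include_tfi: bool = False,
    alias_table: AliasTable | None = None,
    drop_collinear: bool = False,
):
    """Build terms + matrix for ``design`` and fit.

    With ``drop_collinear`` interaction representatives that break full rank
    on the observed runs (after run removal fewer alias classes may be
    identifiable) are dropped greedily in term order; the dropped terms are
    returned alongside the fit. Intercept and MEs are never dropped.

    Returns ``(fit, dropped_terms)``.
    """
    terms = model_terms(design, include_tfi, alias_table)
    observed = set(responses["run_id"])
    keep_rows = [i for i, rid in enumerate(design.run_ids) if rid in observed]
    exec_design = CodedDesign(
        design.runs[keep_rows],
        design.factor_names,
        generators=(),
        run_ids=tuple(design.run_ids[i] for i in keep_rows),
    )
    dropped: list[ModelTerm] = []
    if drop_collinear:
        run_cols = _term_columns(exec_design, terms)
        kept_idx: list[int] = []
        kept = np.empty((run_cols.shape[0], 0))
        rank = 0
        for j, t in enumerate(terms):
            trial = np.column_stack([kept, run_cols[:, j]])
            s = np.linalg.svd(trial, compute_uv=False)
            r = int(np.sum(s > _RANK_TOL * s[0]))
            if r > rank:
                kept, rank = trial, r
                kept_idx.append(j)
            elif t.kind == "2FI":
                dropped.append(t)
            else:
                kept_idx.append(j)  # keep MEs; fit_ols will raise if singular
        terms = [terms[j] for j in kept_idx]
    X, y = build_model_matrix(exec_design, terms, responses)
    return fit_ols(X, y, terms), tuple(dropped)


def bonferroni(p_values, m: int):
    """Bonferroni adjustment: min(1, m * p), elementwise."""
    p = np.asarray(p_values, dtype=float)
    if m < 1 or int(m) != m:
        raise DomainError("m must be a positive integer")
    if np.any((p < 0) | (p > 1)):
        raise DomainError("p-values must lie in [0, 1]")
    out = np.minimum(1.0, m * p)
    return float(out) if np.isscalar(p_values) else out


def fit_metrics(observed, predicted, n_terms: int):
    """(Adjusted R^2, MAE) of predictions against observations.

    ``n_terms`` counts the non-intercept model terms; Adj R^2 applies the
    usual (n-1)/(n-n_terms-1) penalty.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise DomainError("observed and predicted must have equal length")
    n = obs.size
    if n <= n_terms + 1:
        raise DomainError("need more observations than model terms")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise UndefinedMetricError("zero response variance: R^2 undefined")
    ss_res = np.sum((obs - pred) ** 2)
    r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_terms - 1)
    mae = float(np.mean(np.abs(obs - pred)))
    return float(adj), mae


def predict(fit: FitResult, settings: Mapping[str, float]) -> float:
    """Predicted response at a coded level assignment.

    Every factor appearing in the fitted terms must be supplied; values off
    the +/-1 grid are accepted as interpolation but flagged with a warning.
    """
    needed = {f for t in fit.terms for f in t.factors}
    missing = needed - set(settings)
    if missing:
        raise IncompleteSettingsError(f"missing factors: {sorted(missing)}")
    off_grid = [f for f in needed if settings[f] not in (-1, 1)]
    if off_grid:
        warnings.warn(
            f"interpolating at non-coded levels for {sorted(off_grid)}",
            stacklevel=2,
        )
    total = 0.0
    for coef, term in zip(fit.coefficients, fit.terms):
        val = 1.0
        for f in term.factors:
            val *= settings[f]
        total += coef * val
    return float(total)


def predict_frame(fit: FitResult, settings: pd.DataFrame) -> np.ndarray:
    """Vectorized :func:`predict` over the rows of a coded settings frame."""
    needed = {f for t in fit.terms for f in t.factors}
    missing = needed - set(settings.columns)
    if missing:
        raise IncompleteSettingsError(f"missing factors: {sorted(missing)}")
    out = np.zeros(len(settings))
    for coef, term in zip(fit.coefficients, fit.terms):
        col = np.ones(len(settings))
        for f in term.factors:
            col = col * settings[f].to_numpy(dtype=float)
        out += coef * col
    return out
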