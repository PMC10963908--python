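"""Synthetic ground truths and noisy replicate datasets.

The generator emulates the statistical structure of a combinatorial
strain/media/process titre study: a sparse linear ground truth over eleven
two-level factors whose noiseless responses span roughly two orders of
magnitude, multiplicative log-normal replicate noise (titres are positive
and replicate spread scales with the mean), and truncation at a floor so no
simulated titre is negative. Every pipeline stage can thus be exercised,
and its parameter recovery quantified, without any external data.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .design import CodedDesign, alias_groups
from .errors import DomainError, EnumerationCapError, MismatchError, SingularModelError
from .factors import pca_factors
from .model import build_model_matrix, fit_ols, model_terms

NOISE_MODELS = ("lognormal", "gaussian")


@dataclass(frozen=True)
class GroundTruth:
    """Hidden coefficients of a simulated titre response.

    mean(x) = beta0 + sum_i me[i] x_i + sum_{i<j} tfi[i,j] x_i x_j, in mg/L.
    Replicate noise is multiplicative log-normal with coefficient of
    variation ``noise_cv`` (mean-one, so the linear predictor is the
    expectation), or additive Gaussian with sd = noise_cv * mean when
    ``noise_model="gaussian"``. Simulated responses are truncated below at
    ``floor``.
    """

    factor_names: tuple[str, ...]
    beta0: float
    main_effects: Mapping[str, float] = field(default_factory=dict)
    interactions: Mapping[tuple[str, str], float] = field(default_factory=dict)
    noise_cv: float = 0.15
    floor: float = 0.0
    noise_model: str = "lognormal"
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "factor_names", tuple(self.factor_names))
        object.__setattr__(self, "main_effects", dict(self.main_effects))
        object.__setattr__(
            self,
            "interactions",
            {tuple(sorted(k)): v for k, v in dict(self.interactions).items()},
        )
        declared = set(self.factor_names)
        undeclared = set(self.main_effects) - declared
        for pair in self.interactions:
            undeclared |= set(pair) - declared
        if undeclared:
            raise DomainError(
                f"coefficients reference undeclared factors {sorted(undeclared)}"
            )
        if self.noise_cv < 0:
            raise DomainError("noise_cv must be non-negative")
        if self.floor < 0:
            raise DomainError("floor must be non-negative")
        if self.noise_model not in NOISE_MODELS:
            raise DomainError(f"noise_model must be one of {NOISE_MODELS}")

    # -- evaluation ---------------------------------------------------------

    def linear_predictor(self, levels: np.ndarray, names=None) -> np.ndarray:
        """Mean response at coded rows ``levels`` (columns = ``names``)."""
        names = tuple(names) if names is not None else self.factor_names
        levels = np.atleast_2d(np.asarray(levels, dtype=float))
        col = {n: levels[:, i] for i, n in enumerate(names)}
        mu = np.full(levels.shape[0], float(self.beta0))
        for n, coef in self.main_effects.items():
            mu += coef * col[n]
        for (a, b), coef in self.interactions.items():
            mu += coef * col[a] * col[b]
        return mu

    def noiseless_response(self, levels, names=None) -> np.ndarray:
        """Linear predictor truncated below at the floor."""
        return np.maximum(self.linear_predictor(levels, names), self.floor)

    def response_range(self):
        """(min, max, argmin, argmax) of the noiseless response over 2^k."""
        k = len(self.factor_names)
        if k > 20:
            raise EnumerationCapError(f"2^{k} exceeds the enumeration cap")
        grid = np.array(
            list(itertools.product((-1, 1), repeat=k)), dtype=np.int8
        )
        y = self.noiseless_response(grid)
        lo, hi = int(np.argmin(y)), int(np.argmax(y))
        to_settings = lambda row: dict(
            zip(self.factor_names, (int(v) for v in row))
        )
        return float(y[lo]), float(y[hi]), to_settings(grid[lo]), to_settings(grid[hi])

    def argmax(self):
        """Settings maximizing the noiseless response (ties: first in
        lexicographic -1-before-+1 order)."""
        _, hi, _, best = self.response_range()
        return best, hi

    def conditional(self, fixed: Mapping[str, int]) -> "GroundTruth":
        """Truth over the remaining factors with ``fixed`` levels absorbed.

        Fixed MEs and fixed-fixed interactions fold into the intercept;
        active-fixed interactions fold into the active factor's ME.
        """
        for name, level in fixed.items():
            if name not in self.factor_names:
                raise DomainError(f"unknown factor {name!r}")
            if level not in (-1, 1):
                raise DomainError("fixed levels must be coded -1/+1")
        active = tuple(n for n in self.factor_names if n not in fixed)
        beta0 = self.beta0 + sum(
            self.main_effects.get(n, 0.0) * fixed[n] for n in fixed
        )
        me = {n: self.main_effects.get(n, 0.0) for n in active}
        tfi = {}
        for (a, b), coef in self.interactions.items():
            in_fixed = (a in fixed, b in fixed)
            if all(in_fixed):
                beta0 += coef * fixed[a] * fixed[b]
            elif in_fixed[0]:
                me[b] = me.get(b, 0.0) + coef * fixed[a]
            elif in_fixed[1]:
                me[a] = me.get(a, 0.0) + coef * fixed[b]
            else:
                tfi[(a, b)] = coef
        me = {n: v for n, v in me.items() if v != 0.0}
        return replace(
            self,
            factor_names=active,
            beta0=beta0,
            main_effects=me,
            interactions=tfi,
        )


@dataclass(frozen=True)
class SyntheticDataset:
    """A simulated response table with its provenance."""

    design: CodedDesign
    responses: pd.DataFrame
    truth: GroundTruth
    seed: int
    replicates: int


def default_pca_truth(seed: int = 0) -> GroundTruth:
    """The default ground truth of the synthetic p-coumaric-acid study.

    Sign structure mirrors the study narrative: strong positive main effect
    of PAL-C4H expression, strong negative effect of buffering, positive Phe
    supplementation, moderate negative temperature and positive agitation
    effects, a negative ARO4 effect, and positive T:ARO4, rpm:OD and
    AROL:ARO4 interactions. The media and remaining genetic factors carry
    smaller main effects plus synergies with the dominant factors (nitrogen
    source and downstream-gene expression matter more in high-flux strains;
    Glu and a higher inoculum pay off when Phe is supplemented), so that
    every factor left active after fixing the top three still has a decisive
    net effect at the optimum. Magnitudes are calibrated so the noiseless
    response spans about two orders of magnitude (~2 to ~450 mg/L) over the
    full 2^11 space while staying positive everywhere, keeping the truth
    exactly linear on the design region. The truth itself is deterministic;
    ``seed`` is recorded as provenance for downstream simulation.
    """
    names = tuple(f.name for f in pca_factors())
    return GroundTruth(
        factor_names=names,
        beta0=147.0,
        main_effects={
            "PAL-C4H": 35.0,
            "pH": -25.0,
            "Phe": 18.0,
            "T": -16.0,
            "rpm": 16.0,
            "ARO4": -16.0,
            "AROL": -14.0,
            "OD": 12.0,
            "N": -12.0,
            "Glu": 12.0,
            "ARO7": 12.0,
        },
        interactions={
            ("T", "ARO4"): 9.0,
            ("OD", "rpm"): 9.0,
            ("ARO4", "AROL"): 9.0,
            ("N", "PAL-C4H"): -18.0,
            ("Glu", "Phe"): 18.0,
            ("ARO7", "PAL-C4H"): 18.0,
            ("OD", "Phe"): 8.0,
            ("T", "PAL-C4H"): -8.0,
            ("rpm", "PAL-C4H"): 8.0,
            ("AROL", "Phe"): -8.0,
        },
        seed=seed,
    )


def zero_effect_truth(beta0: float = 147.0, seed: int = 0) -> GroundTruth:
    """A null truth (intercept only) for type-I-error studies."""
    names = tuple(f.name for f in pca_factors())
    return GroundTruth(factor_names=names, beta0=beta0, seed=seed)


def simulate_response(
    truth: GroundTruth,
    design: CodedDesign,
    replicates: int,
    seed: int,
) -> SyntheticDataset:
    """Draw ``replicates`` noisy observations per run of ``design``.

    Each observation has expectation equal to the truth's linear predictor
    at the run's settings (log-normal noise is mean-one), and is truncated
    below at the truth's floor. Bit-reproducible for a given seed.
    """
    if replicates < 1:
        raise DomainError("replicates must be >= 1")
    if set(design.factor_names) != set(truth.factor_names):
        raise MismatchError(
            f"design factors {sorted(design.factor_names)} != "
            f"truth factors {sorted(truth.factor_names)}"
        )
    idx = [design.factor_names.index(n) for n in truth.factor_names]
    mu = truth.linear_predictor(design.runs[:, idx].astype(float))
    mu_rep = np.repeat(mu, replicates)
    rng = np.random.default_rng(seed)
    if truth.noise_cv == 0:
        y = mu_rep.copy()
    elif truth.noise_model == "lognormal":
        sigma2 = np.log1p(truth.noise_cv**2)
        eps = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=mu_rep.size)
        y = np.where(mu_rep > 0, mu_rep * eps, mu_rep)
    else:
        y = mu_rep + rng.normal(0.0, truth.noise_cv * np.abs(mu_rep))
    y = np.maximum(y, truth.floor)
    table = pd.DataFrame(
        {
            "run_id": np.repeat(design.run_ids, replicates),
            "replicate": np.tile(np.arange(1, replicates + 1), design.n_runs),
            "response_mg_per_L": y,
        }
    )
    return SyntheticDataset(design, table, truth, seed, replicates)


# ---------------------------------------------------------------------------
# recovery studies


def _true_coefficients(truth: GroundTruth, design: CodedDesign, terms):
    """Expected value of each fitted coefficient under the truth.

    On a regular fraction a term estimates the sum of the truth
    coefficients over its whole alias class (all aliases enter with sign +1
    on the principal fraction built here), so the reference value per term
    is that aliased sum, not just the term's own coefficient.
    """
    table = alias_groups(design)
    true = []
    for t in terms:
        if not t.factors:
            true.append(truth.beta0)
            continue
        group = table.group_of(t.factors)
        total = 0.0
        for effect in group:
            if len(effect) == 1:
                total += truth.main_effects.get(effect[0], 0.0)
            else:
                total += truth.interactions.get(tuple(sorted(effect)), 0.0)
        true.append(total)
    return np.array(true)


def parameter_recovery_report(
    truth: GroundTruth,
    design: CodedDesign,
    replicates: int,
    n_sims: int,
    seed: int,
    include_tfi: bool = True,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Bias, RMSE and CI coverage per coefficient over simulate-fit cycles.

    A truth effect that is aliased with another truth effect of the model is
    not separately estimable; the reference value of each term is therefore
    the aliased sum of truth coefficients (see ``_true_coefficients``), which
    reduces to the plain coefficient whenever the design resolution leaves
    the term unconfounded.
    """
    terms = model_terms(design, include_tfi)
    true = _true_coefficients(truth, design, terms)
    n, p = design.n_runs * replicates, len(terms)
    if n <= p:
        raise SingularModelError(f"{n} observations cannot identify {p} terms")
    seeds = np.random.SeedSequence(seed).generate_state(n_sims) % (2**31)
    df = n - p
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df)
    estimates = np.empty((n_sims, p))
    covered = np.zeros((n_sims, p), dtype=bool)
    for s in range(n_sims):
        data = simulate_response(truth, design, replicates, int(seeds[s]))
        Xs, ys = build_model_matrix(design, terms, data.responses)
        fit = fit_ols(Xs, ys, terms)
        estimates[s] = fit.coefficients
        half = tcrit * fit.standard_errors
        covered[s] = np.abs(fit.coefficients - true) <= half
    bias = estimates.mean(axis=0) - true
    rmse = np.sqrt(np.mean((estimates - true) ** 2, axis=0))
    if n_sims > 1:
        mc_se = estimates.std(axis=0, ddof=1) / np.sqrt(n_sims)
    else:
        mc_se = np.zeros(p)
    return pd.DataFrame(
        {
            "term": [t.label for t in terms],
            "true": true,
            "mean_estimate": estimates.mean(axis=0),
            "bias": bias,
            "mc_se": mc_se,
            "rmse": rmse,
            "coverage": covered.mean(axis=0),
        }
    )


def familywise_error_rate(
    truth: GroundTruth,
    design: CodedDesign,
    replicates: int,
    n_sims: int,
    seed: int,
    alpha: float = 0.05,
    include_tfi: bool = True,
) -> float:
    """Fraction of simulations flagging any term at Bonferroni level alpha.

    With a zero-effect truth this estimates the family-wise type-I error of
    the screening procedure.
    """
    terms = model_terms(design, include_tfi)
    seeds = np.random.SeedSequence(seed).generate_state(n_sims) % (2**31)
    hits = 0
    for s in range(n_sims):
        data = simulate_response(truth, design, replicates, int(seeds[s]))
        X, y = build_model_matrix(design, terms, data.responses)
        fit = fit_ols(X, y, terms)
        tested = fit.p_adjusted[~np.isnan(fit.p_adjusted)]
        if np.any(tested <= alpha):
            hits += 1
    return hits / n_sims
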