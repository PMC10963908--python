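"""Regular two-level factorial and fractional-factorial designs.

A regular 2^(k-p) fraction keeps the 2^(k-p) runs of the full 2^k factorial
on which p generator words evaluate to a constant sign. The closure of the
generators under elementwise products is the defining contrast subgroup; its
minimum word length is the design's *resolution*, which governs what can be
estimated: resolution IV keeps main effects (MEs) clear of two-factor
interactions (2FIs) but confounds 2FIs with each other, resolution V leaves
both MEs and 2FIs clear. Among fractions of equal resolution the generator
search below returns the *minimum aberration* one (fewest shortest words,
ties broken by the next length, then by lexicographic candidate order).

Factor subsets of a word are represented as Python int bitmasks over column
indices, so word products are XORs and word length is a popcount.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    BudgetExceededError,
    EmptyDesignError,
    InfeasibleAssignmentError,
    InfeasibleDesignError,
    InvalidSpecError,
    NotRegularError,
    UnknownFactorError,
)
from .factors import DesignSpec

#: Numeric minimum word length demanded by each resolution request.
RESOLUTION_MIN_LENGTH = {"III": 3, "IV": 4, "V": 5}

#: Distinguished resolution of a full factorial (no defining words).
UNBOUNDED = math.inf

_SEARCH_NODE_BUDGET = 5_000_000


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DefiningWord:
    """A product of factor columns that is constant (= sign) over a fraction."""

    members: frozenset
    sign: int = 1

    def __post_init__(self):
        if not self.members:
            raise InvalidSpecError("a defining word needs at least one member")
        if self.sign not in (-1, 1):
            raise InvalidSpecError("word sign must be -1 or +1")

    @property
    def length(self) -> int:
        return len(self.members)

    def mask(self) -> int:
        m = 0
        for i in self.members:
            m |= 1 << i
        return m

    def label(self, names: Sequence[str]) -> str:
        body = ":".join(names[i] for i in sorted(self.members))
        return body if self.sign == 1 else "-" + body


def _mask_to_word(mask: int, sign: int = 1) -> DefiningWord:
    return DefiningWord(frozenset(_bits(mask)), sign)


def _bits(mask: int):
    i = 0
    while mask:
        if mask & 1:
            yield i
        mask >>= 1
        i += 1


@dataclass(frozen=True)
class CodedDesign:
    """A run x factor matrix over {-1, +1} with generator provenance.

    ``runs[i, j]`` is the coded level of factor ``factor_names[j]`` in run
    ``run_ids[i]``. ``generators`` hold the p defining words used to fold the
    fraction; empty for full factorials and for designs whose provenance is
    unknown (e.g. read from a bare CSV), in which case the defining subgroup
    is recovered from the matrix itself.
    """

    runs: np.ndarray
    factor_names: tuple[str, ...]
    generators: tuple[DefiningWord, ...] = ()
    run_ids: tuple[str, ...] = ()

    def __post_init__(self):
        runs = np.asarray(self.runs, dtype=np.int8)
        object.__setattr__(self, "runs", runs)
        object.__setattr__(self, "factor_names", tuple(self.factor_names))
        object.__setattr__(self, "generators", tuple(self.generators))
        if runs.ndim != 2:
            raise InvalidSpecError("runs must be a 2-D matrix")
        n, k = runs.shape
        if k != len(self.factor_names):
            raise InvalidSpecError("factor_names length != number of columns")
        if len(set(self.factor_names)) != k:
            raise InvalidSpecError("duplicate factor names")
        if not np.all(np.isin(runs, (-1, 1))):
            raise InvalidSpecError("design entries must be -1 or +1")
        ids = self.run_ids or tuple(f"r{i + 1:02d}" for i in range(n))
        if len(ids) != n or len(set(ids)) != n:
            raise InvalidSpecError("run_ids must be unique, one per run")
        object.__setattr__(self, "run_ids", tuple(ids))
        for w in self.generators:
            col = runs[:, sorted(w.members)].prod(axis=1)
            if not np.all(col == w.sign):
                raise InvalidSpecError(
                    f"generator {w.label(self.factor_names)} does not "
                    "evaluate to its sign on every run"
                )

    # -- basic accessors ----------------------------------------------------

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    @property
    def n_factors(self) -> int:
        return self.runs.shape[1]

    def column_index(self, name: str) -> int:
        try:
            return self.factor_names.index(name)
        except ValueError:
            raise UnknownFactorError(
                f"factor {name!r} not in design {self.factor_names}"
            ) from None

    def column(self, name: str) -> np.ndarray:
        return self.runs[:, self.column_index(name)]

    def effect_column(self, effect: Sequence[str]) -> np.ndarray:
        """Model-matrix column of an ME (one name) or 2FI (two names)."""
        idx = [self.column_index(n) for n in effect]
        return self.runs[:, idx].prod(axis=1)

    def settings(self, i: int) -> dict:
        return dict(zip(self.factor_names, (int(v) for v in self.runs[i])))

    def settings_for(self, run_id: str) -> dict:
        return self.settings(self.run_ids.index(run_id))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.runs, index=list(self.run_ids), columns=list(self.factor_names)
        ).rename_axis("run_id")

    @property
    def resolution(self):
        """Minimum defining-word length; UNBOUNDED for a full factorial."""
        words = defining_subgroup(self)
        if not words:
            return UNBOUNDED
        return min(w.length for w in words)


@dataclass(frozen=True)
class AliasTable:
    """Partition of all MEs and 2FIs into confounded groups.

    Each effect is a tuple of factor names (length 1 = ME, 2 = 2FI); effects
    in one group have identical model-matrix columns up to sign on the
    fraction. ``resolution`` is the minimum defining-word length
    (:data:`UNBOUNDED` for a full factorial).
    """

    groups: tuple[tuple[tuple[str, ...], ...], ...]
    resolution: float

    def group_of(self, effect: Sequence[str]) -> tuple[tuple[str, ...], ...]:
        key = tuple(sorted(effect))
        for g in self.groups:
            if key in g:
                return g
        raise UnknownFactorError(f"effect {key} not in alias table")

    def tfi_representatives(self) -> tuple[tuple[str, str], ...]:
        """One 2FI per group that contains interactions but no main effect.

        The lexicographically smallest pair represents its alias class; these
        are the interaction columns a model can include alongside all MEs
        without building a singular matrix.
        """
        reps = []
        for g in self.groups:
            if any(len(e) == 1 for e in g):
                continue
            pairs = [e for e in g if len(e) == 2]
            if pairs:
                reps.append(min(pairs))
        return tuple(sorted(reps))

    def report(self) -> str:
        lines = []
        for g in self.groups:
            lines.append(" = ".join(":".join(e) for e in g))
        return "\n".join(lines)


@dataclass(frozen=True)
class EstimabilityReport:
    """Diagnostics for a design after run removal.

    ``me_rank`` is the rank of the intercept+ME model matrix on the
    survivors; all MEs stay estimable iff it equals 1 + k. The correlation
    lists name effect pairs whose columns, orthogonal on the parent design,
    became correlated on the survivors — run removal leaves main effects
    estimable here but makes the confounding pattern messier.
    """

    n_runs: int
    me_rank: int
    n_me_params: int
    all_main_effects_estimable: bool
    new_me_correlations: tuple
    new_tfi_correlations: tuple


# ---------------------------------------------------------------------------
# sizes and generator search


def full_factorial_size(spec: DesignSpec) -> int:
    """Product of level counts over all factors of ``spec``."""
    size = 1
    for lv in spec.levels_per_factor:
        size *= lv
    return size


@lru_cache(maxsize=None)
def _min_aberration_generators(k: int, m: int, min_wl: int):
    """Best generator assignment for a 2^(k-(k-m)) fraction, or None.

    Returns a tuple of p = k - m bitmasks over the m basic columns; added
    factor j's column is the product of the basic columns in mask j. Searches
    all admissible assignments depth-first (candidates in increasing bitmask
    order), pruning any branch that creates a word shorter than ``min_wl``,
    and keeps the minimum-aberration word-length pattern.
    """
    p = k - m
    if p <= 0:
        return ()
    # Every generator word (mask + its added factor) must reach min_wl.
    cands = [c for c in range(1, 1 << m) if c.bit_count() >= min_wl - 1]
    if len(cands) < p:
        return None
    best_wlp = None
    best = None
    nodes = 0

    def dfs(start: int, chosen: list, xors: list):
        nonlocal best_wlp, best, nodes
        t = len(chosen)
        if t == p:
            wlp = [0] * (k + 1)
            for s in range(1, 1 << p):
                wlp[xors[s].bit_count() + s.bit_count()] += 1
            wlp_t = tuple(wlp[3:])
            if best_wlp is None or wlp_t < best_wlp:
                best_wlp = wlp_t
                best = tuple(chosen)
            return
        for i in range(start, len(cands) - (p - t) + 1):
            nodes += 1
            if nodes > _SEARCH_NODE_BUDGET:
                raise BudgetExceededError(
                    f"generator search for k={k}, m={m} exceeded its budget"
                )
            c = cands[i]
            size = 1 << t
            new = xors + [0] * size
            ok = True
            for s in range(size):
                x = xors[s] ^ c
                # word = subset-product of chosen ∪ {c}: |S|+1 added factors
                if x.bit_count() + s.bit_count() + 1 < min_wl:
                    ok = False
                    break
                new[size + s] = x
            if ok:
                chosen.append(c)
                dfs(i + 1, chosen, new)
                chosen.pop()

    dfs(0, [], [0])
    return best


def min_runs_for_resolution(k: int, res: str) -> int:
    """Smallest N = 2^(k-p) admitting a regular fraction of resolution >= res.

    Determined by generator search, not a catalog lookup: run sizes are tried
    in increasing order until an admissible generator set exists. The full
    factorial (p = 0) always succeeds, so the search terminates.
    """
    if k < 1:
        raise InvalidSpecError("need at least one factor")
    if res not in RESOLUTION_MIN_LENGTH:
        raise InvalidSpecError(f"resolution {res!r} not in III/IV/V")
    min_wl = RESOLUTION_MIN_LENGTH[res]
    for m in range(2, k + 1):
        if _min_aberration_generators(k, m, min_wl) is not None:
            return 1 << m
    return 1 << k


def generate_design(
    spec: DesignSpec,
    seed: int = 0,
    n_runs: int | None = None,
    shuffle: bool = False,
) -> CodedDesign:
    """Construct a regular design meeting ``spec.resolution_request``.

    Runs appear in standard order (first factor alternating slowest); pass
    ``shuffle=True`` for a seeded random run order. The first m = log2(N)
    factors sit on basic columns, the rest on minimum-aberration generator
    products; use :func:`assign_columns` afterwards if a particular factor
    subset must project onto a full factorial.
    """
    if any(lv != 2 for lv in spec.levels_per_factor):
        raise InvalidSpecError("fraction construction requires two-level factors")
    k = spec.n_factors
    res = spec.resolution_request
    if res == "full":
        if n_runs not in (None, 1 << k):
            raise InvalidSpecError("a full factorial has exactly 2^k runs")
        m, masks = k, ()
    else:
        if n_runs is None:
            n_runs = min_runs_for_resolution(k, res)
        m = int(round(math.log2(n_runs)))
        if 1 << m != n_runs:
            raise InvalidSpecError("n_runs must be a power of two")
        if m > k:
            raise InvalidSpecError("n_runs exceeds the full factorial size")
        if m == k:
            masks = ()
        else:
            masks = _min_aberration_generators(k, m, RESOLUTION_MIN_LENGTH[res])
            if masks is None:
                raise InfeasibleDesignError(
                    f"no resolution {res} fraction of {k} factors in "
                    f"{n_runs} runs"
                )
    base = np.array(
        list(itertools.product((-1, 1), repeat=m)), dtype=np.int8
    )
    cols = [base[:, j] for j in range(m)]
    generators = []
    for j, mask in enumerate(masks):
        members = list(_bits(mask))
        cols.append(base[:, members].prod(axis=1))
        generators.append(DefiningWord(frozenset(members + [m + j]), 1))
    runs = np.column_stack(cols).astype(np.int8)
    if shuffle:
        order = np.random.default_rng(seed).permutation(runs.shape[0])
        runs = runs[order]
    return CodedDesign(runs, spec.names, tuple(generators))


def flip_columns(design: CodedDesign, signs: Mapping[str, int]) -> CodedDesign:
    """Swap the coded orientation of selected factor columns.

    Flipping column j maps the fraction to the sign-variant fraction in
    which every defining word containing j changes sign; resolution, word
    lengths, balance and alias structure are untouched. Useful to pick, out
    of the 2^p statistically equivalent fractions, the one containing a
    particular run (e.g. a known reference condition).
    """
    flip = np.ones(design.n_factors, dtype=np.int8)
    for name, s in signs.items():
        if s not in (-1, 1):
            raise InvalidSpecError("column signs must be -1 or +1")
        flip[design.column_index(name)] = s
    new_words = []
    for w in design.generators:
        sign = w.sign
        for i in w.members:
            sign *= int(flip[i])
        new_words.append(DefiningWord(w.members, sign))
    return CodedDesign(
        design.runs * flip[None, :],
        design.factor_names,
        generators=tuple(new_words),
        run_ids=design.run_ids,
    )


def orient_fraction_towards(design: CodedDesign, settings: Mapping[str, int]) -> CodedDesign:
    """Column-flip a fraction so that ``settings`` is one of its runs.

    The first run is mapped onto the requested corner; every other run moves
    accordingly. The result is the same design up to level relabelling.
    """
    signs = {
        n: int(settings[n]) * int(design.runs[0, j])
        for j, n in enumerate(design.factor_names)
    }
    return flip_columns(design, signs)


# ---------------------------------------------------------------------------
# word algebra


def _closure(generator_words: Iterable[DefiningWord], k: int):
    """All 2^p - 1 non-identity (mask, sign) products of the generators."""
    items = [(w.mask(), w.sign) for w in generator_words]
    words = {}
    frontier = {0: 1}
    for mask, sign in items:
        new = {}
        for fm, fs in frontier.items():
            new[fm ^ mask] = fs * sign
        frontier.update(new)
    frontier.pop(0, None)
    for mask, sign in frontier.items():
        words[mask] = sign
    return words


def defining_subgroup(design: CodedDesign) -> list[DefiningWord]:
    """The defining contrast subgroup (all 2^p - 1 non-identity words).

    When generator provenance is present the subgroup is its product
    closure; otherwise every constant column product is recovered from the
    matrix by exhaustive mask enumeration (k <= 16). Raises
    :class:`NotRegularError` when the constant words found are inconsistent
    with a regular 2^(k-p) fraction — e.g. after arbitrary run removal.
    """
    k = design.n_factors
    n = design.n_runs
    if design.generators:
        found = _closure(design.generators, k)
    else:
        if (1 << k) == n:
            return []
        if k > 16:
            raise BudgetExceededError(
                f"cannot recover words of a {k}-factor design without "
                "generator provenance"
            )
        neg = (design.runs < 0).astype(np.uint32)
        rows = np.zeros(n, dtype=np.uint32)
        for j in range(k):
            rows |= neg[:, j] << np.uint32(j)
        found = {}
        for mask in range(1, 1 << k):
            parity = np.bitwise_count(rows & np.uint32(mask)) & 1
            if parity.min() == parity.max():
                found[mask] = 1 if parity[0] == 0 else -1
    count = len(found)
    if count and (count + 1) & count:  # count+1 not a power of two
        raise NotRegularError(
            f"{count} constant words found; not a regular fraction"
        )
    p = (count + 1).bit_length() - 1
    if n * (1 << p) != 1 << k:
        raise NotRegularError(
            f"{n} runs with {count} defining words is inconsistent with a "
            f"regular 2^({k}-{p}) fraction"
        )
    return sorted(
        (_mask_to_word(mask, sign) for mask, sign in found.items()),
        key=lambda w: (w.length, tuple(sorted(w.members))),
    )


def alias_groups(design: CodedDesign) -> AliasTable:
    """Partition MEs and 2FIs into alias groups.

    Two effects are aliased iff the symmetric difference of their factor
    sets is a defining word, i.e. their columns agree up to sign on every
    run of the fraction.
    """
    k = design.n_factors
    names = design.factor_names
    words = defining_subgroup(design)
    word_masks = [w.mask() for w in words]
    effects = [1 << i for i in range(k)]
    effects += [
        (1 << i) | (1 << j) for i, j in itertools.combinations(range(k), 2)
    ]
    buckets: dict[int, list[int]] = {}
    for e in effects:
        key = min([e] + [e ^ wm for wm in word_masks])
        buckets.setdefault(key, []).append(e)
    groups = []
    for key in buckets:
        group = tuple(
            sorted(
                (tuple(sorted(names[i] for i in _bits(e))) for e in buckets[key]),
                key=lambda e: (len(e), e),
            )
        )
        groups.append(group)
    groups.sort(key=lambda g: (len(g[0]), g[0]))
    resolution = min((w.length for w in words), default=UNBOUNDED)
    return AliasTable(tuple(groups), resolution)


def check_orthogonality(design: CodedDesign, effects: Sequence[Sequence[str]]):
    """Whether all listed effect columns are mutually orthogonal.

    Returns ``(ok, offenders)`` where offenders lists every non-orthogonal
    pair with its inner product, worst first.
    """
    cols = [design.effect_column(e) for e in effects]
    offenders = []
    for (a, ea), (b, eb) in itertools.combinations(zip(cols, effects), 2):
        ip = int(a @ b)
        if ip != 0:
            offenders.append(((tuple(ea), tuple(eb)), ip))
    offenders.sort(key=lambda item: -abs(item[1]))
    return (not offenders), offenders


def project_onto(
    design: CodedDesign, subset: Sequence[str]
) -> dict[tuple[int, ...], int]:
    """Occupancy of every coded combination of the ``subset`` factors.

    A regular fraction projects onto a (replicated) full factorial in a
    subset exactly when no defining word's members all lie in the subset.
    """
    if not subset:
        raise InvalidSpecError("projection subset must be non-empty")
    idx = [design.column_index(n) for n in subset]
    counts = {
        combo: 0 for combo in itertools.product((-1, 1), repeat=len(subset))
    }
    for row in design.runs[:, idx]:
        counts[tuple(int(v) for v in row)] += 1
    return counts


def assign_columns(
    spec: DesignSpec,
    design: CodedDesign,
    must_project_full: Sequence[str],
):
    """Re-assign factors to design columns so a subset projects fully.

    Searches column subsets in lexicographic order for one containing no
    defining word; the ``must_project_full`` factors are placed on those
    columns (in their given order) and the remaining spec factors fill the
    remaining columns in spec order. Returns ``(design, mapping)`` where
    mapping sends each factor name to its column index.
    """
    must = list(must_project_full)
    unknown = set(must) - set(spec.names)
    if unknown:
        raise UnknownFactorError(f"unknown factors {sorted(unknown)}")
    if set(spec.names) != set(design.factor_names):
        raise InvalidSpecError("spec and design declare different factors")
    k = design.n_factors
    if len(must) > k:
        raise InvalidSpecError("subset larger than the design")
    words = defining_subgroup(design)
    member_sets = [set(w.members) for w in words]
    for combo in itertools.combinations(range(k), len(must)):
        cset = set(combo)
        if any(ms <= cset for ms in member_sets):
            continue
        new_names: list[str | None] = [None] * k
        for name, col in zip(must, combo):
            new_names[col] = name
        rest = [n for n in spec.names if n not in must]
        free = [j for j in range(k) if new_names[j] is None]
        for name, col in zip(rest, free):
            new_names[col] = name
        assigned = replace(design, factor_names=tuple(new_names))
        mapping = {name: new_names.index(name) for name in spec.names}
        return assigned, mapping
    raise InfeasibleAssignmentError(
        f"no column assignment lets {must} project onto a full factorial"
    )


# ---------------------------------------------------------------------------
# run removal diagnostics


def _pairwise_new_correlations(matrix: np.ndarray, labels, tol=1e-9):
    """Off-diagonal correlations among columns that were orthogonal before."""
    out = []
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(matrix, rowvar=False)
    for i, j in itertools.combinations(range(matrix.shape[1]), 2):
        c = corr[i, j]
        if np.isnan(c):
            c = 1.0  # a constant column is maximally confounded
        if abs(c) > tol:
            out.append(((labels[i], labels[j]), float(c)))
    out.sort(key=lambda item: -abs(item[1]))
    return tuple(out)


def remove_runs(design: CodedDesign, drop: Callable[[dict], bool]):
    """Drop the runs where ``drop(settings)`` is true; report estimability.

    Returns ``(reduced, report)``. The reduced design loses its generator
    provenance (an arbitrary subset is generally not a regular fraction).
    The report gives the rank of the intercept+ME matrix on the survivors,
    whether all MEs stay estimable, and the column correlations the removal
    introduced among MEs and among 2FI alias-class representatives.
    """
    keep = [i for i in range(design.n_runs) if not drop(design.settings(i))]
    if not keep:
        raise EmptyDesignError("run removal left no surviving runs")
    reduced = CodedDesign(
        design.runs[keep],
        design.factor_names,
        generators=(),
        run_ids=tuple(design.run_ids[i] for i in keep),
    )
    sub = reduced.runs.astype(float)
    me_matrix = np.column_stack([np.ones(len(keep)), sub])
    svals = np.linalg.svd(me_matrix, compute_uv=False)
    rank = int(np.sum(svals > 1e-10 * svals[0]))
    me_labels = list(design.factor_names)
    new_me = _pairwise_new_correlations(sub, me_labels)
    try:
        reps = alias_groups(design).tfi_representatives()
    except NotRegularError:
        reps = tuple(
            itertools.combinations(design.factor_names, 2)
        )  # unknown structure: inspect all pairs
    if reps:
        tfi_cols = np.column_stack(
            [reduced.effect_column(r).astype(float) for r in reps]
        )
        full_cols = np.column_stack(
            [design.effect_column(r).astype(float) for r in reps]
        )
        before = {
            pair for pair, _ in _pairwise_new_correlations(
                full_cols, [":".join(r) for r in reps]
            )
        }
        new_tfi = tuple(
            item
            for item in _pairwise_new_correlations(
                tfi_cols, [":".join(r) for r in reps]
            )
            if item[0] not in before
        )
    else:
        new_tfi = ()
    report = EstimabilityReport(
        n_runs=len(keep),
        me_rank=rank,
        n_me_params=1 + design.n_factors,
        all_main_effects_estimable=rank == 1 + design.n_factors,
        new_me_correlations=new_me,
        new_tfi_correlations=new_tfi,
    )
    return reduced, report
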