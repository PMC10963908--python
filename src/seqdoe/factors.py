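"""Experimental factors and design specifications.

A :class:`Factor` is one experimental variable studied at two coded levels,
-1 (low) and +1 (high), with human-readable labels for each level and a
category tag (genetic / process / media) used when a design must project a
full factorial onto the genetic subset (each distinct genetic combination is
one strain to construct).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import InvalidSpecError

CATEGORIES = ("genetic", "process", "media")

#: Resolution requests accepted by the design generator.
RESOLUTIONS = ("III", "IV", "V", "full")


@dataclass(frozen=True)
class Factor:
    """One two-level experimental variable.

    Parameters
    ----------
    name : str
        Short unique identifier, used as the CSV column header.
    category : {"genetic", "process", "media"}
    low_label, high_label : str
        Real-world meaning of coded -1 and +1 (e.g. "20C" / "30C").
    """

    name: str
    category: str
    low_label: str
    high_label: str

    def __post_init__(self):
        if not self.name:
            raise InvalidSpecError("factor name must be non-empty")
        if self.category not in CATEGORIES:
            raise InvalidSpecError(
                f"factor {self.name!r}: category {self.category!r} "
                f"not in {CATEGORIES}"
            )
        if self.low_label == self.high_label:
            raise InvalidSpecError(
                f"factor {self.name!r}: low and high labels must differ"
            )


@dataclass(frozen=True)
class DesignSpec:
    """An ordered factor list plus a resolution request.

    ``levels_per_factor`` is only consulted by :func:`full_factorial_size`;
    fraction construction requires every factor at two levels.
    """

    factors: tuple[Factor, ...]
    resolution_request: str = "full"
    levels_per_factor: tuple[int, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        if not self.factors:
            raise InvalidSpecError("a design spec needs at least one factor")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise InvalidSpecError(f"duplicate factor names in {names}")
        if self.resolution_request not in RESOLUTIONS:
            raise InvalidSpecError(
                f"resolution_request {self.resolution_request!r} "
                f"not in {RESOLUTIONS}"
            )
        levels = self.levels_per_factor or tuple(2 for _ in self.factors)
        if len(levels) != len(self.factors):
            raise InvalidSpecError("levels_per_factor length != factor count")
        if any(lv < 2 for lv in levels):
            raise InvalidSpecError("every factor needs at least 2 levels")
        object.__setattr__(self, "levels_per_factor", tuple(levels))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def n_factors(self) -> int:
        return len(self.factors)


def spec_from_names(names: Sequence[str], resolution: str = "full") -> DesignSpec:
    """Build a spec from bare names (process category, generic labels)."""
    return DesignSpec(
        tuple(Factor(n, "process", "low", "high") for n in names),
        resolution_request=resolution,
    )


def pca_factors() -> tuple[Factor, ...]:
    """The eleven factors of the p-coumaric-acid optimization study.

    Four genetic factors set promoter strength for pathway genes; the rest
    are process and media variables. Labels give the real-world setting
    behind each coded level.
    """
    return (
        Factor("T", "process", "20C", "30C"),
        Factor("rpm", "process", "180 rpm", "250 rpm"),
        Factor("OD", "process", "0.3", "0.6"),
        Factor("N", "media", "urea", "ammonium sulfate"),
        Factor("pH", "media", "unbuffered", "buffered"),
        Factor("Phe", "media", "0 mM", "5 mM"),
        Factor("Glu", "media", "0 mM", "5 mM"),
        Factor("PAL-C4H", "genetic", "VMA6-PXR1", "RPS9A-CHO1"),
        Factor("ARO7", "genetic", "PFY1", "ACT1"),
        Factor("AROL", "genetic", "RPL28", "TEF1"),
        Factor("ARO4", "genetic", "MYO4", "TDH3"),
    )


def pca_infeasible(settings: dict) -> bool:
    """Whether a run's genotype cannot be built.

    Two of the sixteen gene clusters could not be assembled; both carry low
    PAL-C4H expression together with high ARO7 and high ARO4 (they differ
    only in AROL), so the predicate is expressed on those three genetic
    columns rather than on row indices.
    """
    return (
        settings["PAL-C4H"] == -1
        and settings["ARO7"] == 1
        and settings["ARO4"] == 1
    )
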