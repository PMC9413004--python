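"""Factors, the L18 orthogonal array, run labels, and the flocculation-efficiency metric.

The experiment screens five three-level process factors of a chitosan jar
test — chitosan type (A), pH (B), dosage (C), rapid-mixing speed (D) and
slow-mixing speed (E) — over the 18 runs of a Taguchi L18 orthogonal array.
Level indices are 1-based throughout, matching the subscripts in run labels
such as ``A_3_B_1_C_2_D_1_E_3_``; the physical level values (mg/L, rpm, pH)
are attached metadata and never enter any arithmetic.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

__all__ = [
    "FACTOR_NOTATIONS",
    "FactorSpec",
    "DesignMatrix",
    "BalanceReport",
    "CombinationParseError",
    "parse_combination",
    "format_combination",
    "build_l18",
    "default_factors",
    "check_balance",
    "flocculation_efficiency",
]

FACTOR_NOTATIONS = ("A", "B", "C", "D", "E")


class CombinationParseError(ValueError):
    """A run label does not encode a valid factor/level combination."""


@dataclass(frozen=True)
class FactorSpec:
    """One controllable process factor with exactly three ordered levels.

    ``levels`` holds the physical settings (e.g. dosage 45/55/65 mg/L) in
    level order, so ``levels[i - 1]`` is the setting of 1-based level ``i``.
    """

    notation: str
    name: str
    levels: tuple
    unit: str = ""

    def __post_init__(self) -> None:
        if len(self.notation) != 1 or not self.notation.isalpha():
            raise ValueError(f"notation must be a single letter, got {self.notation!r}")
        if len(self.levels) != 3:
            raise ValueError(f"factor {self.notation}: exactly 3 levels required, got {len(self.levels)}")

    def level_value(self, level: int):
        """Physical setting of a 1-based level index."""
        if level not in (1, 2, 3):
            raise ValueError(f"level index must be 1-3, got {level}")
        return self.levels[level - 1]


def default_factors() -> tuple[FactorSpec, ...]:
    """The five jar-test factors with their physical level settings."""
    return (
        FactorSpec("A", "chitosan type", ("ch1", "ch2", "ch3")),
        FactorSpec("B", "pH value", (5, 6, 7)),
        FactorSpec("C", "chitosan dosage", (45, 55, 65), unit="mg/L"),
        FactorSpec("D", "rapid mixing", (250, 350, 450), unit="rpm"),
        FactorSpec("E", "slow mixing", (50, 100, 150), unit="rpm"),
    )


@dataclass(frozen=True)
class DesignMatrix:
    """An orthogonal design: runs x factors grid of 1-based level indices."""

    factors: tuple[FactorSpec, ...]
    assignment: np.ndarray  # shape (n_runs, n_factors), ints in {1,2,3}
    run_ids: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.assignment, dtype=int)
        if arr.ndim != 2 or arr.shape[1] != len(self.factors):
            raise ValueError("assignment must be (n_runs, n_factors)")
        if not np.isin(arr, (1, 2, 3)).all():
            raise ValueError("level indices must be in {1,2,3}")
        notations = [f.notation for f in self.factors]
        if len(set(notations)) != len(notations):
            raise ValueError("factor notations must be unique within a design")
        object.__setattr__(self, "assignment", arr)
        if self.run_ids is None:
            object.__setattr__(self, "run_ids", tuple(range(1, arr.shape[0] + 1)))
        elif len(self.run_ids) != arr.shape[0]:
            raise ValueError("run_ids length must equal run count")

    @property
    def n_runs(self) -> int:
        return self.assignment.shape[0]

    @property
    def notations(self) -> tuple[str, ...]:
        return tuple(f.notation for f in self.factors)

    def factor_index(self, notation: str) -> int:
        try:
            return self.notations.index(notation)
        except ValueError:
            raise KeyError(f"unknown factor {notation!r}; design has {self.notations}") from None

    def column(self, notation: str) -> np.ndarray:
        """Level-index column of one factor, over all runs."""
        return self.assignment[:, self.factor_index(notation)]

    def level_mask(self, notation: str, level: int) -> np.ndarray:
        """Boolean run mask selecting runs at a given 1-based level."""
        return self.column(notation) == level

    def run_combination(self, run_id: int) -> tuple[int, ...]:
        return tuple(self.assignment[self.run_ids.index(run_id)])

    def labels(self) -> list[str]:
        return [format_combination(row) for row in self.assignment]


# The 18 run labels of the study's L18 assignment, in run order.
L18_LABELS = (
    "A_1_B_1_C_1_D_1_E_1_",
    "A_1_B_2_C_2_D_2_E_2_",
    "A_1_B_3_C_3_D_3_E_3_",
    "A_2_B_1_C_1_D_2_E_2_",
    "A_2_B_2_C_2_D_3_E_3_",
    "A_2_B_3_C_3_D_1_E_1_",
    "A_3_B_1_C_2_D_1_E_3_",
    "A_3_B_2_C_3_D_2_E_1_",
    "A_3_B_3_C_1_D_3_E_2_",
    "A_1_B_1_C_3_D_3_E_2_",
    "A_1_B_2_C_1_D_1_E_3_",
    "A_1_B_3_C_2_D_2_E_1_",
    "A_2_B_1_C_2_D_3_E_1_",
    "A_2_B_2_C_3_D_1_E_2_",
    "A_2_B_3_C_1_D_2_E_3_",
    "A_3_B_1_C_3_D_2_E_3_",
    "A_3_B_2_C_1_D_3_E_1_",
    "A_3_B_3_C_2_D_1_E_2_",
)

_TOKEN_RE = re.compile(r"([A-Za-z])_?(\d)_?")


def parse_combination(label: str) -> tuple[int, ...]:
    """Parse a run label like ``A_3_B_1_C_2_D_1_E_3_`` into level indices.

    The five factor letters A-E must each appear once, in order, each
    followed by a level digit 1-3. Underscores are optional, so the compact
    form ``A3B1C2D1E3`` is accepted too.
    """
    tokens = _TOKEN_RE.findall(label.strip())
    residue = _TOKEN_RE.sub("", label.strip())
    if residue:
        raise CombinationParseError(f"unparseable text {residue!r} in label {label!r}")
    if len(tokens) != len(FACTOR_NOTATIONS):
        raise CombinationParseError(
            f"label {label!r} has {len(tokens)} factor tokens, expected {len(FACTOR_NOTATIONS)}"
        )
    levels = []
    for (letter, digit), expected in zip(tokens, FACTOR_NOTATIONS):
        if letter.upper() != expected:
            raise CombinationParseError(
                f"label {label!r}: expected factor {expected!r}, found token {letter + digit!r}"
            )
        level = int(digit)
        if level not in (1, 2, 3):
            raise CombinationParseError(
                f"label {label!r}: level digit {digit!r} for factor {expected!r} outside 1-3"
            )
        levels.append(level)
    return tuple(levels)


def format_combination(levels: Sequence[int]) -> str:
    """Inverse of :func:`parse_combination`; renders the study's label style."""
    if len(levels) != len(FACTOR_NOTATIONS):
        raise ValueError(f"expected {len(FACTOR_NOTATIONS)} levels, got {len(levels)}")
    for letter, level in zip(FACTOR_NOTATIONS, levels):
        if int(level) not in (1, 2, 3):
            raise ValueError(f"factor {letter}: level {level} outside 1-3")
    return "".join(f"{letter}_{int(level)}_" for letter, level in zip(FACTOR_NOTATIONS, levels))


def build_l18(factors: Sequence[FactorSpec] | None = None) -> DesignMatrix:
    """The study's exact L18 assignment (run 1 = (1,1,1,1,1), ..., run 18 = (3,3,2,1,2)).

    The array is stored as the explicit list of 18 run labels rather than
    generated from a generic L18(3^6) catalogue: the study fixes one
    particular column selection, and that assignment is the contract.
    """
    assignment = np.array([parse_combination(lab) for lab in L18_LABELS], dtype=int)
    return DesignMatrix(tuple(factors) if factors is not None else default_factors(), assignment)


@dataclass(frozen=True)
class BalanceReport:
    """Level and pairwise-combination counts of a design, with a verdict.

    ``level_counts`` maps factor notation -> {level: count}; ``pair_counts``
    maps (notation, notation) -> {(level, level): count}. ``balanced`` is
    true iff every factor is level-balanced and every factor pair sees all
    nine level combinations equally often.
    """

    level_counts: dict
    pair_counts: dict
    balanced: bool
    violations: tuple[str, ...] = ()


def check_balance(design: DesignMatrix) -> BalanceReport:
    """Verify the orthogonal-array property: level and pairwise balance."""
    if len(design.factors) < 2:
        raise ValueError("balance check needs at least 2 factors")
    violations: list[str] = []
    level_counts = {}
    for f in design.factors:
        counts = dict(Counter(design.column(f.notation).tolist()))
        level_counts[f.notation] = counts
        expected = design.n_runs / 3
        if set(counts) != {1, 2, 3} or any(c != expected for c in counts.values()):
            violations.append(f"factor {f.notation} level counts {counts} != {expected:g} each")
    pair_counts = {}
    for fa, fb in combinations(design.notations, 2):
        counts = dict(Counter(zip(design.column(fa).tolist(), design.column(fb).tolist())))
        pair_counts[(fa, fb)] = counts
        expected = design.n_runs / 9
        if len(counts) != 9 or any(c != expected for c in counts.values()):
            violations.append(f"pair ({fa},{fb}) combination counts unbalanced: {counts}")
    return BalanceReport(level_counts, pair_counts, not violations, tuple(violations))


def flocculation_efficiency(od_before: float, od_after: float) -> float:
    """Flocculation efficiency in percent from optical densities at 600 nm.

    EF = 100 * (OD_0 - OD) / OD_0 where OD_0 is measured before treatment
    and OD after settling. A negative value signals failed flocculation
    (suspension got denser) and is returned as-is, not clamped.
    """
    if od_before <= 0:
        raise ValueError(f"od_before must be positive, got {od_before}")
    if od_after < 0:
        raise ValueError(f"od_after must be non-negative, got {od_after}")
    return 100.0 * (od_before - od_after) / od_before
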