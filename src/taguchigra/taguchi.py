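"""Signal-to-noise conversion, main effects, balanced ANOVA, and additive prediction.

Implements the Taguchi larger-the-better analysis chain for a balanced
three-level orthogonal design: per-run S/N ratios in decibels, per-factor
per-level mean effects, a no-interaction fixed-effects ANOVA of the S/N
vector, argmax optimal-level selection, and the additive main-effects
prediction at an arbitrary level combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix, check_balance

__all__ = [
    "snr_larger_better",
    "snr_table",
    "MainEffectsTable",
    "main_effects",
    "select_optimal",
    "AnovaTable",
    "anova_balanced",
    "PredictionResult",
    "predict_additive",
]

LEVELS = (1, 2, 3)


def snr_larger_better(replicates: Sequence[float]) -> float:
    """Larger-the-better signal-to-noise ratio, in decibels.

    S/N = -10 * log10( (1/n) * sum 1/y_i^2 ). For a single replicate this
    reduces to 20 * log10(y). Undefined for non-positive responses.
    """
    y = np.asarray(replicates, dtype=float)
    if y.size == 0:
        raise ValueError("at least one replicate required")
    if (y <= 0).any():
        raise ValueError("all replicates must be positive for the larger-the-better S/N")
    return float(-10.0 * np.log10(np.mean(1.0 / y**2)))


def snr_table(values, name: str | None = None) -> pd.Series:
    """Elementwise single-replicate larger-the-better S/N of a per-run vector."""
    s = pd.Series(values, dtype=float)
    if (s <= 0).any():
        bad = s.index[s <= 0].tolist()
        raise ValueError(f"non-positive values at runs {bad}: S/N undefined")
    out = 20.0 * np.log10(s)
    out.name = f"snr({name})" if name else "snr"
    return out


@dataclass(frozen=True)
class MainEffectsTable:
    """Per-factor per-level means of an analysed per-run quantity.

    ``level_means`` is a (factor x level) DataFrame; ``delta`` is the range
    max-min of each factor's level means and ``delta_rank`` orders factors
    by delta (1 = largest, i.e. most influential). In a balanced design the
    mean of each factor's three level means equals ``overall_mean``.
    """

    level_means: pd.DataFrame  # index: factor notations, columns: levels 1..3
    overall_mean: float
    response: str = ""

    @property
    def delta(self) -> pd.Series:
        return self.level_means.max(axis=1) - self.level_means.min(axis=1)

    @property
    def delta_rank(self) -> pd.Series:
        return self.delta.rank(ascending=False, method="min").astype(int)

    def to_frame(self) -> pd.DataFrame:
        df = self.level_means.copy()
        df.columns = [f"level_{c}" for c in df.columns]
        df["delta"] = self.delta
        df["rank"] = self.delta_rank
        return df


def main_effects(design: DesignMatrix, values, response: str = "") -> MainEffectsTable:
    """Level means of ``values`` over the six runs at each factor level."""
    y = np.asarray(values, dtype=float)
    if y.shape != (design.n_runs,):
        raise ValueError(f"values length {y.shape} != design run count {design.n_runs}")
    if not check_balance(design).balanced:
        raise ValueError("design is not level/pairwise balanced; level means would be confounded")
    means = pd.DataFrame(
        {
            level: [y[design.level_mask(n, level)].mean() for n in design.notations]
            for level in LEVELS
        },
        index=list(design.notations),
    )
    return MainEffectsTable(means, float(y.mean()), response)


def select_optimal(effects: MainEffectsTable) -> tuple[tuple[int, ...], ...]:
    """Per factor, the level(s) with maximal level mean (larger-the-better).

    Returns one tuple of argmax levels per factor; a singleton when the
    maximum is unique. Exact ties are surfaced, never silently broken.
    """
    out = []
    for _, row in effects.level_means.iterrows():
        best = row.max()
        out.append(tuple(int(level) for level, m in row.items() if m == best))
    return tuple(out)


def unique_optimal(effects: MainEffectsTable) -> tuple[int, ...]:
    """The optimal combination when every factor has a unique argmax level."""
    picks = select_optimal(effects)
    if any(len(p) != 1 for p in picks):
        raise ValueError(f"tied optimal levels: {picks}")
    return tuple(p[0] for p in picks)


@dataclass(frozen=True)
class AnovaTable:
    """Balanced fixed-effects ANOVA of a per-run vector over the design factors.

    ``table`` has one row per factor plus Error and Total rows, with columns
    df, sum_sq, mean_sq, F, p. Factor SS are sequential = adjusted here
    (orthogonal design), and the decomposition sum(factor SS) + error SS =
    total SS holds to machine precision.
    """

    table: pd.DataFrame

    def ss(self, source: str) -> float:
        return float(self.table.loc[source, "sum_sq"])

    def f_value(self, source: str) -> float:
        return float(self.table.loc[source, "F"])

    def p_value(self, source: str) -> float:
        return float(self.table.loc[source, "p"])


def anova_balanced(design: DesignMatrix, values) -> AnovaTable:
    """No-interaction ANOVA: factor SS = 6 * sum over levels of (level mean - grand mean)^2.

    Error SS is total SS minus the factor SS; F compares each factor mean
    square against the error mean square with an F(2, error df) reference.
    A zero error mean square yields infinite F with p = 0.
    """
    y = np.asarray(values, dtype=float)
    if y.shape != (design.n_runs,):
        raise ValueError("values length must equal design run count")
    if not check_balance(design).balanced:
        raise ValueError("ANOVA requires a balanced design")
    n_per_level = design.n_runs // len(LEVELS)
    grand = y.mean()
    total_ss = float(((y - grand) ** 2).sum())
    total_df = design.n_runs - 1
    rows = {}
    factor_df = len(LEVELS) - 1
    for notation in design.notations:
        level_means = np.array([y[design.level_mask(notation, lv)].mean() for lv in LEVELS])
        rows[notation] = n_per_level * float(((level_means - grand) ** 2).sum())
    error_df = total_df - factor_df * len(design.notations)
    if error_df <= 0:
        raise ValueError(f"error degrees of freedom {error_df} <= 0: model saturates the design")
    error_ss = total_ss - sum(rows.values())
    error_ss = max(error_ss, 0.0)  # guard float cancellation on exact fits
    error_ms = error_ss / error_df
    records = []
    for notation, ss in rows.items():
        ms = ss / factor_df
        if error_ms > 0:
            f_val = ms / error_ms
            p = float(stats.f.sf(f_val, factor_df, error_df))
        else:
            f_val, p = (np.inf if ms > 0 else np.nan), 0.0
        records.append((notation, factor_df, ss, ms, f_val, p))
    records.append(("Error", error_df, error_ss, error_ms, np.nan, np.nan))
    records.append(("Total", total_df, total_ss, np.nan, np.nan, np.nan))
    table = pd.DataFrame.from_records(
        records, columns=["source", "df", "sum_sq", "mean_sq", "F", "p"]
    ).set_index("source")
    return AnovaTable(table)


@dataclass(frozen=True)
class PredictionResult:
    """Additive main-effects prediction at a level combination.

    On the "snr-db" scale ``back_transformed`` is the response implied by
    the predicted decibel value, 10^(pred/20); on the "value" scale it is
    None. With an empty term set the prediction is the overall mean.
    """

    combination: tuple[int, ...]
    scale: str
    terms: tuple[str, ...]
    predicted: float
    back_transformed: float | None = None


def predict_additive(
    effects: MainEffectsTable,
    combination: Sequence[int],
    terms: Sequence[str] | None = None,
    scale: str = "value",
) -> PredictionResult:
    """Predict the response at ``combination`` as overall mean plus chosen factor gains.

    prediction = grand mean + sum over f in terms of (mean of f at its
    chosen level - grand mean), on whichever scale ``effects`` was built
    (raw values or S/N decibels — pass the matching ``scale`` label).
    """
    if scale not in ("value", "snr-db"):
        raise ValueError(f"scale must be 'value' or 'snr-db', got {scale!r}")
    notations = list(effects.level_means.index)
    if len(combination) != len(notations):
        raise ValueError(f"combination needs one level per factor ({len(notations)})")
    terms = tuple(notations) if terms is None else tuple(terms)
    unknown = [t for t in terms if t not in notations]
    if unknown:
        raise ValueError(f"unknown factor(s) in terms: {unknown}; design has {notations}")
    pred = effects.overall_mean
    for notation, level in zip(notations, combination):
        if notation in terms:
            pred += effects.level_means.loc[notation, int(level)] - effects.overall_mean
    back = 10.0 ** (pred / 20.0) if scale == "snr-db" else None
    return PredictionResult(tuple(int(l) for l in combination), scale, terms, float(pred), back)
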