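"""Grey relational analysis for multi-response larger-the-better optimization.

The chain: min-max normalize each response over the design runs, form
deviation sequences from the ideal, convert deviations to grey relational
coefficients with a distinguishing coefficient psi, and average the
coefficients (optionally weighted) into a single grey relational grade per
run, ranked descending. Out-of-design validation runs are scored against
the stored normalization context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RESPONSE_NAMES",
    "ResponseMatrix",
    "NormalizationContext",
    "GRAResult",
    "normalize_larger_better",
    "deviation_sequences",
    "grey_relational_coefficient",
    "grey_relational_grade",
    "gra_pipeline",
    "score_external",
]

# Column order of the study's five responses: flocculation efficiency (%)
# then the four inhibition-zone diameters (mm).
RESPONSE_NAMES = (
    "EF",
    "zone_xanthomonas",
    "zone_colletotrichum",
    "zone_fusarium",
    "zone_aspergillus",
)


@dataclass(frozen=True)
class ResponseMatrix:
    """Runs x responses grid of non-negative larger-the-better responses."""

    data: pd.DataFrame  # index: run ids, columns: response names

    def __post_init__(self) -> None:
        df = self.data
        if df.isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise ValueError(f"missing cells in responses {bad}")
        if (df.values < 0).any():
            raise ValueError("responses must be non-negative")
        object.__setattr__(self, "data", df.astype(float))

    @property
    def run_ids(self) -> list:
        return list(self.data.index)

    @property
    def responses(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_runs(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class NormalizationContext:
    """Per-response min and max over the design runs, fixed at fit time."""

    minima: pd.Series
    maxima: pd.Series

    def __post_init__(self) -> None:
        if not (self.maxima > self.minima).all():
            flat = self.minima.index[~(self.maxima > self.minima)].tolist()
            raise ValueError(f"degenerate (constant) response column(s): {flat}")


def normalize_larger_better(matrix: ResponseMatrix) -> tuple[pd.DataFrame, NormalizationContext]:
    """Column-wise min-max normalization: X = (Y - min) / (max - min), in [0, 1]."""
    df = matrix.data
    ctx = NormalizationContext(df.min(), df.max())
    normalized = (df - ctx.minima) / (ctx.maxima - ctx.minima)
    return normalized, ctx


def deviation_sequences(normalized: pd.DataFrame) -> pd.DataFrame:
    """Quality-loss deviations from the ideal: delta = 1 - X."""
    if ((normalized.values < 0) | (normalized.values > 1)).any():
        raise ValueError("normalized values must lie in [0, 1]")
    return 1.0 - normalized


def grey_relational_coefficient(
    deviations: pd.DataFrame,
    psi: float = 0.5,
    delta_min: float | None = None,
    delta_max: float | None = None,
) -> pd.DataFrame:
    """GRC = (delta_min + psi*delta_max) / (delta + psi*delta_max).

    delta_min / delta_max default to the global extrema of the deviation
    matrix; after larger-the-better min-max normalization these are 0 and 1,
    so per-column and global conventions coincide on in-design data.
    """
    if not 0 < psi <= 1:
        raise ValueError(f"distinguishing coefficient psi must be in (0, 1], got {psi}")
    d = deviations.values
    if (d < 0).any():
        raise ValueError("deviations must be non-negative")
    dmin = float(d.min()) if delta_min is None else float(delta_min)
    dmax = float(d.max()) if delta_max is None else float(delta_max)
    if dmax <= 0:
        raise ValueError("delta_max must be positive (all deviations identical at 0?)")
    return (dmin + psi * dmax) / (deviations + psi * dmax)


def _check_weights(weights, columns) -> pd.Series:
    if weights is None:
        w = pd.Series(1.0 / len(columns), index=columns)
    else:
        w = pd.Series(weights, dtype=float)
        if list(w.index) != list(columns):
            w.index = columns  # positional weights
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
    return w


def grey_relational_grade(
    grc: pd.DataFrame, weights=None
) -> tuple[pd.Series, pd.Series]:
    """Weighted mean of each run's coefficients, and descending competition ranks."""
    w = _check_weights(weights, grc.columns)
    grg = grc.mul(w, axis=1).sum(axis=1)
    grg.name = "GRG"
    ranks = grg.rank(ascending=False, method="min").astype(int)
    ranks.name = "rank"
    return grg, ranks


@dataclass(frozen=True)
class GRAResult:
    """All intermediates of one grey relational analysis over a design."""

    normalized: pd.DataFrame
    deviations: pd.DataFrame
    grc: pd.DataFrame
    grg: pd.Series
    ranks: pd.Series
    psi: float
    weights: pd.Series
    context: NormalizationContext
    flags: tuple[str, ...] = field(default=())

    @property
    def best_run(self):
        return self.grg.idxmax()


def gra_pipeline(matrix: ResponseMatrix, psi: float = 0.5, weights=None) -> GRAResult:
    """Full chain normalize -> deviations -> GRC -> GRG -> ranks, keeping the context."""
    normalized, ctx = normalize_larger_better(matrix)
    dev = deviation_sequences(normalized)
    grc = grey_relational_coefficient(dev, psi=psi, delta_min=0.0, delta_max=1.0)
    w = _check_weights(weights, grc.columns)
    grg, ranks = grey_relational_grade(grc, w)
    return GRAResult(normalized, dev, grc, grg, ranks, psi, w, ctx)


def score_external(
    new_responses,
    context: NormalizationContext,
    psi: float = 0.5,
    weights=None,
    clamp: bool = True,
) -> tuple[pd.Series, tuple[str, ...]]:
    """Grade out-of-design runs against a stored normalization context.

    ``new_responses`` is a DataFrame (runs x responses), a Series or a dict
    for a single run; response names must match the context. Values outside
    the design [min, max] normalize outside [0, 1]; with ``clamp`` (the
    default) X is clipped to [0, 1] before deviations, so a response
    exceeding the design maximum counts as ideal (delta = 0). With
    ``clamp=False`` out-of-range values are kept — coefficients may then
    exceed 1 — and each offending cell is reported in the returned flags.
    """
    if isinstance(new_responses, dict):
        new_responses = pd.Series(new_responses)
    if isinstance(new_responses, pd.Series):
        df = new_responses.to_frame().T
    else:
        df = pd.DataFrame(new_responses)
    expected = list(context.minima.index)
    unknown = [c for c in df.columns if c not in expected]
    if unknown or list(df.columns) != expected:
        raise ValueError(f"response names {list(df.columns)} do not match context {expected}")
    x = (df - context.minima) / (context.maxima - context.minima)
    flags: list[str] = []
    out_of_range = (x < 0) | (x > 1)
    if out_of_range.any().any():
        for run in x.index[out_of_range.any(axis=1)]:
            cols = x.columns[out_of_range.loc[run]].tolist()
            flags.append(f"run {run}: responses {cols} outside the design range")
    if clamp:
        x = x.clip(0.0, 1.0)
    # without clamping a negative deviation drives the GRC above 1; the
    # offending cells are already flagged, so keep the arithmetic honest
    dev = 1.0 - x
    grc = (0.0 + psi * 1.0) / (dev + psi * 1.0)
    w = _check_weights(weights, grc.columns)
    grg = grc.mul(w, axis=1).sum(axis=1)
    grg.name = "GRG"
    return grg, tuple(flags)
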