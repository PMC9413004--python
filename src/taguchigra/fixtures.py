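"""The study's designed-experiment data, shipped as in-package fixtures.

All inputs of the analysis are small printed tables: the L18 design with
its factor levels, the flocculation-efficiency column with its S/N
conversion, the five-response matrix (EF plus four inhibition-zone
diameters), and the validation run measured at the multi-response optimum.

Zone diameters are triplicate means; printed values ending .33/.67 are the
2-decimal renderings of repeating thirds (x + 1/3, x + 2/3). The loader
expands them back to exact thirds by default (``thirds=True``), which
reproduces the study's downstream tables to 4 decimals; with literal
2-decimal inputs agreement degrades to about 5e-4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignMatrix, build_l18
from .gra import RESPONSE_NAMES, ResponseMatrix

__all__ = ["expand_thirds", "load_fixture", "StudyFixture", "load_study"]

# Run id, EF (%), printed single-replicate larger-the-better S/N (dB).
_TABLE4 = (
    (1, 98.60, 39.8776),
    (2, 97.63, 39.7918),
    (3, 76.63, 37.6883),
    (4, 89.23, 39.0104),
    (5, 76.06, 37.6230),
    (6, 73.76, 37.3566),
    (7, 97.27, 39.7598),
    (8, 97.60, 39.7886),
    (9, 79.83, 38.0431),
    (10, 95.55, 39.6045),
    (11, 86.36, 38.7263),
    (12, 75.27, 37.5323),
    (13, 94.19, 39.4797),
    (14, 83.35, 38.4176),
    (15, 63.10, 36.0008),
    (16, 93.90, 39.4531),
    (17, 91.56, 39.2346),
    (18, 72.97, 37.2631),
)

# Run id, EF (%), zone diameters (mm): Xanthomonas, Colletotrichum,
# Fusarium, Aspergillus — triplicate means as printed (2 dp).
_TABLE6 = (
    (1, 98.60, 42.00, 40.33, 36.33, 36.33),
    (2, 97.63, 42.67, 34.67, 37.00, 32.33),
    (3, 76.63, 22.33, 29.33, 35.33, 41.00),
    (4, 89.23, 43.33, 35.00, 35.00, 41.67),
    (5, 76.06, 43.00, 35.00, 35.00, 39.33),
    (6, 73.76, 41.33, 33.00, 34.33, 35.33),
    (7, 97.27, 40.33, 41.00, 36.67, 44.33),
    (8, 97.60, 40.00, 38.33, 37.67, 41.33),
    (9, 79.83, 43.67, 39.33, 34.67, 40.67),
    (10, 95.55, 29.00, 32.00, 38.00, 26.00),
    (11, 86.36, 31.00, 32.67, 36.67, 33.00),
    (12, 75.27, 32.33, 32.67, 35.00, 29.67),
    (13, 94.19, 40.00, 41.00, 37.00, 37.33),
    (14, 83.35, 37.33, 34.67, 35.67, 35.33),
    (15, 63.10, 31.33, 32.00, 31.33, 40.67),
    (16, 93.90, 40.00, 35.00, 35.33, 40.33),
    (17, 91.56, 44.67, 35.33, 34.67, 40.00),
    (18, 72.97, 34.00, 31.67, 34.00, 43.67),
)

# Validation experiment at the multi-response optimum A3 B1 C2 D3 E1.
_TABLE10_EXPERIMENT = (97.50, 43.00, 40.33, 37.00, 44.85)
_TABLE10_COMBINATION = (3, 1, 2, 3, 1)

_ZONE_COLUMNS = RESPONSE_NAMES[1:]


def expand_thirds(values):
    """Restore repeating thirds in 2-decimal triplicate means.

    x.33 -> x + 1/3 and x.67 -> x + 2/3; every other fractional part is
    kept literally. Accepts scalars, arrays or Series.
    """
    arr = np.asarray(values, dtype=float)
    frac = np.round(arr - np.floor(arr), 2)
    out = np.where(
        frac == 0.33, np.floor(arr) + 1.0 / 3.0, np.where(frac == 0.67, np.floor(arr) + 2.0 / 3.0, arr)
    )
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    if np.isscalar(values) or np.asarray(values).ndim == 0:
        return float(out)
    return out


def _table4_frame() -> pd.DataFrame:
    df = pd.DataFrame(_TABLE4, columns=["run", "EF", "snr"]).set_index("run")
    return df


def _table6_matrix(thirds: bool = True) -> ResponseMatrix:
    df = pd.DataFrame(_TABLE6, columns=["run", *RESPONSE_NAMES]).set_index("run")
    if thirds:
        for col in _ZONE_COLUMNS:
            df[col] = expand_thirds(df[col])
    return ResponseMatrix(df)


def _table10_series(thirds: bool = True) -> pd.Series:
    s = pd.Series(_TABLE10_EXPERIMENT, index=list(RESPONSE_NAMES), name="validation")
    if thirds:
        s[list(_ZONE_COLUMNS)] = expand_thirds(s[list(_ZONE_COLUMNS)])
    return s


def load_fixture(name: str, thirds: bool = True):
    """Load a packaged study table by name.

    * ``"design"`` — the L18 :class:`DesignMatrix` with factor metadata;
    * ``"table4"`` — DataFrame of EF (%) and the printed S/N (dB) per run;
    * ``"table6"`` — the 18 x 5 :class:`ResponseMatrix`;
    * ``"table10"`` — the validation run's responses as a Series.

    ``thirds`` controls the repeating-thirds expansion of zone diameters.
    """
    loaders = {
        "design": lambda: build_l18(),
        "table4": _table4_frame,
        "table6": lambda: _table6_matrix(thirds),
        "table10": lambda: _table10_series(thirds),
    }
    try:
        return loaders[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(loaders)}") from None


@dataclass(frozen=True)
class StudyFixture:
    """Everything the end-to-end analysis consumes, loaded in one call."""

    design: DesignMatrix
    ef_table: pd.DataFrame
    responses: ResponseMatrix
    validation: pd.Series
    validation_combination: tuple[int, ...] = _TABLE10_COMBINATION


def load_study(thirds: bool = True) -> StudyFixture:
    return StudyFixture(
        design=load_fixture("design"),
        ef_table=load_fixture("table4"),
        responses=load_fixture("table6", thirds=thirds),
        validation=load_fixture("table10", thirds=thirds),
    )
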