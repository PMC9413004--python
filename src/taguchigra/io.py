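"""CSV / YAML input and output for designs, responses and result tables.

Response tables use the header ``run,EF,zone_xanthomonas,
zone_colletotrichum,zone_fusarium,zone_aspergillus``; designs use
``run,A,B,C,D,E`` with a YAML sidecar naming the factors and their
physical level values. Unicode minus signs (U+2212), as they appear in
typeset tables, are normalized to ASCII on ingest.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import DesignMatrix, FactorSpec
from .gra import ResponseMatrix

__all__ = [
    "read_response_csv",
    "write_response_csv",
    "write_design_csv",
    "read_design_csv",
    "write_factor_specs",
    "read_factor_specs",
]

_MINUS = "−"


def _read_normalized(path) -> _io.StringIO:
    text = Path(path).read_text(encoding="utf-8")
    return _io.StringIO(text.replace(_MINUS, "-"))


def read_response_csv(path, responses=None) -> ResponseMatrix:
    """Read a runs x responses table; runs are reordered by run id.

    Raises a descriptive error (naming the row) for missing columns,
    non-numeric or blank cells, and duplicate run ids.
    """
    df = pd.read_csv(_read_normalized(path))
    if "run" not in df.columns:
        raise ValueError(f"{path}: missing required column 'run'")
    expected = list(responses) if responses is not None else [c for c in df.columns if c != "run"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing response column(s) {missing}")
    dup = df["run"][df["run"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate run id(s) {dup}")
    for col in expected:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric or blank cell in column {col!r}, row {int(bad[0]) + 2}"
            )
    df = df.astype({c: float for c in expected})
    df = df.set_index("run").sort_index()[expected]
    return ResponseMatrix(df)


def write_response_csv(matrix: ResponseMatrix, path) -> None:
    matrix.data.to_csv(path, index_label="run")


def write_design_csv(design: DesignMatrix, path) -> None:
    df = pd.DataFrame(design.assignment, columns=list(design.notations))
    df.insert(0, "run", list(design.run_ids))
    df.to_csv(path, index=False)


def read_design_csv(path, factors) -> DesignMatrix:
    df = pd.read_csv(_read_normalized(path))
    notations = [f.notation for f in factors]
    missing = [c for c in ["run", *notations] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df = df.sort_values("run")
    return DesignMatrix(tuple(factors), df[notations].to_numpy(int), tuple(int(r) for r in df["run"]))


def write_factor_specs(factors, path) -> None:
    payload = [
        {"notation": f.notation, "name": f.name, "unit": f.unit, "levels": list(f.levels)}
        for f in factors
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


def read_factor_specs(path) -> tuple[FactorSpec, ...]:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return tuple(
        FactorSpec(d["notation"], d["name"], tuple(d["levels"]), d.get("unit", ""))
        for d in payload
    )
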