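"""CSV and configuration I/O for the depolarization pipeline.

Two plain-text dialects are used throughout (comment lines start with ``#``):

* Lab series: ``addition_index, added_volume_mL, s_co, s_cross, dark_co,
  dark_cross, c_spec``; the row with ``addition_index == 0`` is the blank.
* Field series: ``obs_id, b_p, b_bp, b_b_labile, b_sw, b_bsw, z_m,
  delta_obs`` (coefficients in 1/m, range in m).

Model constants live in a single JSON or YAML file whose keys override the
:class:`~lidarpol.forward_model.ModelConstants` defaults.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .forward_model import DEFAULT_CONSTANTS, ModelConstants, OpticalState
from .lab_reduction import (
    Addition,
    DepolResult,
    SignalPair,
    StandardAdditionSeries,
)

__all__ = [
    "FIELD_COLUMNS",
    "LAB_COLUMNS",
    "read_field_csv",
    "write_field_csv",
    "read_lab_csv",
    "write_lab_csv",
    "write_reduction_csv",
    "load_constants",
]

FIELD_COLUMNS = ["obs_id", "b_p", "b_bp", "b_b_labile", "b_sw", "b_bsw",
                 "z_m", "delta_obs"]
LAB_COLUMNS = ["addition_index", "added_volume_mL", "s_co", "s_cross",
               "dark_co", "dark_cross", "c_spec"]


def _read_table(path, required: Sequence[str], optional: Sequence[str] = ()):
    path = Path(path)
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; "
                         f"found {list(df.columns)}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    numeric = [c for c in list(required) + list(optional)
               if c in df.columns and c != "obs_id"]
    errors = []
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for row in bad:
            errors.append(f"row {row + 1}: non-numeric value "
                          f"{df.at[row, col]!r} in column {col!r}")
        df[col] = coerced
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    return df


def read_field_csv(
    path, constants: ModelConstants = DEFAULT_CONSTANTS
) -> list[tuple[OpticalState, float]]:
    """Parse a field IOP/delta CSV into (OpticalState, delta_obs) rows.

    Rows violating the IOP invariants (negative coefficients,
    b_b_labile > b_bp, delta outside [0, 1)) are collected into a single
    row-numbered error report.
    """
    df = _read_table(path, FIELD_COLUMNS)
    observations = []
    errors = []
    for row, rec in df.iterrows():
        try:
            delta = float(rec["delta_obs"])
            if not 0 <= delta < 1:
                raise ValueError(f"delta_obs={delta} outside [0, 1)")
            state = OpticalState(
                b_p=float(rec["b_p"]),
                b_bp=float(rec["b_bp"]),
                b_b_labile=float(rec["b_b_labile"]),
                b_sw=float(rec["b_sw"]),
                b_bsw=float(rec["b_bsw"]),
                z=float(rec["z_m"]),
                backscatter_ratio_labile=constants.backscatter_ratio_labile,
            )
        except ValueError as exc:
            errors.append(f"row {row + 1} (obs_id={rec['obs_id']!r}): {exc}")
            continue
        observations.append((state, delta))
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    return observations


def write_field_csv(path, observations: Sequence[tuple[OpticalState, float]],
                    header_comment: str | None = None) -> None:
    rows = [
        {
            "obs_id": i,
            "b_p": s.b_p, "b_bp": s.b_bp, "b_b_labile": s.b_b_labile,
            "b_sw": s.b_sw, "b_bsw": s.b_bsw, "z_m": s.z,
            "delta_obs": d,
        }
        for i, (s, d) in enumerate(observations)
    ]
    _write_csv(path, pd.DataFrame(rows, columns=FIELD_COLUMNS), header_comment)


def read_lab_csv(path) -> StandardAdditionSeries:
    """Parse a lab standard-addition CSV into a series.

    The ``addition_index == 0`` row is the blank; dark readings are taken from
    it. ``c_spec`` may be empty.
    """
    df = _read_table(path, [c for c in LAB_COLUMNS if c != "c_spec"],
                     optional=["c_spec"])
    blanks = df[df["addition_index"] == 0]
    if len(blanks) != 1:
        raise ValueError(
            f"{path}: expected exactly one blank row (addition_index=0), "
            f"found {len(blanks)}"
        )
    blank_rec = blanks.iloc[0]
    blank = SignalPair(co=float(blank_rec["s_co"]),
                       cross=float(blank_rec["s_cross"]))
    additions = []
    errors = []
    for row, rec in df[df["addition_index"] != 0].iterrows():
        try:
            c_spec = rec.get("c_spec")
            c_spec = None if c_spec is None or pd.isna(c_spec) else float(c_spec)
            additions.append(
                Addition(
                    added_volume_mL=float(rec["added_volume_mL"]),
                    signal=SignalPair(co=float(rec["s_co"]),
                                      cross=float(rec["s_cross"])),
                    c_spec=c_spec,
                )
            )
        except ValueError as exc:
            errors.append(f"row {row + 1}: {exc}")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    return StandardAdditionSeries(
        blank=blank,
        additions=tuple(additions),
        dark_co=float(blank_rec["dark_co"]),
        dark_cross=float(blank_rec["dark_cross"]),
        sample_id=Path(path).stem,
    )


def write_lab_csv(path, series: StandardAdditionSeries,
                  header_comment: str | None = None) -> None:
    rows = [
        {
            "addition_index": 0, "added_volume_mL": 0.0,
            "s_co": series.blank.co, "s_cross": series.blank.cross,
            "dark_co": series.dark_co, "dark_cross": series.dark_cross,
            "c_spec": np.nan,
        }
    ]
    for i, a in enumerate(series.additions, start=1):
        rows.append(
            {
                "addition_index": i, "added_volume_mL": a.added_volume_mL,
                "s_co": a.signal.co, "s_cross": a.signal.cross,
                "dark_co": series.dark_co, "dark_cross": series.dark_cross,
                "c_spec": np.nan if a.c_spec is None else a.c_spec,
            }
        )
    _write_csv(path, pd.DataFrame(rows, columns=LAB_COLUMNS), header_comment)


def write_reduction_csv(path, results: Sequence[tuple[str, DepolResult]],
                        header_comment: str | None = None) -> None:
    """Write reduced series: sample_id, delta_p, ci95, m22, n_additions."""
    rows = [
        {
            "sample_id": sid, "delta_p": r.delta_p, "ci95": r.ci95_delta,
            "m22": r.m22, "n_additions": r.n_additions,
        }
        for sid, r in results
    ]
    _write_csv(path, pd.DataFrame(
        rows, columns=["sample_id", "delta_p", "ci95", "m22", "n_additions"]),
        header_comment)


def _write_csv(path, df: pd.DataFrame, header_comment: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def load_constants(path) -> ModelConstants:
    """Load model constants from JSON or YAML, overriding the defaults."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        return ModelConstants()
    valid = {f.name for f in dataclasses.fields(ModelConstants)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"{path}: unknown constant(s) {sorted(unknown)}")
    return ModelConstants(**data)
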