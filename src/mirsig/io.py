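"""Plain-text interchange formats for every pipeline table.

Count matrices: TSV, probes as rows, first columns ``probe`` and
``probe_class``, then one column per lane named ``<sample_id>:<replicate>``.
Ct matrices: TSV with ``assay`` and ``reference`` annotation columns, samples
as columns. Sample sheets: CSV with header ``sample_id,cohort,diagnosis``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ASSAY_ROLES,
    PROBE_CLASSES,
    CountMatrix,
    CtMatrix,
    SampleSheet,
    ValidationError,
)


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValidationError(f"{path}: malformed TSV ({exc})") from exc


def write_count_matrix(m: CountMatrix, path) -> Path:
    path = Path(path)
    out = m.counts.copy()
    out.insert(0, "probe_class", m.probe_class)
    out.index.name = "probe"
    out.reset_index().to_csv(path, sep="\t", index=False)
    return path


def read_count_matrix(path) -> CountMatrix:
    path = Path(path)
    raw = _read_tsv(path)
    for col in ("probe", "probe_class"):
        if col not in raw.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    dupes = raw["probe"][raw["probe"].duplicated()]
    if len(dupes):
        line = int(dupes.index[0]) + 2  # header is line 1
        raise ValidationError(
            f"{path}: duplicate probe name {dupes.iloc[0]!r} at line {line}"
        )
    bad_class = ~raw["probe_class"].isin(PROBE_CLASSES)
    if bad_class.any():
        i = int(np.flatnonzero(bad_class)[0])
        raise ValidationError(
            f"{path}: unknown probe_class {raw['probe_class'].iloc[i]!r} "
            f"at line {i + 2}"
        )
    lane_cols = [c for c in raw.columns if c not in ("probe", "probe_class")]
    try:
        counts = raw[lane_cols].astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric count value ({exc})") from exc
    if (counts.to_numpy() < 0).any():
        r, _ = np.argwhere(counts.to_numpy() < 0)[0]
        raise ValidationError(f"{path}: negative count at line {int(r) + 2}")
    counts.index = pd.Index(raw["probe"].to_numpy())
    lanes = pd.DataFrame(
        {
            "lane_id": lane_cols,
            "sample_id": [c.rsplit(":", 1)[0] for c in lane_cols],
            "replicate": [
                int(c.rsplit(":", 1)[1]) if ":" in c else 1 for c in lane_cols
            ],
        }
    ).set_index("lane_id")
    probe_class = pd.Series(raw["probe_class"].to_numpy(), index=counts.index)
    return CountMatrix(counts, probe_class, lanes)


def write_ct_matrix(m: CtMatrix, path) -> Path:
    path = Path(path)
    out = m.ct.copy()
    out.insert(0, "reference", m.assay_role)
    out.index.name = "assay"
    out.reset_index().to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def read_ct_matrix(path) -> CtMatrix:
    path = Path(path)
    raw = _read_tsv(path)
    for col in ("assay", "reference"):
        if col not in raw.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    bad = ~raw["reference"].isin(ASSAY_ROLES)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"{path}: unknown reference token {raw['reference'].iloc[i]!r} "
            f"at line {i + 2}"
        )
    sample_cols = [c for c in raw.columns if c not in ("assay", "reference")]
    ct = raw[sample_cols].replace("NA", np.nan).astype(float)
    ct.index = pd.Index(raw["assay"].to_numpy())
    role = pd.Series(raw["reference"].to_numpy(), index=ct.index)
    return CtMatrix(ct, role)


def write_sample_sheet(sheet: SampleSheet, path) -> Path:
    path = Path(path)
    sheet.table[["sample_id", "cohort", "diagnosis"]].to_csv(path, index=False)
    return path


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, dtype={"sample_id": str}))


def write_relative_expression(rel, path) -> Path:
    """Long-format TSV: sample_id, mirna, dct, ddct, linear_fc."""
    path = Path(path)
    long = rel.dct.stack(future_stack=True).rename("dct").reset_index()
    long.columns = ["mirna", "sample_id", "dct"]
    if rel.ddct is not None:
        long["ddct"] = rel.ddct.stack(future_stack=True).to_numpy()
        long["linear_fc"] = rel.linear_fc.stack(future_stack=True).to_numpy()
    long[["sample_id", "mirna"] + [c for c in ("dct", "ddct", "linear_fc") if c in long]].to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )
    return path
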