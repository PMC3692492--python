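"""CSV input/output for two-group data and simulation fixtures.

The interchange format is a plain CSV with a header and two columns: a group
label and a numeric value (defaults ``group,value``), one row per patient.
This is the audience-appropriate stand-in for a spreadsheet of raw study
data: anything exportable from Excel/LibreOffice round-trips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .manipulations import ManipulationSpec, TwoGroupStudy, apply_manipulation

__all__ = [
    "GroupedDataFile",
    "TwoGroupData",
    "read_two_group_csv",
    "write_study_csv",
    "generate_fixture",
]


@dataclass(frozen=True)
class GroupedDataFile:
    """Location and parsing options of a two-group CSV file."""

    path: str | Path
    group_column: str = "group"
    value_column: str = "value"
    delimiter: str = ","


@dataclass(frozen=True)
class TwoGroupData:
    """Parsed two-group data, oriented by observed sample means.

    ``study.group_high`` holds the group with the larger *observed* mean
    (the Tadpole orientation); the original file labels are preserved.
    ``n_dropped`` counts rows rejected for missing values.
    """

    study: TwoGroupStudy
    n_dropped: int


def read_two_group_csv(file: GroupedDataFile | str | Path) -> TwoGroupData:
    """Read a two-group CSV into a :class:`TwoGroupStudy`.

    Exactly two distinct group labels are required; rows with a missing
    group or value are dropped (and counted); non-numeric values raise with
    the offending row numbers.  The higher observed-mean group becomes
    ``group_high`` -- orientation is by the data, never by user assertion.
    """
    if not isinstance(file, GroupedDataFile):
        file = GroupedDataFile(path=file)
    path = Path(file.path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep=file.delimiter, dtype=str, skipinitialspace=True)
    for col in (file.group_column, file.value_column):
        if col not in df.columns:
            raise ValueError(
                f"{path}: missing column {col!r}; found {list(df.columns)}"
            )
    raw_n = len(df)
    df = df.dropna(subset=[file.group_column, file.value_column])
    n_dropped = raw_n - len(df)
    values = pd.to_numeric(df[file.value_column], errors="coerce")
    bad = values.isna() | ~np.isfinite(values.fillna(np.inf))
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad][:10]]  # +2: header + 1-based
        raise ValueError(f"{path}: non-numeric or non-finite values at rows {rows}")
    labels = sorted(df[file.group_column].unique())
    if len(labels) != 2:
        raise ValueError(
            f"{path}: expected exactly 2 group labels, found {len(labels)}: {labels}"
        )
    groups = {
        lab: values[df[file.group_column] == lab].to_numpy(dtype=float)
        for lab in labels
    }
    a, b = labels
    if groups[a].mean() >= groups[b].mean():
        hi, lo = a, b
    else:
        hi, lo = b, a
    study = TwoGroupStudy(
        group_high=groups[hi], group_low=groups[lo], labels=(hi, lo)
    )
    return TwoGroupData(study=study, n_dropped=n_dropped)


def write_study_csv(
    study: TwoGroupStudy,
    path: str | Path,
    *,
    group_column: str = "group",
    value_column: str = "value",
) -> Path:
    """Write a study to the interchange CSV (stable row and column order)."""
    path = Path(path)
    hi, lo = study.labels
    df = pd.DataFrame(
        {
            group_column: [hi] * study.group_high.size + [lo] * study.group_low.size,
            value_column: np.concatenate([study.group_high, study.group_low]),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def generate_fixture(
    kind: str,
    n: int,
    k: int,
    seed: int,
    path: str | Path,
    *,
    icc: float = 0.5,
) -> GroupedDataFile:
    """Write a simulated, optionally manipulated, two-group CSV fixture.

    Draws a null study (both groups N(0,1), size ``n``), applies the
    requested manipulation at count ``k``, writes the CSV, and records a
    sidecar ``<path>.meta.json`` with everything needed to regenerate the
    file bit-for-bit (kind, n, k, icc, seed, package version).
    """
    from . import __version__
    from .engine import generate_null_study

    rng = np.random.default_rng(seed)
    study = generate_null_study(n, rng)
    spec = ManipulationSpec(kind=kind, k=k, icc=icc)
    study = apply_manipulation(study, spec, rng)
    path = Path(path)
    write_study_csv(study, path)
    meta = {
        "kind": kind,
        "n_per_group": n,
        "k": k,
        "icc": icc,
        "seed": seed,
        "version": __version__,
    }
    Path(f"{path}.meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return GroupedDataFile(path=path)
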