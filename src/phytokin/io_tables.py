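"""Reading, validation and reshaping of the three kinematics input tables.

The workflow consumes three tab-delimited text files:

* **leaf lengths** — one row per plant (`plant_id`), one column per
  measurement time; headers are timestamps in ``yyyy/mm/dd hh:mm`` or
  ``yyyy/mm/dd hh:mm:ss`` format, values are whole-leaf lengths in mm,
  missing entries allowed;
* **cell lengths** — stacked records with columns `plant_id`, `position`
  (cm from the leaf base) and `cell_length` (µm);
* **meristem sizes** — columns `plant_id` and `mer_length_um` (µm), one row
  per plant.

Column names and units are enforced strictly: silent unit mix-ups are the
classic failure mode of this analysis.  Numbers use ``.`` as the decimal
separator; a ``,`` raises a targeted error because locale-configured
spreadsheet exports are a common source of broken files.  Files are read as
UTF-8, tolerating a byte-order mark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

__all__ = [
    "LeafLengthTable",
    "ValidationReport",
    "TableFormatError",
    "ValidationError",
    "read_leaf_lengths",
    "write_leaf_lengths",
    "read_cell_lengths",
    "write_cell_lengths",
    "read_meristem_sizes",
    "write_meristem_sizes",
    "validate_inputs",
    "tidy_to_wide",
    "wide_to_tidy",
]

#: tokens read as a missing measurement (robustness to spreadsheet exports)
MISSING_TOKENS = frozenset({"", "NA", "na", "NaN", "nan"})

#: accepted timestamp layouts for leaf-length column headers
TIME_FORMATS = ("%Y/%m/%d %H:%M", "%Y/%m/%d %H:%M:%S")

#: significant digits used when writing numeric table cells
OUTPUT_DIGITS = 6


class TableFormatError(ValueError):
    """A file does not conform to the required tabular layout."""


class ValidationError(ValueError):
    """Structurally parseable data that violates a content rule."""


@dataclass
class LeafLengthTable:
    """Per-plant leaf-length time series.

    ``data`` holds one row per plant (index: plant_id) and one column per
    timepoint (a timezone-naive DatetimeIndex, strictly increasing); values
    are leaf lengths in mm with NaN for missing measurements.
    """

    data: pd.DataFrame

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique()
            raise ValidationError(f"duplicate plant_id: {', '.join(map(str, dups))}")
        self.data = self.data.sort_index(axis=1)
        cols = pd.DatetimeIndex(self.data.columns)
        if not cols.is_monotonic_increasing or cols.has_duplicates:
            raise ValidationError("timepoints must be unique")
        self.data.columns = cols

    @property
    def plant_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def timepoints(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data.columns)

    def lengths(self, plant_id: str) -> np.ndarray:
        return self.data.loc[plant_id].to_numpy(dtype=float)


@dataclass
class ValidationReport:
    """Cross-file consistency findings.

    ``findings`` are conditions that will make the downstream kinematic
    analysis fail for some plant; ``warnings`` flag suspicious but workable
    data.  An empty ``findings`` list means all structural rules pass.
    """

    findings: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    plant_counts: pd.DataFrame | None = None

    @property
    def ok(self) -> bool:
        return not self.findings


def _parse_number(token: str, where: str, allow_missing: bool) -> float:
    tok = token.strip()
    if tok in MISSING_TOKENS:
        if allow_missing:
            return float("nan")
        raise TableFormatError(f"missing value not allowed at {where}")
    if "," in tok:
        raise TableFormatError(
            f"non-numeric value {tok!r} at {where}: decimal commas are not "
            "supported, use '.' as the decimal separator"
        )
    try:
        return float(tok)
    except ValueError:
        raise TableFormatError(f"non-numeric value {tok!r} at {where}") from None


def _parse_timestamp(token: str) -> datetime:
    tok = token.strip()
    for fmt in TIME_FORMATS:
        try:
            return datetime.strptime(tok, fmt)
        except ValueError:
            continue
    raise TableFormatError(
        f"malformed date-time column header {token!r}: expected "
        "'yyyy/mm/dd hh:mm' or 'yyyy/mm/dd hh:mm:ss'"
    )


def _read_raw(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8-sig"
    )


def _fmt(value: float) -> str:
    if value != value:  # NaN
        return ""
    return f"{value:.{OUTPUT_DIGITS}g}"


def read_leaf_lengths(path) -> LeafLengthTable:
    """Read a leaf-length file (first column `plant_id`, timestamp headers).

    Columns given out of chronological order are sorted; empty cells and
    NA tokens become missing values.
    """
    raw = _read_raw(path)
    if raw.columns[0] != "plant_id":
        raise TableFormatError(
            f"first column header must be 'plant_id', found {raw.columns[0]!r}"
        )
    if raw.shape[1] < 2:
        raise TableFormatError("leaf-length file has no measurement columns")
    times = [_parse_timestamp(c) for c in raw.columns[1:]]

    values = np.empty((len(raw), len(times)))
    for j, col in enumerate(raw.columns[1:]):
        for i, tok in enumerate(raw[col]):
            v = _parse_number(tok, f"row {i + 2}, column {col!r}", allow_missing=True)
            if v == v and v < 0:
                raise ValidationError(
                    f"negative leaf length {v} at row {i + 2}, column {col!r}"
                )
            values[i, j] = v
    frame = pd.DataFrame(values, index=raw["plant_id"].str.strip(), columns=times)
    frame.index.name = "plant_id"
    return LeafLengthTable(frame)


def write_leaf_lengths(table: LeafLengthTable, path) -> None:
    """Write a leaf-length table back to its tab-delimited form."""
    cols = []
    for t in table.timepoints:
        fmt = TIME_FORMATS[1] if t.second else TIME_FORMATS[0]
        cols.append(t.strftime(fmt))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["plant_id", *cols]) + "\n")
        for pid in table.plant_ids:
            row = [_fmt(v) for v in table.lengths(pid)]
            fh.write("\t".join([str(pid), *row]) + "\n")


def _read_two_or_three_column(
    path, expected: tuple[str, ...], ignore_extra_columns: bool
) -> pd.DataFrame:
    raw = _read_raw(path)
    found = list(raw.columns)
    if found[: len(expected)] != list(expected):
        raise TableFormatError(
            f"expected columns {list(expected)}, found {found}"
        )
    extra = found[len(expected) :]
    if extra and not ignore_extra_columns:
        raise TableFormatError(
            f"unrecognized extra columns {extra}; pass "
            "ignore_extra_columns=True to drop them"
        )
    out = raw[list(expected)].copy()
    out["plant_id"] = out["plant_id"].str.strip()
    for col in expected[1:]:
        out[col] = [
            _parse_number(tok, f"row {i + 2}, column {col!r}", allow_missing=False)
            for i, tok in enumerate(out[col])
        ]
    return out


def read_cell_lengths(path, ignore_extra_columns: bool = False) -> pd.DataFrame:
    """Read stacked cell-length measurements.

    Returns a DataFrame with columns plant_id, position (cm), cell_length
    (µm) in file order.  Duplicate (plant_id, position) rows are legal:
    several cells are measured at each sampling location.
    """
    out = _read_two_or_three_column(
        path, ("plant_id", "position", "cell_length"), ignore_extra_columns
    )
    bad = out.index[out["position"] < 0]
    if len(bad):
        raise ValidationError(f"negative position at row {bad[0] + 2}")
    bad = out.index[out["cell_length"] <= 0]
    if len(bad):
        raise ValidationError(f"non-positive cell_length at row {bad[0] + 2}")
    return out


def write_cell_lengths(cells: pd.DataFrame, path) -> None:
    _write_records(cells, ("plant_id", "position", "cell_length"), path)


def read_meristem_sizes(path, ignore_extra_columns: bool = False) -> pd.DataFrame:
    """Read per-plant meristem lengths (µm); plant ids must be unique."""
    out = _read_two_or_three_column(
        path, ("plant_id", "mer_length_um"), ignore_extra_columns
    )
    if out["plant_id"].duplicated().any():
        dups = out.loc[out["plant_id"].duplicated(), "plant_id"].unique()
        raise ValidationError(
            f"duplicate plant_id in meristem file: {', '.join(dups)}"
        )
    bad = out.index[out["mer_length_um"] <= 0]
    if len(bad):
        raise ValidationError(
            f"meristem length must be positive, offending row {bad[0] + 2}"
        )
    return out


def write_meristem_sizes(mer: pd.DataFrame, path) -> None:
    _write_records(mer, ("plant_id", "mer_length_um"), path)


def _write_records(frame: pd.DataFrame, columns: tuple[str, ...], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for _, row in frame[list(columns)].iterrows():
            cells = [str(row[columns[0]])] + [_fmt(row[c]) for c in columns[1:]]
            fh.write("\t".join(cells) + "\n")


def validate_inputs(
    leaf: LeafLengthTable, cells: pd.DataFrame, mer: pd.DataFrame
) -> ValidationReport:
    """Cross-check plant ids and measurement counts across the three files.

    Plants with cell-length data but no leaf-length or meristem entry are
    reported as findings (the kinematic analysis would fail for them);
    plants with fewer than two leaf-length measurements get a warning
    because no elongation rate can be computed.
    """
    report = ValidationReport()
    cell_ids = list(dict.fromkeys(cells["plant_id"]))
    leaf_ids = set(leaf.plant_ids)
    mer_ids = set(mer["plant_id"])
    for pid in cell_ids:
        if pid not in leaf_ids:
            report.findings.append(f"{pid} missing leaf-length measurements")
        if pid not in mer_ids:
            report.findings.append(f"{pid} missing meristem size")
    for pid in leaf.plant_ids:
        n = int(np.isfinite(leaf.lengths(pid)).sum())
        if n < 2:
            report.warnings.append(
                f"{pid} has {n} leaf-length measurement(s): cannot compute any LER"
            )
    counts = pd.DataFrame(
        {
            "plant_id": cell_ids,
            "n_cell_lengths": [
                int((cells["plant_id"] == pid).sum()) for pid in cell_ids
            ],
            "n_leaf_lengths": [
                int(np.isfinite(leaf.lengths(pid)).sum()) if pid in leaf_ids else 0
                for pid in cell_ids
            ],
            "has_meristem": [pid in mer_ids for pid in cell_ids],
        }
    )
    report.plant_counts = counts
    return report


def tidy_to_wide(
    records: pd.DataFrame,
    index: str = "plant_id",
    key: str | None = None,
    value: str | None = None,
) -> pd.DataFrame:
    """Pivot tidy (index, key, value) records to a wide matrix.

    Missing (index, key) combinations become missing cells; conflicting
    duplicates raise.  Defaults take key/value from the second and third
    columns.
    """
    cols = list(records.columns)
    key = key or cols[1]
    value = value or cols[2]
    dup = records.duplicated(subset=[index, key], keep=False)
    if dup.any():
        conflicting = records[dup].groupby([index, key])[value].nunique()
        if (conflicting > 1).any():
            pair = conflicting[conflicting > 1].index[0]
            raise ValidationError(
                f"conflicting duplicate records for ({pair[0]}, {pair[1]})"
            )
        records = records.drop_duplicates(subset=[index, key])
    return records.pivot(index=index, columns=key, values=value)


def wide_to_tidy(
    table: pd.DataFrame,
    index: str = "plant_id",
    key: str = "key",
    value: str = "value",
) -> pd.DataFrame:
    """Melt a wide matrix back to tidy records, dropping missing cells."""
    tidy = table.rename_axis(index=index, columns=key).stack().rename(value)
    return tidy.reset_index()
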