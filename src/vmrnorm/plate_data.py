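"""Data model and I/O for plate-based activity time series and light maps.

The in-memory containers are plain :class:`pandas.DataFrame` objects with a
fixed column schema. An *activity table* holds one row per larva x second of
Burst Duration (the fraction of video frames within one second in which a
larva moved), together with the grouping metadata needed by the
normalization models: strain, developmental stage (dpf), biological
replicate (batch), trial, stimulus type and well address. A *light map* is a
:class:`pandas.Series` of per-well stimulus intensity (W/m^2) covering all
96 wells of a standard 8x12 plate.

Time convention: the light change falls between ``t = 0`` and ``t = 1``;
pre-stimulus seconds are ``t in {-29..0}`` and post-stimulus seconds are
``t in {1..30}``. Each integer ``t`` indexes one 1-second bin.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "WellAddress",
    "PlateDataError",
    "ROW_LABELS",
    "N_COLUMNS",
    "N_WELLS",
    "ACTIVITY_COLUMNS",
    "DEFAULT_GROUPING",
    "DEFAULT_WINDOW",
    "DEFAULT_BASELINE_WINDOW",
    "parse_well_address",
    "all_wells",
    "read_activity_table",
    "write_activity_table",
    "validate_activity_table",
    "read_light_map",
    "write_light_map",
    "light_map_from_array",
    "validate_light_map",
    "join_light",
    "subset_window",
    "group_keys",
]

ROW_LABELS = "ABCDEFGH"
N_COLUMNS = 12
N_WELLS = len(ROW_LABELS) * N_COLUMNS

#: Required columns of an activity table, in canonical order.
ACTIVITY_COLUMNS = [
    "larva_id",
    "well",
    "strain",
    "stage_dpf",
    "batch",
    "trial",
    "stimulus",
    "t",
    "activity",
]

#: Default grouping scheme: models are fitted separately per
#: strain x stage x stimulus cell; trials are pooled and batch is a
#: predictor, never a grouping factor.
DEFAULT_GROUPING = ["strain", "stage_dpf", "stimulus"]

#: Default analysis window in seconds relative to the light change.
DEFAULT_WINDOW = (-30, 30)

#: Default baseline window: the last 30 pre-change seconds.
DEFAULT_BASELINE_WINDOW = (-29, 0)

_WELL_RE = re.compile(r"^\s*([A-Ha-h])\s*0*([1-9]\d?)\s*$")


class PlateDataError(ValueError):
    """Malformed or invariant-violating plate data."""


class WellAddress(NamedTuple):
    """One well of an 8x12 plate, e.g. ``WellAddress('A', 1)``."""

    row: str
    column: int

    def __str__(self) -> str:  # "A1" .. "H12"
        return f"{self.row}{self.column}"


def parse_well_address(text: str) -> WellAddress:
    """Parse a well label such as ``"A1"`` or ``"h12"`` (case-insensitive).

    Raises
    ------
    PlateDataError
        If the text is not a letter A-H followed by a column 1-12.
    """
    m = _WELL_RE.match(str(text))
    if m is None:
        raise PlateDataError(f"malformed well address: {text!r}")
    row = m.group(1).upper()
    column = int(m.group(2))
    if column > N_COLUMNS:
        raise PlateDataError(
            f"well address {text!r}: column {column} outside 1..{N_COLUMNS}"
        )
    return WellAddress(row, column)


def all_wells() -> list[WellAddress]:
    """The 96 well addresses in row-major order (A1..A12, B1, ..., H12)."""
    return [
        WellAddress(r, c) for r in ROW_LABELS for c in range(1, N_COLUMNS + 1)
    ]


# ---------------------------------------------------------------------------
# activity tables


def validate_activity_table(df: pd.DataFrame, raw: bool = True) -> pd.DataFrame:
    """Validate schema and invariants of an activity table.

    Parameters
    ----------
    df : DataFrame
        Candidate table.
    raw : bool
        If True the activities are un-normalized Burst Durations and must
        lie in [0, 1]. Normalized tables (``raw=False``) are exempt from the
        upper bound; no clipping is ever applied.

    Returns
    -------
    DataFrame
        The validated table with canonical dtypes and well labels.
    """
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise PlateDataError(f"activity table missing column(s): {missing}")
    out = df.copy()
    out["well"] = [str(parse_well_address(w)) for w in out["well"]]
    for col in ("stage_dpf", "trial", "t"):
        out[col] = pd.to_numeric(out[col], errors="raise").astype(int)
    out["activity"] = pd.to_numeric(out["activity"], errors="raise").astype(float)

    dup = out.duplicated(subset=["larva_id", "trial", "t"])
    if dup.any():
        rows = (out.index[dup] + 0).tolist()[:10]
        raise PlateDataError(
            f"duplicate (larva_id, trial, t) at row index(es) {rows}"
        )
    if out["activity"].isna().any():
        rows = out.index[out["activity"].isna()].tolist()[:10]
        raise PlateDataError(f"missing activity at row index(es) {rows}")
    if raw:
        bad = (out["activity"] < 0) | (out["activity"] > 1)
        if bad.any():
            rows = out.index[bad].tolist()[:10]
            raise PlateDataError(
                "raw activity outside [0, 1] at row index(es) "
                f"{rows}: {out.loc[rows, 'activity'].tolist()}"
            )
    out.attrs.setdefault("provenance", list(df.attrs.get("provenance", [])))
    return out


def read_activity_table(
    path,
    dialect: Mapping[str, str] | None = None,
    raw: bool = True,
) -> pd.DataFrame:
    """Read a long-format activity CSV (one row per larva x second).

    ``dialect`` maps canonical column names to the names used in the file,
    e.g. ``{"activity": "burdur"}`` — export headers of tracking software
    vary. Missing mapping entries default to the canonical names.
    """
    df = pd.read_csv(path)
    if dialect:
        rename = {v: k for k, v in dialect.items() if v in df.columns}
        df = df.rename(columns=rename)
    df = validate_activity_table(df, raw=raw)
    df.attrs["provenance"] = [f"read_activity_table({path})"]
    return df


def write_activity_table(df: pd.DataFrame, path) -> None:
    """Write an activity table as UTF-8 CSV with '.' decimals and LF endings."""
    cols = ACTIVITY_COLUMNS + [
        c for c in df.columns if c not in ACTIVITY_COLUMNS
    ]
    df.to_csv(path, index=False, columns=cols, lineterminator="\n",
              float_format="%.12g", encoding="utf-8")


# ---------------------------------------------------------------------------
# light maps


def validate_light_map(lm: pd.Series, for_fitting: bool = False) -> pd.Series:
    """Check completeness (all 96 wells) and non-negativity of a light map."""
    lm = pd.Series(
        {str(parse_well_address(w)): float(v) for w, v in lm.items()},
        name="intensity_w_m2",
    )
    expected = {str(w) for w in all_wells()}
    missing = sorted(expected - set(lm.index))
    if missing:
        raise PlateDataError(f"light map missing well(s): {missing[:10]}")
    extra = sorted(set(lm.index) - expected)
    if extra:
        raise PlateDataError(f"light map has unknown well(s): {extra[:10]}")
    if (lm < 0).any():
        bad = lm.index[lm < 0].tolist()
        raise PlateDataError(f"negative intensity at well(s): {bad[:10]}")
    if for_fitting and lm.nunique() == 1:
        raise PlateDataError(
            "light map is constant across all wells; degenerate predictor"
        )
    order = [str(w) for w in all_wells()]
    return lm.loc[order]


def light_map_from_array(grid: np.ndarray) -> pd.Series:
    """Build a light map from an 8x12 array in plate orientation (rows A-H)."""
    grid = np.asarray(grid, dtype=float)
    if grid.shape != (len(ROW_LABELS), N_COLUMNS):
        raise PlateDataError(
            f"expected {len(ROW_LABELS)}x{N_COLUMNS} grid, got {grid.shape}"
        )
    data = {
        f"{ROW_LABELS[i]}{j + 1}": grid[i, j]
        for i in range(len(ROW_LABELS))
        for j in range(N_COLUMNS)
    }
    return validate_light_map(pd.Series(data))


def read_light_map(path) -> pd.Series:
    """Read a per-well light-intensity CSV (W/m^2).

    Two dialects are accepted: a grid (8 data rows labelled A-H, 12 columns
    labelled 1-12) and a long table with columns ``well`` and
    ``intensity_w_m2`` (or ``intensity``).
    """
    df = pd.read_csv(path)
    lower = [str(c).strip().lower() for c in df.columns]
    if "well" in lower:
        df.columns = lower
        value_col = "intensity_w_m2" if "intensity_w_m2" in lower else "intensity"
        if value_col not in lower:
            raise PlateDataError(
                "long-format light map needs an 'intensity_w_m2' or "
                "'intensity' column"
            )
        return validate_light_map(pd.Series(
            df[value_col].to_numpy(float), index=df["well"].astype(str)
        ))
    # grid dialect: first column holds the row labels A..H
    grid = pd.read_csv(path, index_col=0)
    if len(grid) != len(ROW_LABELS):
        raise PlateDataError(f"expected {len(ROW_LABELS)} rows, got {len(grid)}")
    if grid.shape[1] != N_COLUMNS:
        raise PlateDataError(
            f"expected {N_COLUMNS} columns, got {grid.shape[1]}"
        )
    data = {}
    for row_label, row in grid.iterrows():
        for col_label, v in row.items():
            data[f"{str(row_label).strip().upper()}{int(col_label)}"] = float(v)
    return validate_light_map(pd.Series(data))


def write_light_map(lm: pd.Series, path, dialect: str = "long") -> None:
    """Write a light map in the long (default) or grid CSV dialect."""
    lm = validate_light_map(lm)
    if dialect == "long":
        out = pd.DataFrame(
            {"well": lm.index, "intensity_w_m2": lm.to_numpy()}
        )
        out.to_csv(path, index=False, lineterminator="\n",
                   float_format="%.12g", encoding="utf-8")
    elif dialect == "grid":
        grid = pd.DataFrame(
            lm.to_numpy().reshape(len(ROW_LABELS), N_COLUMNS),
            index=list(ROW_LABELS),
            columns=range(1, N_COLUMNS + 1),
        )
        grid.to_csv(path, lineterminator="\n", float_format="%.12g",
                    encoding="utf-8")
    else:
        raise ValueError(f"unknown light-map dialect: {dialect!r}")


def join_light(df: pd.DataFrame, lm: pd.Series) -> pd.DataFrame:
    """Attach per-record light intensity (column ``light_intensity``).

    Idempotent: an existing ``light_intensity`` column is overwritten from
    the map. Every record's well must resolve in the map.
    """
    lm = validate_light_map(lm)
    out = df.copy()
    out["light_intensity"] = out["well"].map(lm)
    if out["light_intensity"].isna().any():
        bad = sorted(out.loc[out["light_intensity"].isna(), "well"].unique())
        raise PlateDataError(f"well(s) not in light map: {bad[:10]}")
    return out


# ---------------------------------------------------------------------------
# windows and grouping


def subset_window(df: pd.DataFrame, t_min: int, t_max: int) -> pd.DataFrame:
    """Records with ``t_min <= t <= t_max`` (closed interval of second bins)."""
    if t_min > t_max:
        raise ValueError(f"empty window: t_min={t_min} > t_max={t_max}")
    out = df[(df["t"] >= t_min) & (df["t"] <= t_max)].copy()
    prov = list(df.attrs.get("provenance", []))
    prov.append(f"subset_window([{t_min}, {t_max}])"
                + (" -> EMPTY" if out.empty else ""))
    out.attrs["provenance"] = prov
    return out


def group_keys(df: pd.DataFrame, grouping: Iterable[str] = DEFAULT_GROUPING):
    """Sorted distinct group keys (tuples) under a grouping scheme."""
    grouping = list(grouping)
    return sorted(
        tuple(k) for k in df[grouping].drop_duplicates().itertuples(index=False)
    )
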