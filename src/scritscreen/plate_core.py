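"""Plate data model: 96-well layouts, dose series, and per-cell feature tables.

A screening plate is an 8 x 12 grid of wells, each holding one treatment:
a compound at a dose in one nutrient condition (glucose medium, ``glu_plus``,
or galactose-substituted medium, ``glu_minus``), or a control.  Positive
controls are wells treated with the uncoupler FCCP at 75 uM; negative
controls carry vehicle (DMSO) only, i.e. dose 0.

Per-cell measurements are stored in a :class:`CellFeatureTable`: one row per
segmented cell, with the seven fluorescence / morphology features used by the
downstream statistics (TMRM peripheral integral and max pixel, Hoechst
integral and mean, nuclear area and circularity, TO-PRO-3 mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, DomainError, FormatError

__all__ = [
    "ROW_LETTERS",
    "CONDITIONS",
    "ROLES",
    "FEATURE_COLUMNS",
    "ID_COLUMNS",
    "POSITIVE_CONTROL_DOSE",
    "WellAssignment",
    "PlateLayout",
    "DoseSeries",
    "CellFeatureTable",
    "well_id",
    "parse_well_id",
    "dose_series",
    "build_control_plate",
    "build_dose_response_plate",
    "build_primary_screen_plate",
    "read_feature_table",
    "write_feature_table",
]

ROW_LETTERS = "ABCDEFGH"
CONDITIONS = ("glu_plus", "glu_minus")
ROLES = ("negative_control", "positive_control", "test")

#: Dose (uM) applied to FCCP positive-control wells.
POSITIVE_CONTROL_DOSE = 75.0

#: Mandatory per-cell feature columns, in canonical order.
FEATURE_COLUMNS = (
    "tmrm_peripheral_integral",
    "tmrm_max_pixel",
    "hoechst_integral",
    "hoechst_mean",
    "nuclear_area",
    "nuclear_circularity",
    "topro_mean",
)

#: Identifier columns preceding the features.
ID_COLUMNS = ("well", "field", "cell")


def well_id(row: int, col: int) -> str:
    """Return the plate-convention well id for 1-based *row*, *col* (e.g. ``A01``)."""
    if not (1 <= row <= 8 and 1 <= col <= 12):
        raise DomainError(f"well position out of range: row={row}, col={col}")
    return f"{ROW_LETTERS[row - 1]}{col:02d}"


def parse_well_id(wid: str) -> tuple[int, int]:
    """Inverse of :func:`well_id`; returns 1-based (row, col)."""
    wid = wid.strip().upper()
    if len(wid) < 2 or wid[0] not in ROW_LETTERS or not wid[1:].isdigit():
        raise DomainError(f"malformed well id: {wid!r}")
    row = ROW_LETTERS.index(wid[0]) + 1
    col = int(wid[1:])
    if not 1 <= col <= 12:
        raise DomainError(f"column out of range in well id: {wid!r}")
    return row, col


@dataclass(frozen=True)
class WellAssignment:
    """Treatment of a single well."""

    well: str
    compound: str | None
    dose: float  # uM
    condition: str
    role: str  # one of ROLES

    def __post_init__(self) -> None:
        parse_well_id(self.well)
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown well role {self.role!r}")
        if self.dose < 0:
            raise ConfigurationError(f"negative dose in well {self.well}")
        if self.role == "negative_control" and self.dose != 0:
            raise ConfigurationError(
                f"negative control {self.well} must have dose 0, got {self.dose}"
            )


@dataclass
class PlateLayout:
    """Assignment of treatments to the wells of one 96-well plate."""

    wells: list[WellAssignment] = field(default_factory=list)
    n_rows: int = 8
    n_cols: int = 12
    plate_id: str = "plate"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for w in self.wells:
            if w.well in seen:
                raise ConfigurationError(f"well {w.well} assigned more than once")
            seen.add(w.well)

    # -- queries ---------------------------------------------------------
    def by_well(self) -> dict[str, WellAssignment]:
        return {w.well: w for w in self.wells}

    def wells_with_role(self, role: str) -> list[WellAssignment]:
        return [w for w in self.wells if w.role == role]

    def compounds(self) -> list[str]:
        out: list[str] = []
        for w in self.wells:
            if w.role == "test" and w.compound is not None and w.compound not in out:
                out.append(w.compound)
        return out

    def require_controls(self, min_each: int = 4) -> None:
        """Screening plates must carry enough controls for in-plate normalisation."""
        n_neg = len(self.wells_with_role("negative_control"))
        n_pos = len(self.wells_with_role("positive_control"))
        if n_neg < min_each or n_pos < min_each:
            raise ConfigurationError(
                f"plate {self.plate_id}: needs >= {min_each} controls of each kind, "
                f"got {n_pos} positive / {n_neg} negative"
            )

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "plate_id": self.plate_id,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "wells": [
                {
                    "well": w.well,
                    "compound": w.compound,
                    "dose": w.dose,
                    "condition": w.condition,
                    "role": w.role,
                }
                for w in self.wells
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlateLayout":
        return cls(
            wells=[WellAssignment(**w) for w in d["wells"]],
            n_rows=int(d.get("n_rows", 8)),
            n_cols=int(d.get("n_cols", 12)),
            plate_id=str(d.get("plate_id", "plate")),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlateLayout":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class DoseSeries:
    """Geometric dilution series: dose_k = top / ratio**(k-1), k = 1..n_points."""

    top: float  # uM
    ratio: float  # dilution factor, > 1
    n_points: int

    def __post_init__(self) -> None:
        if self.top <= 0:
            raise DomainError(f"top dose must be positive, got {self.top}")
        if self.ratio <= 1:
            raise DomainError(f"dilution ratio must exceed 1, got {self.ratio}")
        if self.n_points < 1:
            raise DomainError(f"need at least one dose point, got {self.n_points}")

    def doses(self) -> list[float]:
        return [self.top / self.ratio**k for k in range(self.n_points)]


def dose_series(top: float, ratio: float, n_points: int) -> list[float]:
    """Strictly decreasing geometric dose series starting at *top* (uM).

    A 10-point 1:3 series from 100 uM bottoms out at 100/3**9 ~= 0.005 uM,
    the range used for the full dose-response screens.
    """
    return DoseSeries(top, ratio, n_points).doses()


def build_control_plate(
    n_cols_per_condition: int,
    condition: str = "glu_plus",
    plate_id: str = "control",
) -> PlateLayout:
    """Assay-development plate: whole columns of FCCP next to whole columns of DMSO.

    With ``n_cols_per_condition=6`` this reproduces the 48 positive / 48
    negative control plate used to estimate well-to-well variability and Z'.
    """
    if n_cols_per_condition < 1:
        raise ConfigurationError("need at least one column per condition")
    if 2 * n_cols_per_condition > 12:
        raise ConfigurationError(
            f"2 x {n_cols_per_condition} columns do not fit on a 12-column plate"
        )
    wells = []
    for col in range(1, 2 * n_cols_per_condition + 1):
        positive = col <= n_cols_per_condition
        for row in range(1, 9):
            wells.append(
                WellAssignment(
                    well=well_id(row, col),
                    compound="FCCP" if positive else None,
                    dose=POSITIVE_CONTROL_DOSE if positive else 0.0,
                    condition=condition,
                    role="positive_control" if positive else "negative_control",
                )
            )
    return PlateLayout(wells=wells, plate_id=plate_id)


def build_dose_response_plate(
    compounds: Sequence[str],
    series: DoseSeries,
    n_pos: int = 8,
    n_neg: int = 8,
    n_replicate_rows: int = 2,
    condition: str = "glu_plus",
    plate_id: str = "dose",
) -> PlateLayout:
    """Secondary-screen plate: two replicate dose rows per compound plus controls.

    Each compound occupies ``n_replicate_rows`` adjacent rows; doses run
    left-to-right from the top dose, one column per dose point.  Controls fill
    the right-most columns top-to-bottom, positives first.  The canonical
    layout (4 compounds x 10-point series x 2 rows + 8 + 8 controls) uses all
    96 wells.
    """
    n_c = len(compounds)
    n_test = n_c * n_replicate_rows * series.n_points
    if n_test + n_pos + n_neg > 96:
        raise ConfigurationError(
            f"{n_test} test + {n_pos + n_neg} control wells exceed 96"
        )
    n_control_cols = -(-(n_pos + n_neg) // 8)  # ceil
    if series.n_points + n_control_cols > 12:
        raise ConfigurationError(
            f"{series.n_points} dose columns + {n_control_cols} control columns "
            "exceed 12"
        )
    if n_c * n_replicate_rows > 8:
        raise ConfigurationError(
            f"{n_c} compounds x {n_replicate_rows} rows exceed 8 plate rows"
        )

    wells: list[WellAssignment] = []
    doses = series.doses()
    row = 1
    for comp in compounds:
        for _ in range(n_replicate_rows):
            for k, dose in enumerate(doses):
                wells.append(
                    WellAssignment(
                        well=well_id(row, k + 1),
                        compound=comp,
                        dose=dose,
                        condition=condition,
                        role="test",
                    )
                )
            row += 1

    # controls in the right-most columns, positives first, top-to-bottom
    slots = [
        (r, c)
        for c in range(12, 12 - n_control_cols, -1)
        for r in range(1, 9)
    ]
    for i in range(n_pos + n_neg):
        r, c = slots[i]
        positive = i < n_pos
        wells.append(
            WellAssignment(
                well=well_id(r, c),
                compound="FCCP" if positive else None,
                dose=POSITIVE_CONTROL_DOSE if positive else 0.0,
                condition=condition,
                role="positive_control" if positive else "negative_control",
            )
        )
    return PlateLayout(wells=wells, plate_id=plate_id)


def build_primary_screen_plate(
    compounds: Sequence[str],
    dose: float = 100.0,
    n_pos: int = 4,
    n_neg: int = 4,
    condition: str = "glu_plus",
    plate_id: str = "primary",
) -> PlateLayout:
    """Single-dose pre-screen plate: one well per compound at a high dose.

    The last column holds the controls (positives on top, negatives below),
    mirroring the primary-screen arrangement of four FCCP and four DMSO wells.
    """
    if n_pos + n_neg > 8:
        raise ConfigurationError("controls must fit in the last column")
    capacity = 96 - 8  # compounds avoid the control column entirely
    if len(compounds) > capacity:
        raise ConfigurationError(f"{len(compounds)} compounds exceed {capacity} wells")
    slots = [(r, c) for c in range(1, 12) for r in range(1, 9)]
    wells = [
        WellAssignment(
            well=well_id(*slots[i]),
            compound=comp,
            dose=dose,
            condition=condition,
            role="test",
        )
        for i, comp in enumerate(compounds)
    ]
    for i in range(n_pos + n_neg):
        positive = i < n_pos
        wells.append(
            WellAssignment(
                well=well_id(i + 1, 12),
                compound="FCCP" if positive else None,
                dose=POSITIVE_CONTROL_DOSE if positive else 0.0,
                condition=condition,
                role="positive_control" if positive else "negative_control",
            )
        )
    return PlateLayout(wells=wells, plate_id=plate_id)


# ---------------------------------------------------------------------------
# Per-cell feature tables
# ---------------------------------------------------------------------------


@dataclass
class CellFeatureTable:
    """Per-cell feature records for one or more plates.

    Thin wrapper around a :class:`pandas.DataFrame` with the mandatory
    identifier columns (``well``, ``field``, ``cell``) and the seven feature
    columns; extra columns are preserved untouched.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [
            c for c in (*ID_COLUMNS, *FEATURE_COLUMNS) if c not in self.frame.columns
        ]
        if missing:
            raise FormatError(f"feature table missing mandatory column(s): {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    def validate(self) -> None:
        """Check physical invariants: non-negative intensities, circularity in (0, 1]."""
        f = self.frame
        if len(f) == 0:
            return
        for col in FEATURE_COLUMNS:
            if col == "nuclear_circularity":
                continue
            if (f[col] < 0).any():
                raise FormatError(f"negative values in column {col!r}")
        circ = f["nuclear_circularity"]
        if ((circ <= 0) | (circ > 1)).any():
            raise FormatError("nuclear_circularity must lie in (0, 1]")

    def wells(self) -> list[str]:
        return list(pd.unique(self.frame["well"]))

    @classmethod
    def concat(cls, tables: Iterable["CellFeatureTable"]) -> "CellFeatureTable":
        frames = [t.frame for t in tables]
        if not frames:
            return cls.empty()
        return cls(pd.concat(frames, ignore_index=True))

    @classmethod
    def empty(cls) -> "CellFeatureTable":
        cols = [*ID_COLUMNS, *FEATURE_COLUMNS]
        return cls(pd.DataFrame({c: pd.Series(dtype=float) for c in cols}))


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_feature_table(path: str | Path) -> CellFeatureTable:
    """Read a TSV (default) or CSV per-cell feature table.

    Raises :class:`FormatError` naming the missing column when a mandatory
    feature is absent.
    """
    frame = pd.read_csv(path, sep=_sep_for(path))
    return CellFeatureTable(frame)


def write_feature_table(table: CellFeatureTable, path: str | Path) -> None:
    """Write a feature table; the round trip through read is lossless."""
    table.frame.to_csv(path, sep=_sep_for(path), index=False)
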