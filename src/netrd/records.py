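"""Data model and validated I/O for lab textile tests and field hole censuses.

Lab CSV schema (one row per net product)::

    net_id, brand, bursting_kpa, snag_n, abrasion_rubs, end_hole_mm, secondary_damage

Field CSV schema: ``net_id, brand, months_in_use`` plus EITHER band counts
``n1, n2, n3, n4`` OR a semicolon-separated ``hole_diameters_cm`` column,
never both.  Files are UTF-8, comma-separated, dot decimal separator.
JSON files carry a list of objects with the same keys.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .holes import RECORDING_THRESHOLD_CM, HoleCensus

__all__ = [
    "SecondaryDamage",
    "HoleEnlargementOutcome",
    "TextileTestResult",
    "FieldSurveyRecord",
    "RecordValidationError",
    "read_lab_records",
    "read_field_records",
    "write_report",
    "LAB_COLUMNS",
]


class RecordValidationError(ValueError):
    """A record file violated the documented schema."""


class SecondaryDamage(enum.Enum):
    """Secondary damage mode observed in the hole-enlargement test.

    Tearing combined with laddering and tearing combined with unravelling
    form a single category: both produce the largest field holes.
    """

    NONE = "none"
    LADDERING = "laddering"
    UNRAVELLING = "unravelling"
    TEARING_COMBINED = "tearing_combined"

    @classmethod
    def parse(cls, label: str) -> "SecondaryDamage":
        key = str(label).strip().lower().replace(" ", "_").replace("-", "_")
        aliases = {
            "none": cls.NONE,
            "laddering": cls.LADDERING,
            "unravelling": cls.UNRAVELLING,
            "unraveling": cls.UNRAVELLING,
            "tearing_combined": cls.TEARING_COMBINED,
            "tearing+laddering": cls.TEARING_COMBINED,
            "tearing+unravelling": cls.TEARING_COMBINED,
            "tearing+unraveling": cls.TEARING_COMBINED,
            "tearing_combined_with_laddering_or_unravelling": cls.TEARING_COMBINED,
        }
        if key not in aliases:
            raise ValueError(f"unknown secondary-damage label {label!r}")
        return aliases[key]


@dataclass(frozen=True)
class HoleEnlargementOutcome:
    """Result of the hole-enlargement test: final hole size and damage mode."""

    end_hole_size_mm: float
    secondary_damage: SecondaryDamage = SecondaryDamage.NONE

    def __post_init__(self) -> None:
        if not math.isfinite(self.end_hole_size_mm) or self.end_hole_size_mm < 0:
            raise ValueError(
                f"end_hole_size_mm must be finite and >= 0, got {self.end_hole_size_mm}"
            )
        if not isinstance(self.secondary_damage, SecondaryDamage):
            raise ValueError(f"invalid secondary damage {self.secondary_damage!r}")


@dataclass(frozen=True)
class TextileTestResult:
    """One net product's four laboratory textile-test values.

    ``bursting_strength_kpa`` (lambda_B), ``snag_strength_n`` (lambda_S)
    and ``abrasion_rubs`` (lambda_A) are summary values per net; replicate
    aggregation is the caller's responsibility.
    """

    net_id: str
    brand: str
    bursting_strength_kpa: float
    snag_strength_n: float
    abrasion_rubs: int
    hole_enlargement: HoleEnlargementOutcome

    def __post_init__(self) -> None:
        if not (math.isfinite(self.bursting_strength_kpa) and self.bursting_strength_kpa > 0):
            raise ValueError(
                f"bursting_strength_kpa must be > 0, got {self.bursting_strength_kpa}"
            )
        if not (math.isfinite(self.snag_strength_n) and self.snag_strength_n > 0):
            raise ValueError(f"snag_strength_n must be > 0, got {self.snag_strength_n}")
        if (
            not isinstance(self.abrasion_rubs, int)
            or isinstance(self.abrasion_rubs, bool)
            or self.abrasion_rubs < 0
        ):
            raise ValueError(
                f"abrasion_rubs must be a non-negative integer, got {self.abrasion_rubs!r}"
            )


@dataclass(frozen=True)
class FieldSurveyRecord:
    """Hole damage observed on one retrieved field net.

    ``holes`` is either a :class:`~netrd.holes.HoleCensus` of WHO band
    counts or a list of raw hole diameters in cm (each >= 0.5 cm, the WHO
    recording threshold); classification into bands is left to the
    hole-index machinery.
    """

    net_id: str
    brand: str
    months_in_use: float
    holes: Union[HoleCensus, tuple]

    def __post_init__(self) -> None:
        if not (math.isfinite(self.months_in_use) and self.months_in_use >= 0):
            raise ValueError(f"months_in_use must be >= 0, got {self.months_in_use}")
        if isinstance(self.holes, HoleCensus):
            return
        object.__setattr__(self, "holes", tuple(float(d) for d in self.holes))
        for d in self.holes:
            if not math.isfinite(d) or d < RECORDING_THRESHOLD_CM:
                raise ValueError(
                    f"hole diameter {d} cm is below the recording threshold "
                    f"({RECORDING_THRESHOLD_CM} cm) or not finite"
                )


LAB_COLUMNS = [
    "net_id",
    "brand",
    "bursting_kpa",
    "snag_n",
    "abrasion_rubs",
    "end_hole_mm",
    "secondary_damage",
]

_FIELD_BASE_COLUMNS = ["net_id", "brand", "months_in_use"]
_CENSUS_COLUMNS = ["n1", "n2", "n3", "n4"]
_DIAMETER_COLUMN = "hole_diameters_cm"


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("csv", "json"):
            raise ValueError(f"unsupported format {fmt!r}; use 'csv' or 'json'")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    return suffix if suffix in ("csv", "json") else "csv"


def _load_rows(path: Path, fmt: str) -> list[dict]:
    if fmt == "json":
        data = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(data, list):
            raise RecordValidationError(f"{path}: JSON root must be a list of objects")
        return data
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return df.to_dict(orient="records")


def _num(row: dict, field: str, row_idx: int, path: Path, kind=float):
    raw = row.get(field, "")
    try:
        value = kind(str(raw).strip()) if kind is not float else float(str(raw).strip())
        if kind is int:
            as_float = float(str(raw).strip())
            if as_float != int(as_float):
                raise ValueError
            value = int(as_float)
        return value
    except (TypeError, ValueError):
        raise RecordValidationError(
            f"{path}: row {row_idx}: field {field!r} has non-numeric value {raw!r}"
        ) from None


def read_lab_records(
    path: str | Path, format: str | None = None
) -> list[TextileTestResult]:
    """Read and validate a lab-panel file into ``TextileTestResult`` records.

    Row order is preserved.  Any schema violation (missing column,
    non-numeric value, unknown damage label) raises
    :class:`RecordValidationError` naming the row and field.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    rows = _load_rows(path, fmt)
    records: list[TextileTestResult] = []
    for i, row in enumerate(rows, start=1):
        missing = [c for c in LAB_COLUMNS if c not in row]
        if missing:
            raise RecordValidationError(
                f"{path}: row {i}: missing column(s) {', '.join(missing)}"
            )
        try:
            damage = SecondaryDamage.parse(row["secondary_damage"])
        except ValueError as exc:
            raise RecordValidationError(
                f"{path}: row {i}: field 'secondary_damage': {exc}"
            ) from None
        try:
            record = TextileTestResult(
                net_id=str(row["net_id"]),
                brand=str(row["brand"]),
                bursting_strength_kpa=_num(row, "bursting_kpa", i, path),
                snag_strength_n=_num(row, "snag_n", i, path),
                abrasion_rubs=_num(row, "abrasion_rubs", i, path, kind=int),
                hole_enlargement=HoleEnlargementOutcome(
                    end_hole_size_mm=_num(row, "end_hole_mm", i, path),
                    secondary_damage=damage,
                ),
            )
        except ValueError as exc:
            if isinstance(exc, RecordValidationError):
                raise
            raise RecordValidationError(f"{path}: row {i}: {exc}") from None
        records.append(record)
    return records


def read_field_records(
    path: str | Path, format: str | None = None
) -> list[FieldSurveyRecord]:
    """Read and validate a field-survey file into ``FieldSurveyRecord`` records.

    Each file encodes holes either as WHO band counts (columns n1..n4) or
    as raw diameters (semicolon-separated ``hole_diameters_cm``); a file
    presenting both encodings is rejected.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    rows = _load_rows(path, fmt)
    records: list[FieldSurveyRecord] = []
    for i, row in enumerate(rows, start=1):
        missing = [c for c in _FIELD_BASE_COLUMNS if c not in row]
        if missing:
            raise RecordValidationError(
                f"{path}: row {i}: missing column(s) {', '.join(missing)}"
            )
        has_census = any(c in row and str(row[c]).strip() != "" for c in _CENSUS_COLUMNS)
        has_diams = _DIAMETER_COLUMN in row and str(row[_DIAMETER_COLUMN]).strip() != ""
        if has_census and has_diams:
            raise RecordValidationError(
                f"{path}: row {i}: both band counts and raw diameters present; "
                "use exactly one encoding"
            )
        if not has_census and not has_diams:
            raise RecordValidationError(
                f"{path}: row {i}: no hole data (need n1..n4 or {_DIAMETER_COLUMN})"
            )
        if has_census:
            counts = []
            for c in _CENSUS_COLUMNS:
                v = _num(row, c, i, path, kind=int)
                if v < 0:
                    raise RecordValidationError(
                        f"{path}: row {i}: field {c!r} has negative count {v}"
                    )
                counts.append(v)
            holes: Union[HoleCensus, list] = HoleCensus(*counts)
        else:
            raw = row[_DIAMETER_COLUMN]
            if isinstance(raw, list):
                parts = [str(p) for p in raw]
            else:
                parts = [p for p in str(raw).split(";") if p.strip() != ""]
            try:
                holes = [float(p) for p in parts]
            except ValueError:
                raise RecordValidationError(
                    f"{path}: row {i}: field {_DIAMETER_COLUMN!r} has non-numeric "
                    f"value {raw!r}"
                ) from None
        try:
            record = FieldSurveyRecord(
                net_id=str(row["net_id"]),
                brand=str(row["brand"]),
                months_in_use=_num(row, "months_in_use", i, path),
                holes=holes,
            )
        except ValueError as exc:
            if isinstance(exc, RecordValidationError):
                raise
            raise RecordValidationError(f"{path}: row {i}: {exc}") from None
        records.append(record)
    return records


def _result_row(res) -> dict:
    """Flatten an RDResult or PHIResult to a report row with fixed rounding."""
    # RD reported to 1 dp, PHI to the nearest integer (it is integral anyway).
    if hasattr(res, "total"):  # RDResult
        row = {"net_id": res.net_id, "method": res.method}
        row.update({k: round(v, 4) for k, v in res.contributions.items()})
        row["total_rd"] = round(float(res.total), 1)
        return row
    if hasattr(res, "hole_index"):  # PHIResult
        row = {"net_id": res.net_id}
        n1, n2, n3, n4 = res.census.as_tuple()
        row.update({"n1": n1, "n2": n2, "n3": n3, "n4": n4})
        row.update(
            {f"contrib_size{b.value}": int(v) for b, v in res.contributions.items()}
        )
        row["hole_index"] = int(round(res.hole_index))
        return row
    raise TypeError(f"cannot report object of type {type(res).__name__}")


def write_report(results: Sequence, path: str | Path, format: str | None = None) -> Path:
    """Write scoring or PHI results as a deterministic CSV or JSON report.

    Output is byte-stable: input order preserved, fixed decimal places
    (RD totals to 1 dp, hole indices to the nearest integer).  Empty
    result collections are an error.
    """
    if len(results) == 0:
        raise ValueError("write_report requires a non-empty result collection")
    path = Path(path)
    fmt = _infer_format(path, format)
    rows = [_result_row(r) for r in results]
    if fmt == "json":
        path.write_text(json.dumps(rows, indent=2) + "\n", encoding="utf-8")
    else:
        df = pd.DataFrame(rows)
        # 1 dp for RD totals; counts/indices stay integers
        if "total_rd" in df.columns:
            df["total_rd"] = df["total_rd"].map(lambda v: f"{v:.1f}")
        df.to_csv(path, index=False, lineterminator="\n")
    return path
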