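"""CSV serialization of the linked tables.

Fixed column order, UTF-8, mandatory header row, ISO-8601 dates. A patient's
VTE diagnosis dates are serialized as a ``;``-joined list (empty string for
none). Internal day offsets are restored on read; a malformed date raises
:class:`~oacphen.errors.TablesIOError` naming the file and row.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from oacphen.dates import day_to_iso, iso_to_day
from oacphen.errors import TablesIOError
from oacphen.simulate import (
    CLAIM_COLUMNS,
    ED_COLUMNS,
    PATIENT_COLUMNS,
    TRUTH_COLUMNS,
    VISIT_COLUMNS,
    LinkedTables,
)

FILE_NAMES = {
    "patients": "patients.csv",
    "ed_visits": "ed_visits.csv",
    "drug_claims": "drug_claims.csv",
    "outpatient_visits": "outpatient_visits.csv",
    "ground_truth": "ground_truth.csv",
}

_DATE_COLUMNS = {
    "patients": ["birth_date"],
    "ed_visits": ["registration_date", "departure_date"],
    "drug_claims": ["fill_date"],
    "outpatient_visits": ["service_date"],
    "ground_truth": [],
}
_BOOL_COLUMNS = {
    "patients": ["would_not_benefit"],
    "ed_visits": ["main_diagnosis_is_af"],
    "drug_claims": [],
    "outpatient_visits": [],
    "ground_truth": ["ed_oac_prescribed"],
}
_INT_COLUMNS = {"drug_claims": ["days_supply"]}
_COLUMNS = {
    "patients": PATIENT_COLUMNS,
    "ed_visits": ED_COLUMNS,
    "drug_claims": CLAIM_COLUMNS,
    "outpatient_visits": VISIT_COLUMNS,
    "ground_truth": TRUTH_COLUMNS,
}


def write_tables(tables: LinkedTables, directory: str | Path) -> dict[str, Path]:
    """Write the five CSVs; returns the mapping of table name to file path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, fname in FILE_NAMES.items():
        df = getattr(tables, name).copy()
        for col in _DATE_COLUMNS[name]:
            df[col] = [day_to_iso(d) for d in df[col]]
        if name == "patients":
            df["vte_dates"] = [
                ";".join(day_to_iso(d) for d in ds) for ds in df["vte_dates"]
            ]
        path = directory / fname
        df.to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths


def _parse_dates(series: pd.Series, path: Path) -> pd.Series:
    out = []
    for i, v in enumerate(series):
        try:
            out.append(iso_to_day(v))
        except (ValueError, TypeError) as exc:
            raise TablesIOError(
                f"{path.name}: row {i + 2}: unparseable date {v!r} in column "
                f"{series.name!r}"
            ) from exc
    return pd.Series(out, dtype=int, name=series.name)


def read_tables(directory: str | Path) -> LinkedTables:
    """Read the five CSVs back into a :class:`LinkedTables`.

    Inverse of :func:`write_tables`: ``read_tables(write_tables(t)) == t``.
    """
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    for name, fname in FILE_NAMES.items():
        path = directory / fname
        if not path.exists():
            raise TablesIOError(f"missing table file: {path}")
        try:
            df = pd.read_csv(path, dtype=str, keep_default_na=False)
        except Exception as exc:  # malformed CSV
            raise TablesIOError(f"{path.name}: cannot parse: {exc}") from exc
        missing = [c for c in _COLUMNS[name] if c not in df.columns]
        if missing:
            raise TablesIOError(f"{path.name}: malformed header, missing {missing}")
        df = df[_COLUMNS[name]]
        if len(df):
            for col in _DATE_COLUMNS[name]:
                df[col] = _parse_dates(df[col], path)
            for col in _BOOL_COLUMNS[name]:
                df[col] = df[col].map({"True": True, "False": False})
            for col in _INT_COLUMNS.get(name, []):
                df[col] = df[col].astype(int)
            if name == "patients":
                df["vte_dates"] = [
                    tuple(iso_to_day(x) for x in v.split(";")) if v else ()
                    for v in df["vte_dates"]
                ]
        frames[name] = df
    return LinkedTables(**frames)
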