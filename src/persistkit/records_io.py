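"""Read, validate, and write the three input tables and derived analysis tables.

Canonical schemas
-----------------
``patients.csv``  : patient_id, diagnosis {CD,UC}, age_at_initiation (years),
                    gender {male,female}, province_region, first_weight_kg
``infusions.csv`` : patient_id, date (ISO-8601), dose_mg, weight_kg (optional)
``tdm.csv``       : patient_id, date, ifx_conc_ug_ml (optional),
                    ati_status {positive,negative,missing}

Missing values are empty strings in CSV, never sentinel numerics.  Same-date
duplicate infusions for a patient are collapsed by summing ``dose_mg``
(split-bag administrations), keeping the first recorded weight; this preserves
total administered dose and avoids zero-length dosing intervals.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

DIAGNOSES = ("CD", "UC")
GENDERS = ("male", "female")
PROVINCES = (
    "Alberta",
    "Atlantic",
    "BritishColumbia",
    "Ontario",
    "Quebec",
    "SaskatchewanManitoba",
)
ATI_STATUSES = ("positive", "negative", "missing")

PATIENT_COLUMNS = [
    "patient_id",
    "diagnosis",
    "age_at_initiation",
    "gender",
    "province_region",
    "first_weight_kg",
]
INFUSION_COLUMNS = ["patient_id", "date", "dose_mg", "weight_kg"]
TDM_COLUMNS = ["patient_id", "date", "ifx_conc_ug_ml", "ati_status"]


class SchemaError(ValueError):
    """A table-level violation: missing column or duplicated key."""


class RowValidationError(ValueError):
    """One or more rows violate a hard invariant.

    ``errors`` holds (row_index, message) diagnostics.
    """

    def __init__(self, table: str, errors: list[tuple[int, str]]):
        self.table = table
        self.errors = errors
        lines = "; ".join(f"row {i}: {msg}" for i, msg in errors[:10])
        more = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{table}: {len(errors)} invalid row(s): {lines}{more}")


def _read_csv(path: str | Path, required: list[str], table: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c.lower() not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")
    return df


def _parse_dates(raw: pd.Series, errors: list[tuple[int, str]]) -> pd.Series:
    parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    for i in raw.index[parsed.isna()]:
        errors.append((int(i), f"unparseable date {raw[i]!r}"))
    return parsed


def _parse_float(
    raw: pd.Series, errors: list[tuple[int, str]], name: str, *, allow_missing: bool
) -> pd.Series:
    stripped = raw.str.strip()
    out = pd.to_numeric(stripped.replace("", None), errors="coerce")
    bad = out.isna() & (stripped != "")
    for i in raw.index[bad]:
        errors.append((int(i), f"non-numeric {name} {raw[i]!r}"))
    if not allow_missing:
        for i in raw.index[(stripped == "")]:
            errors.append((int(i), f"missing required {name}"))
    return out


def _finish(
    df: pd.DataFrame,
    errors: list[tuple[int, str]],
    table: str,
    skip_bad_rows: bool,
) -> pd.DataFrame:
    if errors:
        if not skip_bad_rows:
            raise RowValidationError(table, errors)
        bad = sorted({i for i, _ in errors})
        df = df.drop(index=bad)
    return df.reset_index(drop=True)


def read_patients(path: str | Path, skip_bad_rows: bool = False) -> pd.DataFrame:
    df = _read_csv(path, PATIENT_COLUMNS, "patients")
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        raise SchemaError(f"patients: duplicate patient_id {dup!r}")
    errors: list[tuple[int, str]] = []
    age = _parse_float(df["age_at_initiation"], errors, "age", allow_missing=False)
    weight = _parse_float(df["first_weight_kg"], errors, "weight", allow_missing=False)
    for i in df.index:
        if df.at[i, "diagnosis"] not in DIAGNOSES:
            errors.append((int(i), f"diagnosis {df.at[i, 'diagnosis']!r} not in {DIAGNOSES}"))
        if df.at[i, "gender"] not in GENDERS:
            errors.append((int(i), f"gender {df.at[i, 'gender']!r} not in {GENDERS}"))
        if df.at[i, "province_region"] not in PROVINCES:
            errors.append((int(i), f"province_region {df.at[i, 'province_region']!r} unknown"))
        a, w = age.get(i), weight.get(i)
        if pd.notna(a) and a < 0:
            errors.append((int(i), f"age_at_initiation {a} < 0"))
        if pd.notna(w) and w <= 0:
            errors.append((int(i), f"first_weight_kg {w} <= 0"))
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "diagnosis": df["diagnosis"],
            "age_at_initiation": age.round().astype("Int64"),
            "gender": df["gender"],
            "province_region": df["province_region"],
            "first_weight_kg": weight,
        }
    )
    return _finish(out, errors, "patients", skip_bad_rows)


def read_infusions(path: str | Path, skip_bad_rows: bool = False) -> pd.DataFrame:
    df = _read_csv(path, ["patient_id", "date", "dose_mg"], "infusions")
    if "weight_kg" not in df.columns:
        df["weight_kg"] = ""
    errors: list[tuple[int, str]] = []
    dates = _parse_dates(df["date"], errors)
    dose = _parse_float(df["dose_mg"], errors, "dose_mg", allow_missing=False)
    weight = _parse_float(df["weight_kg"], errors, "weight_kg", allow_missing=True)
    for i in df.index:
        if pd.notna(dose.get(i)) and dose[i] <= 0:
            errors.append((int(i), f"dose_mg {dose[i]} <= 0"))
        if pd.notna(weight.get(i)) and weight[i] <= 0:
            errors.append((int(i), f"weight_kg {weight[i]} <= 0"))
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "date": dates,
            "dose_mg": dose,
            "weight_kg": weight,
        }
    )
    out = _finish(out, errors, "infusions", skip_bad_rows)
    return collapse_same_date_infusions(out)


def collapse_same_date_infusions(infusions: pd.DataFrame) -> pd.DataFrame:
    """Sort per patient and collapse same-date duplicates by summing dose_mg."""
    out = (
        infusions.groupby(["patient_id", "date"], as_index=False, sort=False)
        .agg(dose_mg=("dose_mg", "sum"), weight_kg=("weight_kg", "first"))
        .sort_values(["patient_id", "date"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out[INFUSION_COLUMNS]


def read_tdm(path: str | Path, skip_bad_rows: bool = False) -> pd.DataFrame:
    df = _read_csv(path, ["patient_id", "date", "ifx_conc_ug_ml", "ati_status"], "tdm")
    errors: list[tuple[int, str]] = []
    dates = _parse_dates(df["date"], errors)
    conc = _parse_float(df["ifx_conc_ug_ml"], errors, "ifx_conc_ug_ml", allow_missing=True)
    ati = df["ati_status"].str.strip().replace("", "missing")
    for i in df.index:
        if pd.notna(conc.get(i)) and conc[i] < 0:
            errors.append((int(i), f"ifx_conc_ug_ml {conc[i]} < 0"))
        if ati[i] not in ATI_STATUSES:
            errors.append((int(i), f"ati_status {ati[i]!r} not in {ATI_STATUSES}"))
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "date": dates,
            "ifx_conc_ug_ml": conc,
            "ati_status": ati,
        }
    )
    out = _finish(out, errors, "tdm", skip_bad_rows)
    return out.sort_values(["patient_id", "date"], kind="mergesort").reset_index(drop=True)


def read_tables(
    patients_path: str | Path,
    infusions_path: str | Path,
    tdm_path: str | Path,
    skip_bad_rows: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and validate the three canonical input tables."""
    return (
        read_patients(patients_path, skip_bad_rows),
        read_infusions(infusions_path, skip_bad_rows),
        read_tdm(tdm_path, skip_bad_rows),
    )


def write_analysis_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a derived table as CSV with stable column order and ''-as-missing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, na_rep="")
    return path


def read_analysis_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_analysis_table`.

    Columns named ``date`` or ending in ``_date`` are parsed as dates; numeric
    columns are inferred; empty cells become missing.
    """
    df = pd.read_csv(path)
    for col in df.columns:
        if col == "date" or col.endswith("_date"):
            df[col] = pd.to_datetime(df[col], format="ISO8601", errors="raise")
    return df
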