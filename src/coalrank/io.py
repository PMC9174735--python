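"""Validated I/O for the five standard input tables.

All tables are UTF-8 CSV with a header row, comma separators, ISO-8601 dates
and empty fields for missing values. Validation checks schemas, parses dates,
and enforces referential integrity: every male named in the interaction,
coalition or focal tables must appear in the presence table and be resident
on the row's date. Failures are collected as per-row diagnostics (file, row,
rule) and raised together as a :class:`ValidationError`.

Validated tables are returned in a canonical sort order, so shuffling the
rows of an input file does not change the validated output.
"""
from __future__ import annotations

import pathlib

import pandas as pd

from ._exceptions import DataError, ValidationError

TABLE_SCHEMAS = {
    "interactions": ["date", "group", "winner", "loser"],
    "coalitions": ["event_id", "date", "group", "role", "male"],
    "presence": ["male", "group", "entry", "exit", "birth_date"],
    "focal": ["male", "date", "duration_min", "n_aggressive_events"],
    "conceptions": ["infant", "group", "conception_date", "sire"],
}

_DATE_COLUMNS = {
    "interactions": ["date"],
    "coalitions": ["date"],
    "presence": ["entry", "exit", "birth_date"],
    "focal": ["date"],
    "conceptions": ["conception_date"],
}

_SORT_KEYS = {
    "interactions": ["date", "group", "winner", "loser"],
    "coalitions": ["event_id", "role", "male"],
    "presence": ["male"],
    "focal": ["male", "date"],
    "conceptions": ["infant"],
}


def read_table(path, name: str) -> pd.DataFrame:
    """Read one raw table, checking the column schema only."""
    path = pathlib.Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_SCHEMAS[name] if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    return df


def validate_inputs(paths: dict) -> dict:
    """Validate and cross-check the five tables; returns parsed DataFrames.

    ``paths`` maps table name (interactions, coalitions, presence, focal,
    conceptions) to a file path; focal and conceptions are optional.
    """
    diagnostics: list[dict] = []
    raw = {}
    for name in TABLE_SCHEMAS:
        if name in paths and paths[name] is not None:
            raw[name] = read_table(paths[name], name)
    for required in ("interactions", "presence"):
        if required not in raw:
            raise DataError(f"required input table {required!r} not supplied")

    tables = {}
    for name, df in raw.items():
        df = df.copy()
        for col in _DATE_COLUMNS[name]:
            parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
            bad = df.index[parsed.isna() & (df[col] != "")]
            for i in bad:
                diagnostics.append({"file": str(paths[name]), "row": int(i) + 2,
                                    "rule": f"column {col}: unparsable date "
                                            f"{df.loc[i, col]!r}"})
            df[col] = parsed
        tables[name] = df

    pres = tables["presence"]
    dup = pres.index[pres["male"].duplicated()]
    for i in dup:
        diagnostics.append({"file": str(paths["presence"]), "row": int(i) + 2,
                            "rule": f"duplicate male id {pres.loc[i, 'male']!r}"})
    if diagnostics:
        raise ValidationError(diagnostics)

    known = pres.set_index("male")

    def check_presence(name, df, male_col, date_col):
        for i in df.index:
            male = df.loc[i, male_col]
            if male not in known.index:
                diagnostics.append({"file": str(paths[name]), "row": int(i) + 2,
                                    "rule": f"unknown male {male!r}"})
                continue
            d = df.loc[i, date_col]
            row = known.loc[male]
            if not (row["entry"] <= d <= row["exit"]):
                diagnostics.append({
                    "file": str(paths[name]), "row": int(i) + 2,
                    "rule": f"{male!r} not present on {d.date()}"})

    inter = tables["interactions"]
    check_presence("interactions", inter, "winner", "date")
    check_presence("interactions", inter, "loser", "date")
    same = inter.index[inter["winner"] == inter["loser"]]
    for i in same:
        diagnostics.append({"file": str(paths["interactions"]), "row": int(i) + 2,
                            "rule": "winner equals loser"})
    if "coalitions" in tables:
        check_presence("coalitions", tables["coalitions"], "male", "date")
        roles = tables["coalitions"]
        bad_role = roles.index[~roles["role"].isin(["participant", "target"])]
        for i in bad_role:
            diagnostics.append({"file": str(paths["coalitions"]), "row": int(i) + 2,
                                "rule": f"unknown role {roles.loc[i, 'role']!r}"})
    if "focal" in tables:
        check_presence("focal", tables["focal"], "male", "date")
    if "conceptions" in tables:
        conc = tables["conceptions"]
        groups = set(pres["group"])
        bad_grp = conc.index[~conc["group"].isin(groups)]
        for i in bad_grp:
            diagnostics.append({"file": str(paths["conceptions"]), "row": int(i) + 2,
                                "rule": f"unknown group {conc.loc[i, 'group']!r}"})
    if diagnostics:
        raise ValidationError(diagnostics)

    for name, df in tables.items():
        for col in ("duration_min",):
            if col in df.columns:
                df[col] = pd.to_numeric(df[col])
        for col in ("n_aggressive_events",):
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], downcast="integer")
        tables[name] = (df.sort_values(_SORT_KEYS[name], kind="stable")
                        .reset_index(drop=True))
    return tables
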