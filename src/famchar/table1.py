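"""Packaged transcription of the surveyed family's descriptor table.

The package ships ``data/table1.tsv``, a verbatim transcription of the
published 74-row table of family members (accession, name, length, MW, pI,
instability index, aliphatic index, GRAVY). Typographic minus signs and
thousands separators are preserved in the file and normalised on read.
"""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd

from famchar.family_assign import FamilyRoster, RosterEntry
from famchar.physchem import PhyschemProfile

_COLUMNS = {
    "Spud ID": "id",
    "Name": "name",
    "Amino Acid Number": "length",
    "MW": "mw",
    "pI": "pi",
    "Instability Index": "instability",
    "Aliphatic Index": "aliphatic",
    "GRAVY": "gravy",
}


def table1_path():
    """Traversable path of the packaged table."""
    return resources.files("famchar").joinpath("data/table1.tsv")


def load_table1() -> pd.DataFrame:
    """The table as a DataFrame with normalised numeric columns.

    Columns: id, name, group, length, mw, pi, instability, aliphatic, gravy.
    """
    text = table1_path().read_text(encoding="utf-8").replace("−", "-")
    df = pd.read_csv(io.StringIO(text), sep="\t", thousands=",")
    df = df.rename(columns=_COLUMNS)
    df["group"] = df["name"].str.rsplit("-", n=1).str[0]
    for col in ("length", "mw", "pi", "instability", "aliphatic", "gravy"):
        df[col] = pd.to_numeric(df[col])
    return df


def table1_profiles() -> tuple[list[PhyschemProfile], dict[str, str]]:
    """The table as descriptor profiles plus an id -> group map."""
    df = load_table1()
    profiles = [
        PhyschemProfile(
            id=row.id,
            length=int(row.length),
            mw=float(row.mw),
            pi=float(row.pi),
            instability=float(row.instability),
            aliphatic=float(row.aliphatic),
            gravy=float(row.gravy),
        )
        for row in df.itertuples()
    ]
    groups = dict(zip(df["id"], df["group"]))
    return profiles, groups


def table1_roster() -> FamilyRoster:
    """The published family membership as a roster (e-values not published)."""
    df = load_table1()
    roster = FamilyRoster()
    for row in df.itertuples():
        roster.entries[row.id] = RosterEntry(
            gene_id=row.id, group=row.group, best_e_value=0.0, name=row.name
        )
    return roster
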