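"""Readers, writers and validators for site/protein quantification tables.

Conventions used throughout the package:

* residue coordinates are 1-based on the full-length canonical sequence;
* a site is identified as ``"<accession>:K<position>"``;
* all tables are UTF-8, tab-separated, ``.`` decimal; an empty cell is a
  missing value;
* zero intensities are coerced to missing by default because downstream
  log transforms are undefined at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO


class TableError(ValueError):
    """Raised when an input table or sequence file violates its contract."""


SITE_KEY_COLUMNS = ["protein_id", "position", "residue"]

#: accepted aliases (lower-cased) for the site-identity columns
_COLUMN_ALIASES = {
    "protein_id": {"protein_id", "protein", "accession", "uniprot", "protein.id"},
    "position": {"position", "pos", "site_position", "residue_position"},
    "residue": {"residue", "aa", "amino_acid"},
}


def site_id(protein_id: str, position: int, residue: str = "K") -> str:
    """Render the canonical site identifier, e.g. ``"P12345:K108"``."""
    return f"{protein_id}:{residue}{int(position)}"


@dataclass(frozen=True)
class SampleDesign:
    """Two-group experimental design (case vs control).

    Parameters
    ----------
    case, control
        Sample identifiers for each group. Identifiers must be unique
        across both groups and each group must contain at least one sample.
    """

    case: tuple[str, ...]
    control: tuple[str, ...]

    def __post_init__(self) -> None:
        case = tuple(self.case)
        control = tuple(self.control)
        object.__setattr__(self, "case", case)
        object.__setattr__(self, "control", control)
        if not case or not control:
            raise TableError("design needs at least one sample per group")
        all_ids = case + control
        if len(set(all_ids)) != len(all_ids):
            raise TableError("sample ids must be unique across groups")

    @property
    def samples(self) -> tuple[str, ...]:
        return self.control + self.case

    def group_of(self, sample: str) -> str:
        if sample in self.case:
            return "case"
        if sample in self.control:
            return "control"
        raise KeyError(sample)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.samples),
                "group": ["control"] * len(self.control) + ["case"] * len(self.case),
            }
        )


def read_design(path: str | Path) -> SampleDesign:
    """Read a two-column design table (``sample_id``, ``group``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "group" not in cols:
        raise TableError("design file needs 'sample_id' and 'group' columns")
    groups = df[cols["group"]].str.lower()
    bad = set(groups) - {"case", "control"}
    if bad:
        raise TableError(f"unknown group labels: {sorted(bad)}")
    ids = df[cols["sample_id"]]
    return SampleDesign(
        case=tuple(ids[groups == "case"]),
        control=tuple(ids[groups == "control"]),
    )


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def _check_intensities(df: pd.DataFrame, samples: Iterable[str], what: str) -> None:
    for s in samples:
        vals = df[s]
        if (vals.dropna() < 0).any():
            raise TableError(f"negative intensity in {what} column '{s}'")


@dataclass
class SiteQuantTable:
    """Succinyl-site rows × per-sample intensity columns.

    ``data`` holds one row per (protein_id, position) with a ``residue``
    letter and one float column per sample; missing measurements are NaN.
    """

    data: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in SITE_KEY_COLUMNS if c not in df.columns]
        if missing:
            raise TableError(f"site table lacks columns: {missing}")
        absent = [s for s in self.samples if s not in df.columns]
        if absent:
            raise TableError(f"sample column absent from site table: {absent}")
        df = df.copy()
        df["position"] = df["position"].astype(int)
        if (df["position"] < 1).any():
            raise TableError("positions must be >= 1 (1-based coordinates)")
        if df.duplicated(subset=["protein_id", "position"]).any():
            dups = df[df.duplicated(subset=["protein_id", "position"], keep=False)]
            key = dups.iloc[0]
            raise TableError(
                f"duplicate site ({key['protein_id']}, {key['position']})"
            )
        _check_intensities(df, self.samples, "site table")
        df[self.samples] = df[self.samples].astype(float)
        df = df.sort_values(["protein_id", "position"], kind="mergesort")
        df.index = [
            site_id(p, q, r)
            for p, q, r in zip(df["protein_id"], df["position"], df["residue"])
        ]
        self.data = df

    @property
    def site_ids(self) -> pd.Index:
        return self.data.index

    def intensities(self) -> pd.DataFrame:
        """Per-sample intensity matrix indexed by site id."""
        return self.data[self.samples]

    def __len__(self) -> int:
        return len(self.data)

    def equals(self, other: "SiteQuantTable") -> bool:
        a = self.data[SITE_KEY_COLUMNS + self.samples]
        b = other.data[SITE_KEY_COLUMNS + other.samples]
        return self.samples == other.samples and a.equals(b)


@dataclass
class ProteinQuantTable:
    """Protein rows × per-sample intensity columns (abundance correction)."""

    data: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        if "protein_id" not in df.columns:
            raise TableError("protein table lacks 'protein_id' column")
        absent = [s for s in self.samples if s not in df.columns]
        if absent:
            raise TableError(f"sample column absent from protein table: {absent}")
        if df["protein_id"].duplicated().any():
            dup = df["protein_id"][df["protein_id"].duplicated()].iloc[0]
            raise TableError(f"duplicate protein id '{dup}'")
        df = df.copy()
        _check_intensities(df, self.samples, "protein table")
        df[self.samples] = df[self.samples].astype(float)
        df = df.sort_values("protein_id", kind="mergesort")
        df.index = df["protein_id"].to_list()
        self.data = df

    def intensities(self) -> pd.DataFrame:
        return self.data[self.samples]

    def __len__(self) -> int:
        return len(self.data)

    def equals(self, other: "ProteinQuantTable") -> bool:
        a = self.data[["protein_id"] + self.samples]
        b = other.data[["protein_id"] + other.samples]
        return self.samples == other.samples and a.equals(b)


def _map_columns(
    df: pd.DataFrame, column_map: Mapping[str, str] | None, required: list[str]
) -> pd.DataFrame:
    """Rename file columns to canonical names using aliases or an explicit map."""
    rename: dict[str, str] = {}
    if column_map:
        rename = {v: k for k, v in column_map.items()}
    else:
        lower = {c.lower(): c for c in df.columns}
        for canon in required:
            for alias in _COLUMN_ALIASES.get(canon, {canon}):
                if alias in lower:
                    rename[lower[alias]] = canon
                    break
    df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"required column(s) not found: {missing}")
    return df


def _coerce_zeros(df: pd.DataFrame, samples: Iterable[str]) -> pd.DataFrame:
    for s in samples:
        df.loc[df[s] == 0, s] = np.nan
    return df


def read_site_table(
    path: str | Path,
    design: SampleDesign,
    column_map: Mapping[str, str] | None = None,
    coerce_zero_missing: bool = True,
) -> SiteQuantTable:
    """Read a tab-separated site quantification table.

    The header must name the protein accession, residue position and
    residue letter (common aliases are recognized; pass ``column_map``
    for anything else) plus one intensity column per sample in ``design``.
    Empty cells are missing values; zeros become missing unless
    ``coerce_zero_missing`` is false.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = _map_columns(df, column_map, SITE_KEY_COLUMNS)
    for s in design.samples:
        if s not in df.columns:
            raise TableError(f"sample column absent: '{s}'")
    if coerce_zero_missing:
        df = _coerce_zeros(df, design.samples)
    return SiteQuantTable(df, samples=list(design.samples))


def read_protein_table(
    path: str | Path,
    design: SampleDesign,
    column_map: Mapping[str, str] | None = None,
    coerce_zero_missing: bool = True,
) -> ProteinQuantTable:
    """Read a tab-separated protein quantification table."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = _map_columns(df, column_map, ["protein_id"])
    for s in design.samples:
        if s not in df.columns:
            raise TableError(f"sample column absent: '{s}'")
    if coerce_zero_missing:
        df = _coerce_zeros(df, design.samples)
    return ProteinQuantTable(df, samples=list(design.samples))


def write_site_table(table: SiteQuantTable, path: str | Path) -> None:
    cols = SITE_KEY_COLUMNS + table.samples
    table.data[cols].to_csv(path, sep="\t", index=False)


def write_protein_table(table: ProteinQuantTable, path: str | Path) -> None:
    cols = ["protein_id"] + table.samples
    table.data[cols].to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences; the record id is the first header token.

    Returns an id → uppercase sequence mapping. Duplicate ids and empty
    sequences are hard errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise TableError(f"duplicate FASTA id '{rec.id}'")
        seq = str(rec.seq).upper()
        if not seq:
            raise TableError(f"empty sequence for FASTA id '{rec.id}'")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in seqs.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


#: validation outcomes for a site checked against its protein sequence
STATUS_OK = "ok"
STATUS_RESIDUE_MISMATCH = "residue_mismatch"
STATUS_OUT_OF_RANGE = "out_of_range"
STATUS_NO_SEQUENCE = "no_sequence"


def validate_sites_against_sequences(
    sites: SiteQuantTable, seqs: Mapping[str, str]
) -> pd.DataFrame:
    """Classify every site as ok / residue_mismatch / out_of_range / no_sequence.

    Cross-species mapping refuses sites that are not ``ok``; this report
    never raises.
    """
    rows = []
    for sid, row in sites.data.iterrows():
        pid, pos, res = row["protein_id"], int(row["position"]), row["residue"]
        seq = seqs.get(pid)
        if seq is None:
            status = STATUS_NO_SEQUENCE
        elif pos > len(seq):
            status = STATUS_OUT_OF_RANGE
        elif seq[pos - 1] != res:
            status = STATUS_RESIDUE_MISMATCH
        else:
            status = STATUS_OK
        rows.append((sid, pid, pos, res, status))
    return pd.DataFrame(
        rows, columns=["site_id", "protein_id", "position", "residue", "status"]
    )
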