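"""Tabular I/O for PSM tables, experimental designs, and result matrices.

Everything downstream consumes plain TSV (UTF-8, Unix newlines): one row per
peptide-spectrum match with per-channel reporter-ion intensities, plus a
design table mapping (plex, channel) to sample, condition and the pooled
reference flag. Column names are a configurable dialect because vendor
exports vary; the defaults below cover the tables emitted by
:mod:`tmtrollup.synthetic_data`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ParseError",
    "PsmDialect",
    "PsmRecord",
    "Design",
    "read_psm_table",
    "read_design",
    "psms_to_frame",
    "write_table",
]


class SchemaError(ValueError):
    """A mandatory column is missing or a table-level invariant is violated."""


class ParseError(ValueError):
    """A cell could not be parsed; the message carries the 1-based row number."""


@dataclass(frozen=True)
class PsmDialect:
    """Column-name mapping for PSM tables.

    ``channel_pattern`` selects reporter-intensity columns: any header
    matching it is treated as a TMT channel label (e.g. ``126``, ``127N``).
    """

    psm_id: str = "psm_id"
    peptide: str = "peptide"
    modifications: str = "modifications"
    proteins: str = "proteins"
    plex: str = "plex"
    score: str = "score"
    is_decoy: str = "is_decoy"
    protein_sep: str = ";"
    channel_pattern: str = r"^1\d{2}[NC]?$"

    def channel_columns(self, columns) -> list[str]:
        rx = re.compile(self.channel_pattern)
        return [c for c in columns if rx.match(str(c))]


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match with its reporter-ion intensities.

    ``intensities`` maps channel label to a non-negative intensity in
    arbitrary units; a channel that is absent from the map (or carries 0)
    is treated as missing by the quantification stages.
    """

    psm_id: str
    peptide_seq: str
    mod_string: str
    proteins: frozenset[str]
    plex_id: str
    intensities: dict[str, float]
    score: float
    is_decoy: bool

    def __post_init__(self):
        if not self.peptide_seq:
            raise ValueError("peptide_seq must be non-empty")
        if not self.proteins:
            raise ValueError(f"PSM {self.psm_id}: empty protein set")
        for ch, v in self.intensities.items():
            if v < 0:
                raise ValueError(f"PSM {self.psm_id}: negative intensity in channel {ch}")

    @property
    def peptide_key(self) -> str:
        """Peptide identity used for roll-ups: sequence plus modifications."""
        return peptide_key(self.peptide_seq, self.mod_string)

    def mean_intensity(self) -> float:
        """Mean of the positive reporter intensities (0.0 if none)."""
        vals = [v for v in self.intensities.values() if v > 0]
        return float(np.mean(vals)) if vals else 0.0


def peptide_key(seq: str, mod: str) -> str:
    return f"{seq}~{mod}" if mod else seq


@dataclass(frozen=True)
class Design:
    """Mapping (plex, channel) -> sample, condition, reference flag.

    Each plex must contain at least one reference channel (the pooled
    common-reference sample); every non-reference channel carries exactly
    one biological sample with one condition label.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("plex_id", "channel_label", "sample_id", "condition", "is_reference")

    def __post_init__(self):
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise SchemaError(f"design is missing column(s): {', '.join(missing)}")
        dup = t.duplicated(subset=["plex_id", "channel_label"])
        if dup.any():
            key = t.loc[dup.idxmax(), ["plex_id", "channel_label"]].tolist()
            raise SchemaError(f"duplicate (plex, channel) in design: {tuple(key)}")
        for plex, sub in t.groupby("plex_id", sort=False):
            if not sub["is_reference"].any():
                raise SchemaError(f"plex {plex!r} has no reference channel")
        nonref = t[~t["is_reference"]]
        ncond = nonref.groupby("sample_id")["condition"].nunique()
        bad = ncond[ncond > 1]
        if len(bad):
            raise SchemaError(f"sample {bad.index[0]!r} has multiple conditions")
        if nonref["sample_id"].duplicated().any():
            raise SchemaError("a sample_id is assigned to more than one channel")

    @property
    def plexes(self) -> list[str]:
        return list(dict.fromkeys(self.table["plex_id"]))

    @property
    def samples(self) -> list[str]:
        """Non-reference sample ids, in design order."""
        return list(self.table.loc[~self.table["is_reference"], "sample_id"])

    def reference_channels(self, plex_id: str) -> list[str]:
        t = self.table
        sel = (t["plex_id"] == plex_id) & t["is_reference"]
        return list(t.loc[sel, "channel_label"])

    def sample_channels(self, plex_id: str) -> list[tuple[str, str]]:
        """(channel, sample_id) pairs for the non-reference channels of a plex."""
        t = self.table
        sel = (t["plex_id"] == plex_id) & ~t["is_reference"]
        return list(zip(t.loc[sel, "channel_label"], t.loc[sel, "sample_id"]))

    def condition_of(self, sample_id: str) -> str:
        t = self.table
        row = t[(t["sample_id"] == sample_id) & (~t["is_reference"])]
        if row.empty:
            raise KeyError(f"unknown sample {sample_id!r}")
        return str(row["condition"].iloc[0])

    def samples_for(self, condition: str) -> list[str]:
        t = self.table[~self.table["is_reference"]]
        return list(t.loc[t["condition"] == condition, "sample_id"])


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _parse_bool(value, row: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ParseError(f"row {row}: cannot parse {column}={value!r} as boolean")


def read_psm_table(path, dialect: PsmDialect | None = None) -> list[PsmRecord]:
    """Read a PSM TSV into records.

    Empty intensity cells (or ``NA``) become missing channels. Raises
    :class:`SchemaError` when a mapped mandatory column is absent and
    :class:`ParseError` (with the offending 1-based data row) for
    non-numeric intensities or scores.
    """
    d = dialect or PsmDialect()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mandatory = [d.peptide, d.proteins, d.plex, d.score, d.is_decoy]
    for col in mandatory:
        if col not in df.columns:
            raise SchemaError(f"PSM table is missing mandatory column {col!r}")
    channels = d.channel_columns(df.columns)
    records: list[PsmRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        intens: dict[str, float] = {}
        for ch in channels:
            cell = row[ch].strip()
            if cell == "" or cell.upper() == "NA":
                continue
            try:
                intens[ch] = float(cell)
            except ValueError:
                raise ParseError(
                    f"row {i}: non-numeric intensity {cell!r} in channel {ch}"
                ) from None
        try:
            score = float(row[d.score])
        except ValueError:
            raise ParseError(f"row {i}: non-numeric score {row[d.score]!r}") from None
        proteins = frozenset(
            p.strip() for p in row[d.proteins].split(d.protein_sep) if p.strip()
        )
        records.append(
            PsmRecord(
                psm_id=row.get(d.psm_id) or f"row{i}",
                peptide_seq=row[d.peptide].strip(),
                mod_string=row.get(d.modifications, "").strip(),
                proteins=proteins,
                plex_id=row[d.plex].strip(),
                intensities=intens,
                score=score,
                is_decoy=_parse_bool(row[d.is_decoy], i, d.is_decoy),
            )
        )
    return records


def read_design(path) -> Design:
    """Read and validate a design TSV (plex_id, channel_label, sample_id,
    condition, is_reference)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in Design.REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"design is missing column(s): {', '.join(missing)}")
    df = df.copy()
    df["is_reference"] = [
        _parse_bool(v, i, "is_reference")
        for i, v in enumerate(df["is_reference"], start=1)
    ]
    return Design(df.reset_index(drop=True))


def psms_to_frame(records, dialect: PsmDialect | None = None) -> pd.DataFrame:
    """Serialize records back to the tabular dialect (inverse of read)."""
    d = dialect or PsmDialect()
    channels = sorted({ch for r in records for ch in r.intensities})
    rows = []
    for r in records:
        row = {
            d.psm_id: r.psm_id,
            d.peptide: r.peptide_seq,
            d.modifications: r.mod_string,
            d.proteins: d.protein_sep.join(sorted(r.proteins)),
            d.plex: r.plex_id,
            d.score: r.score,
            d.is_decoy: r.is_decoy,
        }
        for ch in channels:
            row[ch] = r.intensities.get(ch, np.nan)
        rows.append(row)
    cols = [d.psm_id, d.peptide, d.modifications, d.proteins, d.plex, d.score, d.is_decoy]
    return pd.DataFrame(rows, columns=cols + channels)


def write_table(frame: pd.DataFrame, path, index: bool | None = None) -> None:
    """Write any result table as TSV: stable column order, ``NA`` for
    missing, floats at 6 significant digits."""
    if index is None:
        index = frame.index.name is not None
    frame.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g", index=index)
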