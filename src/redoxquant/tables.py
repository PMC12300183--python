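"""Tabular containers and tab-delimited I/O for the quantification pipeline.

All pipeline tables are plain tab-delimited UTF-8 text with a fixed header
and empty strings for missing values, mirroring the tabular exports that
database-search engines produce.  Three container kinds matter:

* a *PSM table*: one row per peptide-spectrum match, key columns
  ``protein_id``, ``peptide_id``, ``run_id``, then one intensity column per
  reporter channel;
* a :class:`ChannelDesign` mapping each channel to (strain, replicate, role);
* a :class:`ProteinQuantMatrix` of per-protein, per-channel summed
  intensities, carrying the PSM counts that contributed to each cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STRAIN_HT = "HT"
STRAIN_LT = "LT"
STRAIN_REF = "REF"
ROLE_REDUCED = "reduced"
ROLE_OXIDIZED = "oxidized-complement"
ROLE_ABUNDANCE = "abundance"
ROLE_REFERENCE = "reference"

PSM_KEY_COLUMNS = ["protein_id", "peptide_id", "run_id"]
VALID_STRAINS = {STRAIN_HT, STRAIN_LT, STRAIN_REF}
VALID_ROLES = {ROLE_REDUCED, ROLE_OXIDIZED, ROLE_ABUNDANCE, ROLE_REFERENCE}

#: floats are serialized with 9 significant digits
FLOAT_FORMAT = "%.9g"


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class UsageError(ValueError):
    """An operation was invoked with arguments that make no sense."""


class PipelineError(RuntimeError):
    """A pipeline stage cannot proceed (e.g. every channel failed QC)."""


# ---------------------------------------------------------------------------
# Channel design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelDesign:
    """Maps reporter channels to (strain, replicate, role).

    ``frame`` has columns ``channel_id``, ``strain``, ``replicate``, ``role``.
    ``replicate`` is a nullable integer (the pooled reference channel has
    none).  In a redox design every (strain, replicate) pair owns exactly one
    ``reduced`` (light-label) and one ``oxidized-complement`` (heavy-label)
    channel.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = ["channel_id", "strain", "replicate", "role"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"channel design missing column(s): {missing}")
        if df["channel_id"].duplicated().any():
            dups = df.loc[df["channel_id"].duplicated(), "channel_id"].tolist()
            raise FormatError(f"duplicate channel ids: {dups}")
        bad = set(df["strain"]) - VALID_STRAINS
        if bad:
            raise FormatError(f"unknown strain label(s): {sorted(bad)}")
        bad = set(df["role"]) - VALID_ROLES
        if bad:
            raise FormatError(f"unknown role(s): {sorted(bad)}")
        if self.is_redox:
            per_pair = df[df["role"].isin([ROLE_REDUCED, ROLE_OXIDIZED])]
            counts = per_pair.groupby(["strain", "replicate"])["role"].agg(
                lambda r: (sorted(r) == [ROLE_OXIDIZED, ROLE_REDUCED])
            )
            if not counts.all():
                bad_pairs = counts[~counts].index.tolist()
                raise FormatError(
                    "redox design requires exactly one reduced and one "
                    f"oxidized-complement channel per (strain, replicate); bad: {bad_pairs}"
                )

    @property
    def channels(self) -> list[str]:
        return self.frame["channel_id"].tolist()

    @property
    def is_redox(self) -> bool:
        return bool(self.frame["role"].isin([ROLE_REDUCED, ROLE_OXIDIZED]).any())

    def channels_for(self, strain: str | None = None, role: str | None = None) -> list[str]:
        df = self.frame
        if strain is not None:
            df = df[df["strain"] == strain]
        if role is not None:
            df = df[df["role"] == role]
        return df["channel_id"].tolist()

    def redox_pairs(self) -> list[tuple[str, int, str, str]]:
        """(strain, replicate, light_channel, heavy_channel) per sample."""
        if not self.is_redox:
            raise UsageError("not a redox design: no reduced/oxidized-complement channels")
        out = []
        df = self.frame
        sub = df[df["role"] == ROLE_REDUCED]
        for _, row in sub.iterrows():
            heavy = df[
                (df["strain"] == row["strain"])
                & (df["replicate"] == row["replicate"])
                & (df["role"] == ROLE_OXIDIZED)
            ]["channel_id"].iloc[0]
            out.append((row["strain"], int(row["replicate"]), row["channel_id"], heavy))
        return out

    def replicates(self, strain: str) -> list[int]:
        reps = self.frame.loc[self.frame["strain"] == strain, "replicate"].dropna()
        return sorted(set(int(r) for r in reps))

    def write(self, path: str | Path, force: bool = False) -> Path:
        return write_table(self.frame, path, force=force)

    @classmethod
    def read(cls, path: str | Path) -> "ChannelDesign":
        df = read_table(path)
        df["channel_id"] = df["channel_id"].astype(str)
        df["replicate"] = df["replicate"].astype("Int64")
        return cls(df)


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

def validate_psm_table(psms: pd.DataFrame, design: ChannelDesign) -> pd.DataFrame:
    """Check key columns, channel columns and nonnegativity; return the table."""
    missing = [c for c in PSM_KEY_COLUMNS if c not in psms.columns]
    if missing:
        raise FormatError(f"PSM table missing required column(s): {missing}")
    absent = [c for c in design.channels if c not in psms.columns]
    if absent:
        raise FormatError(f"PSM table lacks design channel column(s): {absent}")
    if psms.empty:
        return psms
    for ch in design.channels:
        col = psms[ch]
        if not pd.api.types.is_numeric_dtype(col):
            raise FormatError(f"channel column {ch!r} is not numeric")
        neg = col[col < 0]
        if len(neg):
            row = int(neg.index[0])
            raise FormatError(
                f"negative intensity {neg.iloc[0]!r} in column {ch!r}, row {row}"
            )
    return psms


def read_psm_table(path: str | Path, design: ChannelDesign) -> pd.DataFrame:
    """Read and validate a tab-delimited PSM table against a channel design.

    Empty cells become missing (NaN); negative intensities are rejected.
    """
    df = read_table(path)
    for ch in design.channels:
        if ch in df.columns:
            try:
                df[ch] = pd.to_numeric(df[ch])
            except (ValueError, TypeError) as exc:
                raise FormatError(f"channel column {ch!r} not parseable: {exc}") from exc
    return validate_psm_table(df, design)


# ---------------------------------------------------------------------------
# Annotation catalog
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a protein → term-set catalog.

    Format: two tab-separated columns ``protein_id``, ``terms`` where terms
    are semicolon-separated.  Duplicate rows for a protein are merged (union)
    with a logged warning; an empty term field records the protein as
    unannotated (empty set).
    """
    df = read_table(path)
    if "protein_id" not in df.columns or "terms" not in df.columns:
        raise FormatError("annotation file needs columns protein_id, terms")
    catalog: dict[str, set[str]] = {}
    dupes = []
    for pid, terms in zip(df["protein_id"].astype(str), df["terms"]):
        parsed = (
            {t.strip() for t in str(terms).split(";") if t.strip()}
            if pd.notna(terms)
            else set()
        )
        if pid in catalog:
            dupes.append(pid)
            catalog[pid] |= parsed
        else:
            catalog[pid] = parsed
    if dupes:
        log.warning("annotation catalog: %d duplicate protein rows merged (%s ...)",
                    len(dupes), dupes[0])
    return {k: frozenset(v) for k, v in catalog.items()}


def write_annotations(catalog: Mapping[str, Iterable[str]], path: str | Path,
                      force: bool = False) -> Path:
    rows = [
        {"protein_id": pid, "terms": ";".join(sorted(terms))}
        for pid, terms in catalog.items()
    ]
    df = pd.DataFrame(rows, columns=["protein_id", "terms"])
    return write_table(df, path, force=force)


# ---------------------------------------------------------------------------
# Protein quantification matrix
# ---------------------------------------------------------------------------

@dataclass
class ProteinQuantMatrix:
    """Protein × channel summed reporter intensities.

    ``values``: DataFrame indexed by protein_id, one column per channel;
    a cell is missing only if no contributing PSM carried a value.
    ``psm_counts``: same shape, number of PSM values summed into each cell.
    ``merged_groups``: provenance of any group merges (group id → members).
    """

    values: pd.DataFrame
    psm_counts: pd.DataFrame
    merged_groups: dict[str, list[str]] = field(default_factory=dict)

    @property
    def channels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    def select_channels(self, channels: list[str]) -> "ProteinQuantMatrix":
        return ProteinQuantMatrix(
            self.values[channels].copy(),
            self.psm_counts[channels].copy(),
            dict(self.merged_groups),
        )

    def channel_totals(self) -> pd.Series:
        return self.values.sum(axis=0, skipna=True)

    def write(self, path: str | Path, force: bool = False) -> Path:
        return write_table(self.values.reset_index(names="protein_id"), path, force=force)


# ---------------------------------------------------------------------------
# Generic TSV round-trip
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, force: bool = False) -> Path:
    """Write a DataFrame as TSV (empty string for missing, %.9g floats).

    Refuses to overwrite an existing file unless ``force`` is given.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format=FLOAT_FORMAT)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t", na_values=[""], keep_default_na=True)


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  force: bool = False) -> dict[str, Path]:
    """Write a named set of result tables as ``<out_dir>/<name>.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        paths[name] = write_table(df, out_dir / f"{name}.tsv", force=force)
    return paths
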