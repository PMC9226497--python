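"""Domain types and readers/writers for peptide-level HDX-MS data.

The central container is :class:`UptakeTable`, a validated, tidy table of
per-peptide deuterium uptake time courses (one row per peptide per exposure
time, with replicate mean and standard deviation).  Two CSV dialects are
supported: the package's own ``canonical`` dialect and DynamX-style state
data exports (``dynamx``), whose exposures are given in minutes.

Residue coordinates are 1-based and inclusive throughout, matching the
conventions of the HDX-MS literature ("residues 72-78" means both
endpoints).  Conversion to 0-based half-open indexing happens only at numpy
array boundaries inside other modules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Canonical CSV column order.
CANONICAL_COLUMNS = [
    "protein", "state", "start", "end", "sequence",
    "exposure_s", "uptake_Da", "sd_Da", "n_reps",
]

#: DynamX state-data export -> canonical column mapping.
DYNAMX_COLUMNS = {
    "Protein": "protein",
    "State": "state",
    "Start": "start",
    "End": "end",
    "Sequence": "sequence",
    "Exposure": "exposure_s",   # minutes in the file; converted on read
    "Uptake": "uptake_Da",
    "Uptake SD": "sd_Da",
}


class DialectError(ValueError):
    """Raised when a CSV header does not match the requested dialect."""


class ValidationError(ValueError):
    """Raised when table contents violate the uptake-table invariants."""


@dataclass(frozen=True, order=True)
class Peptide:
    """A proteolytic peptide identified by its span in the parent protein."""

    protein_id: str
    state: str
    start: int
    end: int
    sequence: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"peptide {self.protein_id} {self.start}-{self.end}: start > end")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValidationError(
                f"peptide {self.protein_id} {self.start}-{self.end}: sequence "
                f"length {len(self.sequence)} != span {self.end - self.start + 1}")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"peptide {self.protein_id} {self.start}-{self.end}: "
                f"non-standard residue letters {sorted(bad)}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class UptakeMeasurement:
    """Mean deuterium uptake of one peptide at one exposure time."""

    peptide: Peptide
    exposure_s: float
    uptake_Da: float
    sd_Da: float
    n_reps: int = 1

    def __post_init__(self):
        if self.exposure_s < 0:
            raise ValidationError("exposure_s must be >= 0")
        if self.uptake_Da < 0:
            raise ValidationError(
                f"negative uptake {self.uptake_Da} for peptide "
                f"{self.peptide.start}-{self.peptide.end} at t={self.exposure_s}s")
        if self.sd_Da < 0:
            raise ValidationError("sd_Da must be >= 0")


class UptakeTable:
    """Tidy peptide-level uptake table with validation and provenance.

    Parameters
    ----------
    df:
        DataFrame with the canonical columns.  Copied and validated.
    metadata:
        Free-form provenance mapping.  The key ``backexchange_corrected``
        tracks whether the back-exchange correction stage has been applied
        (uptake is stored uncorrected on read).
    """

    def __init__(self, df: pd.DataFrame, metadata: Mapping | None = None):
        df = df.copy().reset_index(drop=True)
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing canonical columns: {missing}")
        df = df[CANONICAL_COLUMNS]
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        df["n_reps"] = df["n_reps"].astype(int)
        for col in ("exposure_s", "uptake_Da", "sd_Da"):
            df[col] = df[col].astype(float)
        self.df = df
        self.metadata: dict = dict(metadata or {})
        self.metadata.setdefault("backexchange_corrected", False)
        self._validate()

    def _validate(self):
        df = self.df
        neg = df.index[df["uptake_Da"] < 0]
        if len(neg):
            row = df.loc[neg[0]]
            raise ValidationError(
                f"negative uptake {row['uptake_Da']} in row {neg[0]} "
                f"({row['protein']} {row['start']}-{row['end']} "
                f"t={row['exposure_s']}s)")
        if (df["sd_Da"] < 0).any():
            raise ValidationError("negative sd_Da")
        if (df["exposure_s"] < 0).any():
            raise ValidationError("negative exposure_s")
        key = ["protein", "state", "start", "end", "exposure_s"]
        dup = df.duplicated(subset=key)
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise ValidationError(
                f"duplicate measurement for {row['protein']}/{row['state']} "
                f"{row['start']}-{row['end']} t={row['exposure_s']}s")
        # peptide-level invariants
        for (_, _, start, end, seq), _sub in df.groupby(
                ["protein", "state", "start", "end", "sequence"]):
            if len(seq) != end - start + 1:
                raise ValidationError(
                    f"sequence length mismatch for span {start}-{end}")
        # flag ragged timepoint schedules (allowed, but surfaced)
        for (prot, state), sub in df.groupby(["protein", "state"]):
            sets = sub.groupby(["start", "end"])["exposure_s"].apply(frozenset)
            if sets.nunique() > 1:
                self.metadata.setdefault("ragged_timepoints", []).append(
                    f"{prot}/{state}")
                logger.warning("timepoint set differs across peptides in %s/%s",
                               prot, state)

    # -- accessors ---------------------------------------------------------

    def peptides(self) -> list[Peptide]:
        """Unique peptides in the table, ordered by (protein, state, span)."""
        cols = ["protein", "state", "start", "end", "sequence"]
        uniq = self.df[cols].drop_duplicates().sort_values(cols)
        return [Peptide(p, s, int(a), int(b), q)
                for p, s, a, b, q in uniq.itertuples(index=False)]

    def measurements(self) -> Iterator[UptakeMeasurement]:
        for row in self.df.itertuples(index=False):
            pep = Peptide(row.protein, row.state, row.start, row.end,
                          row.sequence)
            yield UptakeMeasurement(pep, row.exposure_s, row.uptake_Da,
                                    row.sd_Da, row.n_reps)

    def states(self) -> list[str]:
        return sorted(self.df["state"].unique())

    def select(self, protein: str | None = None,
               state: str | None = None) -> "UptakeTable":
        df = self.df
        if protein is not None:
            df = df[df["protein"] == protein]
        if state is not None:
            df = df[df["state"] == state]
        return UptakeTable(df, self.metadata)

    def curve(self, peptide: Peptide) -> pd.DataFrame:
        """Time course (exposure_s, uptake_Da, sd_Da, n_reps) of one peptide."""
        df = self.df
        m = ((df["protein"] == peptide.protein_id)
             & (df["state"] == peptide.state)
             & (df["start"] == peptide.start)
             & (df["end"] == peptide.end))
        return df.loc[m].sort_values("exposure_s").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, UptakeTable):
            return NotImplemented
        return self.df.equals(other.df)

    # -- I/O ---------------------------------------------------------------

    def write_csv(self, path) -> None:
        """Write the canonical CSV dialect (exposures in seconds)."""
        # default float formatting is shortest-repr: values round-trip
        self.df.to_csv(path, index=False)

    def to_json(self) -> str:
        """Archival JSON export (records plus metadata)."""
        return json.dumps({
            "metadata": {k: v for k, v in self.metadata.items()},
            "measurements": self.df.to_dict(orient="records"),
        }, indent=1, default=str)


@dataclass
class ResidueMap:
    """Per-residue numeric values (e.g. differential uptake) for painting
    onto a structure; missing residues are simply absent from ``values``."""

    protein_id: str
    values: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        for idx in self.values:
            if int(idx) < 1:
                raise ValidationError(f"residue index {idx} < 1")


def read_state_table(path, dialect: str = "canonical",
                     column_map: Mapping[str, str] | None = None) -> UptakeTable:
    """Read a peptide-level uptake CSV in the given dialect.

    ``dynamx`` exposures are minutes and converted to seconds; rows with a
    missing uptake value are dropped with a logged count.  ``column_map``
    overrides individual header names for tolerant reading of supplementary
    tables whose exact layout varies.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, float_precision="round_trip")
    if dialect == "canonical":
        mapping = {c: c for c in CANONICAL_COLUMNS}
    elif dialect == "dynamx":
        mapping = dict(DYNAMX_COLUMNS)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if column_map:
        mapping.update(column_map)
    unmatched = [src for src in mapping if src not in raw.columns]
    # n_reps is optional in both dialects
    required = [s for s in unmatched if mapping[s] != "n_reps"]
    if required:
        raise DialectError(
            f"{path.name}: header does not match dialect {dialect!r}; "
            f"first unmatched column: {required[0]!r}")
    df = raw.rename(columns=mapping)
    if "n_reps" not in df.columns:
        df["n_reps"] = 1
    n_missing = df["uptake_Da"].isna().sum()
    if n_missing:
        logger.info("%s: dropped %d rows with missing uptake", path.name,
                    n_missing)
    df = df.dropna(subset=["uptake_Da"])
    if dialect == "dynamx":
        df["exposure_s"] = df["exposure_s"].astype(float) * 60.0
    df["sd_Da"] = df["sd_Da"].fillna(0.0)
    meta = {"source": str(path), "dialect": dialect,
            "dropped_missing_uptake": int(n_missing)}
    return UptakeTable(df[CANONICAL_COLUMNS], meta)


def _load_structure(structure) -> AtomArray:
    """Accept a PDB path, PDB text, or a biotite AtomArray."""
    if isinstance(structure, AtomArray):
        return structure
    if isinstance(structure, (str, Path)) and "\n" in str(structure):
        from io import StringIO
        pdb = PDBFile.read(StringIO(str(structure)))
    else:
        pdb = PDBFile.read(str(structure))
    arr = pdb.get_structure(model=1, extra_fields=["b_factor"])
    return arr


def write_residue_map_pdb(structure, residue_map: ResidueMap, path,
                          sentinel: float = -1.0) -> None:
    """Write ``structure`` with the B-factor column carrying map values.

    Mapped residues receive their value rounded to two decimals; residues
    without a value get ``sentinel``.  Map entries whose residue index is
    absent from the structure are reported in a warning, not fatal.
    """
    arr = _load_structure(structure).copy()
    present = set(arr.res_id.tolist())
    absent = sorted(set(residue_map.values) - present)
    if absent:
        logger.warning("residue indices not in structure, skipped: %s", absent)
    bfac = np.full(arr.array_length(), float(sentinel))
    for res_id, value in residue_map.values.items():
        if res_id in present:
            bfac[arr.res_id == res_id] = round(float(value), 2)
    arr.set_annotation("b_factor", bfac)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_residue_map_pdb(path, sentinel: float = -1.0) -> ResidueMap:
    """Recover a residue map from the B-factor column of a written PDB."""
    arr = _load_structure(path)
    values: dict[int, float] = {}
    for res_id in np.unique(arr.res_id):
        b = float(arr.b_factor[arr.res_id == res_id][0])
        if not np.isclose(b, sentinel):
            values[int(res_id)] = b
    protein = str(arr.chain_id[0]) if arr.array_length() else ""
    return ResidueMap(protein_id=protein, values=values)
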