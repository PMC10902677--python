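"""Core containers for panning-campaign repertoire analysis.

A *clonotype* is a distinct antibody sequence (identified here by a CDR
region, HCDR3 by default) together with the number of sequencing reads
supporting it in one sample.  A :class:`Repertoire` is the clonotype table
of one sample (one panning round, typically); an :class:`ExperimentSet`
collects the repertoires of a whole campaign and exposes the unified
"master table" with one row per (sample, clone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

REGIONS = ("CDR1", "CDR2", "CDR3", "full")

#: columns every repertoire frame carries, in canonical order
REPERTOIRE_COLUMNS = ("clone_id", "read_count", "read_fraction", "nt_seq", "aa_seq")

MASTER_COLUMNS = ("sample_name", "clone_id", "read_count", "read_fraction",
                  "nt_seq", "aa_seq", "region")

FRACTION_TOL = 1e-6


class RepertoireError(ValueError):
    """Invalid repertoire content or parameters."""


class FormatError(RepertoireError):
    """Input file does not match the expected dialect."""


@dataclass(frozen=True)
class ClonotypeRecord:
    """One clone in one sample."""

    clone_id: str
    read_count: int
    read_fraction: float
    nt_seq: str
    aa_seq: str
    region: str = "CDR3"

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise RepertoireError(f"read_count must be >= 0, got {self.read_count}")
        if not (-FRACTION_TOL <= self.read_fraction <= 1 + FRACTION_TOL):
            raise RepertoireError(
                f"read_fraction must lie in [0, 1], got {self.read_fraction}")
        if self.region not in REGIONS:
            raise RepertoireError(f"unknown region {self.region!r}")


@dataclass
class Repertoire:
    """Clonotype table of a single sample.

    The table is held as a DataFrame with columns
    ``clone_id, read_count, read_fraction, nt_seq, aa_seq``; ``region``
    applies to all rows.  ``metadata`` is a free key/value map (e.g.
    ``{"round": 2}``).
    """

    sample_name: str
    df: pd.DataFrame
    region: str = "CDR3"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_name:
            raise RepertoireError("sample_name must be non-empty")
        if self.region not in REGIONS:
            raise RepertoireError(f"unknown region {self.region!r}")
        missing = [c for c in REPERTOIRE_COLUMNS if c not in self.df.columns]
        if missing:
            raise RepertoireError(f"repertoire frame lacks columns {missing}")
        self.df = self.df.loc[:, list(REPERTOIRE_COLUMNS)].reset_index(drop=True)
        self.df["clone_id"] = self.df["clone_id"].astype(str)
        self.df["read_count"] = self.df["read_count"].astype(np.int64)
        self.df["read_fraction"] = self.df["read_fraction"].astype(float)

    # -- views ---------------------------------------------------------
    @property
    def n_clones(self) -> int:
        return len(self.df)

    @property
    def total_reads(self) -> int:
        return int(self.df["read_count"].sum())

    @property
    def aa_sequences(self) -> list[str]:
        return self.df["aa_seq"].tolist()

    @property
    def records(self) -> Iterator[ClonotypeRecord]:
        for row in self.df.itertuples(index=False):
            yield ClonotypeRecord(row.clone_id, int(row.read_count),
                                  float(row.read_fraction), row.nt_seq,
                                  row.aa_seq, self.region)

    def validate(self) -> None:
        """Check the container invariants; raise RepertoireError on violation."""
        if (self.df["read_count"] < 0).any():
            raise RepertoireError(f"{self.sample_name}: negative read_count")
        frac = self.df["read_fraction"]
        if ((frac < -FRACTION_TOL) | (frac > 1 + FRACTION_TOL)).any():
            raise RepertoireError(f"{self.sample_name}: read_fraction outside [0,1]")
        if frac.sum() > 1 + FRACTION_TOL:
            raise RepertoireError(
                f"{self.sample_name}: read fractions sum to {frac.sum():.6f} > 1")
        if self.df["clone_id"].duplicated().any():
            dup = self.df.loc[self.df["clone_id"].duplicated(), "clone_id"].iloc[0]
            raise RepertoireError(f"{self.sample_name}: duplicate clone_id {dup!r}")

    def with_frame(self, df: pd.DataFrame) -> "Repertoire":
        """New repertoire sharing name/region/metadata but with a new table."""
        return Repertoire(self.sample_name, df.reset_index(drop=True),
                          region=self.region, metadata=dict(self.metadata))


class ExperimentSet:
    """Named, ordered collection of repertoires plus the master table."""

    def __init__(self, repertoires: list[Repertoire]):
        names = [r.sample_name for r in repertoires]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RepertoireError(f"duplicate sample names: {sorted(dupes)}")
        self._reps: dict[str, Repertoire] = {r.sample_name: r for r in repertoires}

    @property
    def sample_names(self) -> list[str]:
        return list(self._reps)

    def __len__(self) -> int:
        return len(self._reps)

    def __iter__(self) -> Iterator[Repertoire]:
        return iter(self._reps.values())

    def __getitem__(self, sample_name: str) -> Repertoire:
        return self._reps[sample_name]

    @property
    def master_table(self) -> pd.DataFrame:
        """One row per (sample, clone), in sample then original row order."""
        parts = []
        for rep in self:
            part = rep.df.copy()
            part.insert(0, "sample_name", rep.sample_name)
            part["region"] = rep.region
            parts.append(part)
        if not parts:
            return pd.DataFrame(columns=list(MASTER_COLUMNS))
        out = pd.concat(parts, ignore_index=True)
        return out.loc[:, list(MASTER_COLUMNS)]

    def map(self, fn) -> "ExperimentSet":
        """Apply a Repertoire -> Repertoire function to every sample."""
        return ExperimentSet([fn(rep) for rep in self])


class BindingTable:
    """Immunoassay binding/affinity values keyed by amino-acid sequence.

    Wraps a DataFrame indexed by aa_seq with one numeric column per
    antigen; missing values are NaN.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise FormatError(f"duplicated sequence key {dup!r} in binding table")
        if frame.shape[1] == 0:
            raise FormatError("binding table has no antigen columns")
        self.frame = frame

    @property
    def antigens(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def sequences(self) -> list[str]:
        return list(self.frame.index)

    def values_for(self, antigen: str) -> pd.Series:
        if antigen not in self.frame.columns:
            raise KeyError(
                f"unknown antigen {antigen!r}; available: {self.antigens}")
        return self.frame[antigen]

    def __len__(self) -> int:
        return len(self.frame)


def repertoire_from_records(sample_name: str,
                            records: Mapping | list,
                            region: str = "CDR3",
                            metadata: dict | None = None) -> Repertoire:
    """Build a Repertoire from an iterable of ClonotypeRecord or dicts."""
    rows = []
    for rec in records:
        if isinstance(rec, ClonotypeRecord):
            rows.append({"clone_id": rec.clone_id, "read_count": rec.read_count,
                         "read_fraction": rec.read_fraction,
                         "nt_seq": rec.nt_seq, "aa_seq": rec.aa_seq})
        else:
            rows.append({k: rec[k] for k in REPERTOIRE_COLUMNS})
    df = pd.DataFrame(rows, columns=list(REPERTOIRE_COLUMNS))
    return Repertoire(sample_name, df, region=region, metadata=metadata or {})
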