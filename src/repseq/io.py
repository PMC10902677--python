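"""Readers and writers for clonotype tables and binding data.

Two TSV dialects are supported: MiXCR ``exportClones``-style tables
(``readCount``, ``readFraction``, ``nSeqCDR3``, ``aaSeqCDR3``, ...) and
AIRR Rearrangement tables (``duplicate_count``, ``junction``,
``junction_aa``).  Column matching is case-sensitive against the alias
tables below.  Sequences are upper-cased on ingest and 'U' is mapped to
'T' in nucleotide columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (BindingTable, ExperimentSet, FormatError, MASTER_COLUMNS,
                    Repertoire)

log = logging.getLogger(__name__)

# alias tables: canonical field -> accepted header names, per dialect.
# Region-specific sequence columns are formatted with the region name.
_MIXCR_ALIASES = {
    "clone_id": ("cloneId", "clone_id"),
    "read_count": ("readCount", "cloneCount", "read_count"),
    "read_fraction": ("readFraction", "cloneFraction", "read_fraction"),
    "nt_seq": ("nSeq{region}",),
    "aa_seq": ("aaSeq{region}",),
}

_AIRR_ALIASES = {
    "clone_id": ("sequence_id", "clone_id"),
    "read_count": ("duplicate_count",),
    "read_fraction": ("duplicate_frequency",),
    # AIRR defines junction columns only for the CDR3 junction
    "nt_seq": ("junction",),
    "aa_seq": ("junction_aa",),
}


@dataclass
class LoadReport:
    """Accounting of one table load: kept + dropped == total input rows."""

    path: str
    total_rows: int
    kept_rows: int
    dropped_empty_seq: int
    assumed_unit_counts: bool = False

    def __post_init__(self) -> None:
        assert self.kept_rows + self.dropped_empty_seq == self.total_rows


def _resolve(columns, aliases, region: str) -> dict[str, str | None]:
    found: dict[str, str | None] = {}
    for canon, names in aliases.items():
        found[canon] = None
        for name in names:
            name = name.format(region=region)
            if name in columns:
                found[canon] = name
                break
    return found


def _clean_nt(s: pd.Series) -> pd.Series:
    return s.fillna("").astype(str).str.upper().str.replace("U", "T", regex=False)


def _clean_aa(s: pd.Series) -> pd.Series:
    return s.fillna("").astype(str).str.upper()


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                       na_values=[], encoding="utf-8")


def _parse_counts(raw: pd.Series, path) -> pd.Series:
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() | (out < 0)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise FormatError(
            f"{path}: unparseable read count {raw[bad].iloc[0]!r} on line {line}")
    return out.round().astype(np.int64)


def _assemble(df: pd.DataFrame, cols: dict, path, region: str,
              sample_name: str, recompute_fraction_if_missing: bool
              ) -> tuple[Repertoire, LoadReport]:
    total = len(df)
    assumed_units = False

    if cols["read_count"] is None:
        # stated fallback: every row counts one read
        counts = pd.Series(np.ones(total, dtype=np.int64), index=df.index)
        assumed_units = True
        log.warning("%s: no read-count column; assuming one read per row", path)
    else:
        counts = _parse_counts(df[cols["read_count"]], path)

    nt = _clean_nt(df[cols["nt_seq"]]) if cols["nt_seq"] else pd.Series([""] * total)
    aa = _clean_aa(df[cols["aa_seq"]]) if cols["aa_seq"] else pd.Series([""] * total)

    keep = nt.str.len() > 0
    dropped = int((~keep).sum())
    if dropped:
        log.info("%s: dropped %d rows with empty %s sequence", path, dropped, region)

    if cols["read_fraction"] is not None and not assumed_units:
        frac = pd.to_numeric(df[cols["read_fraction"]], errors="coerce").fillna(0.0)
    else:
        tot = counts[keep].sum()
        frac = counts / tot if tot > 0 else counts.astype(float)
        if not recompute_fraction_if_missing:
            frac = counts.astype(float) * np.nan

    clone_id = (df[cols["clone_id"]].astype(str) if cols["clone_id"]
                else pd.Series([str(i) for i in range(total)]))

    out = pd.DataFrame({
        "clone_id": clone_id[keep].to_numpy(),
        "read_count": counts[keep].to_numpy(),
        "read_fraction": frac[keep].to_numpy(dtype=float),
        "nt_seq": nt[keep].to_numpy(),
        "aa_seq": aa[keep].to_numpy(),
    })
    rep = Repertoire(sample_name, out, region=region)
    report = LoadReport(str(path), total, int(keep.sum()), dropped,
                        assumed_unit_counts=assumed_units)
    log.info("%s: kept %d / %d rows", path, report.kept_rows, report.total_rows)
    return rep, report


def read_mixcr_clones(path, region: str = "CDR3", sample_name: str | None = None,
                      with_report: bool = False):
    """Read a MiXCR exportClones-style TSV into a :class:`Repertoire`.

    Rows with an empty nucleotide sequence for the requested region are
    dropped and counted in the :class:`LoadReport` (returned when
    ``with_report=True``).  The read fraction is taken verbatim from the
    file when present (it may have been computed on pre-trimming totals
    upstream); :func:`repseq.preprocess.recompute_fractions` renormalizes.
    """
    df = _read_tsv(path)
    cols = _resolve(df.columns, _MIXCR_ALIASES, region)
    for canon in ("read_count", "nt_seq", "aa_seq"):
        if cols[canon] is None:
            wanted = _MIXCR_ALIASES[canon][0].format(region=region)
            raise FormatError(f"{path}: required column {wanted!r} missing")
    name = sample_name or Path(path).stem
    rep, report = _assemble(df, cols, path, region, name,
                            recompute_fraction_if_missing=True)
    return (rep, report) if with_report else rep


def read_airr(path, region: str = "CDR3", sample_name: str | None = None,
              with_report: bool = False):
    """Read an AIRR Rearrangement TSV into a :class:`Repertoire`.

    ``duplicate_count`` maps to read_count and ``junction``/``junction_aa``
    to the CDR3 sequences.  When ``duplicate_count`` is absent every row is
    assigned one read and uniform fractions, and the report flags the
    assumption.  Read fractions are recomputed from counts when the file
    carries none.
    """
    if region != "CDR3":
        raise FormatError(
            "AIRR junction columns describe the CDR3 junction only; "
            f"region {region!r} is not available in this dialect")
    df = _read_tsv(path)
    cols = _resolve(df.columns, _AIRR_ALIASES, region)
    for canon in ("nt_seq", "aa_seq"):
        if cols[canon] is None:
            raise FormatError(
                f"{path}: required column {_AIRR_ALIASES[canon][0]!r} missing")
    name = sample_name or Path(path).stem
    rep, report = _assemble(df, cols, path, region, name,
                            recompute_fraction_if_missing=True)
    return (rep, report) if with_report else rep


def read_binding_table(path) -> BindingTable:
    """Read a binding CSV: first column is the amino-acid sequence key,
    every further column one antigen's numeric binding values.  Non-numeric
    cells become missing; duplicated sequence keys are an error."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: need a sequence column plus >=1 antigen column")
    key = raw.columns[0]
    frame = raw.set_index(key)
    frame.index = frame.index.astype(str).str.upper()
    for col in frame.columns:
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    return BindingTable(frame)


def build_experiment(repertoires: list[Repertoire]) -> ExperimentSet:
    """Assemble repertoires into an :class:`ExperimentSet` (unique names)."""
    if not repertoires:
        raise FormatError("build_experiment needs at least one repertoire")
    return ExperimentSet(repertoires)


def write_master_table(experiment: ExperimentSet, path) -> Path:
    """Write the master table as UTF-8 TSV; round-trip safe via
    :func:`read_master_table`."""
    path = Path(path)
    table = experiment.master_table
    table.to_csv(path, sep="\t", index=False, encoding="utf-8",
                 float_format="%.12g")
    return path


def read_master_table(path) -> ExperimentSet:
    """Re-read a master table written by :func:`write_master_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_name": str, "clone_id": str,
                                            "nt_seq": str, "aa_seq": str,
                                            "region": str},
                     keep_default_na=False, na_values=[""], encoding="utf-8")
    missing = [c for c in MASTER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: master table lacks columns {missing}")
    reps = []
    for name in df["sample_name"].unique():
        sub = df[df["sample_name"] == name]
        region = sub["region"].iloc[0]
        reps.append(Repertoire(
            str(name), sub.drop(columns=["sample_name", "region"]),
            region=region))
    return ExperimentSet(reps)
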