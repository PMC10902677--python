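"""Default trimming of clonotype tables and amino-acid aggregation.

The trimming removes nucleotide reads that are not divisible by 3, have a
clone count below 3, or are shorter than 18 nucleotides; all three
thresholds are adjustable.  A row failing several rules is attributed to
the first failing rule in the fixed order div3, count, length, so the
:class:`FilterReport` is deterministic while the keep/remove decision
itself is order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import Repertoire, RepertoireError

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Per-rule removal counts for one trimming pass."""

    sample_name: str
    input_rows: int
    output_rows: int
    not_div3: int
    low_count: int
    short_nt: int

    def __post_init__(self) -> None:
        removed = self.not_div3 + self.low_count + self.short_nt
        assert self.input_rows - self.output_rows == removed


def apply_default_trimming(rep: Repertoire, min_count: int = 3,
                           min_nt_len: int = 18, require_div3: bool = True
                           ) -> tuple[Repertoire, FilterReport]:
    """Keep records with len(nt) % 3 == 0, count >= min_count and
    len(nt) >= min_nt_len; preserve order.  Idempotent."""
    if min_count < 0 or min_nt_len < 0:
        raise RepertoireError("min_count and min_nt_len must be >= 0")

    nt_len = rep.df["nt_seq"].str.len().to_numpy()
    counts = rep.df["read_count"].to_numpy()

    fail_div3 = (nt_len % 3 != 0) if require_div3 else np.zeros(len(rep.df), bool)
    fail_count = counts < min_count
    fail_len = nt_len < min_nt_len
    keep = ~(fail_div3 | fail_count | fail_len)

    # first-failing-rule attribution: div3, then count, then length
    n_div3 = int(fail_div3.sum())
    n_count = int((fail_count & ~fail_div3).sum())
    n_len = int((fail_len & ~fail_div3 & ~fail_count).sum())

    out = rep.with_frame(rep.df[keep])
    report = FilterReport(rep.sample_name, len(rep.df), int(keep.sum()),
                          n_div3, n_count, n_len)
    log.info("%s: trimming kept %d/%d (div3=%d, count=%d, length=%d removed)",
             rep.sample_name, report.output_rows, report.input_rows,
             n_div3, n_count, n_len)
    return out, report


def recompute_fractions(rep: Repertoire) -> Repertoire:
    """Set read_fraction_i = read_count_i / total reads.

    Needed after trimming so clone fractions form a probability
    distribution over the analyzed set, which the diversity indices assume.
    """
    if rep.n_clones == 0:
        raise RepertoireError(f"{rep.sample_name}: empty repertoire")
    total = rep.total_reads
    if total <= 0:
        raise RepertoireError(f"{rep.sample_name}: total read count is 0")
    df = rep.df.copy()
    df["read_fraction"] = df["read_count"] / total
    return rep.with_frame(df)


def aggregate_by_aa(rep: Repertoire) -> Repertoire:
    """Collapse records sharing an amino-acid sequence.

    Several nucleotide clones commonly translate to the same CDR peptide;
    amino-acid-level analyses need the counts pooled.  The collapsed record
    keeps the lexicographically smallest contributing clone_id and the
    nucleotide sequence of that clone; counts are summed and fractions
    recomputed.  Output rows keep the first-appearance order of each
    aa_seq.  Total reads are conserved.
    """
    if rep.n_clones == 0:
        return rep
    df = rep.df
    grouped = df.groupby("aa_seq", sort=False).agg(
        clone_id=("clone_id", "min"),
        read_count=("read_count", "sum"),
    ).reset_index()
    # carry the nt_seq belonging to the chosen clone_id
    nt_by_id = df.set_index("clone_id")["nt_seq"]
    grouped["nt_seq"] = grouped["clone_id"].map(nt_by_id)
    total = grouped["read_count"].sum()
    grouped["read_fraction"] = grouped["read_count"] / total
    return rep.with_frame(grouped)


def standard_pipeline(rep: Repertoire, min_count: int = 3, min_nt_len: int = 18,
                      require_div3: bool = True) -> tuple[Repertoire, FilterReport]:
    """Trim, aggregate by amino acid, renormalize fractions.

    The canonical preparation step before diversity, overlap, composition
    and clustering analyses.
    """
    trimmed, report = apply_default_trimming(rep, min_count=min_count,
                                             min_nt_len=min_nt_len,
                                             require_div3=require_div3)
    if trimmed.n_clones == 0:
        return trimmed, report
    return recompute_fractions(aggregate_by_aa(trimmed)), report
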