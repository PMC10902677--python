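"""CDR length distributions and positional amino-acid composition.

Positional composition is only meaningful across sequences of identical
length: shorter CDR loops end in the middle of longer ones, so pooling
lengths over-represents the terminal positions.  The matrix here therefore
restricts to one length at a time, and the information-content transform
follows the standard logo convention IC_p = log2(20) - H_p with letter
heights f_{a,p} * IC_p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Repertoire, RepertoireError

log = logging.getLogger(__name__)

STANDARD_AA = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class LengthDistribution:
    sample_name: str
    unit: str        # "aa" or "nt"
    weighting: str   # "unique" or "read_weighted"
    histogram: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        lengths = sorted(self.histogram)
        return pd.DataFrame({"sample_name": self.sample_name,
                             "length": lengths,
                             "count": [self.histogram[l] for l in lengths]})


@dataclass
class PositionalAAMatrix:
    """Fraction of each standard amino acid at each position among the
    sequences of exactly one length.  Columns sum to 1."""

    sample_name: str
    length: int
    frame: pd.DataFrame        # rows: 20 AAs; columns: positions 1..L
    n_sequences: int           # sequences contributing (after exclusions)
    n_excluded: int            # sequences with non-standard symbols

    @property
    def positions(self) -> list[int]:
        return list(self.frame.columns)


def length_distribution(rep: Repertoire, unit: str = "aa",
                        weighting: str = "unique") -> LengthDistribution:
    """Histogram of sequence lengths.

    ``unique`` counts each distinct sequence once; ``read_weighted`` sums
    read counts per length.  ``unit`` selects amino-acid or nucleotide
    lengths.
    """
    if rep.n_clones == 0:
        raise RepertoireError(f"{rep.sample_name}: empty repertoire")
    if unit not in ("aa", "nt"):
        raise RepertoireError(f"unknown unit {unit!r}")
    if weighting not in ("unique", "read_weighted"):
        raise RepertoireError(f"unknown weighting {weighting!r}")
    col = "aa_seq" if unit == "aa" else "nt_seq"
    df = rep.df[[col, "read_count"]].copy()
    df["length"] = df[col].str.len()
    if weighting == "unique":
        hist = df.drop_duplicates(col).groupby("length").size()
    else:
        hist = df.groupby("length")["read_count"].sum()
    hist = hist[hist.index > 0]
    return LengthDistribution(rep.sample_name, unit, weighting,
                              {int(k): int(v) for k, v in hist.items()})


def positional_aa_matrix(rep: Repertoire, length: int,
                         weighting: str = "unique") -> PositionalAAMatrix:
    """Per-position amino-acid fractions among sequences of exactly
    ``length`` residues.

    Sequences containing symbols outside the 20 standard amino acids
    (translation artifacts '*', '_', ambiguous 'X', ...) are excluded and
    counted in ``n_excluded``; they are QC signals, not composition.
    Default weighting counts each distinct sequence once so one enriched
    clone cannot dominate the profile; ``read_weighted`` weights by count.
    """
    if weighting not in ("unique", "read_weighted"):
        raise RepertoireError(f"unknown weighting {weighting!r}")
    df = rep.df[rep.df["aa_seq"].str.len() == length]
    if df.empty:
        available = sorted(int(l) for l in rep.df["aa_seq"].str.len().unique())
        raise RepertoireError(
            f"{rep.sample_name}: no sequence of length {length}; "
            f"available lengths: {available}")
    if weighting == "unique":
        seqs = df.drop_duplicates("aa_seq")["aa_seq"]
        weights = np.ones(len(seqs))
    else:
        grouped = df.groupby("aa_seq", sort=False)["read_count"].sum()
        seqs = pd.Series(grouped.index)
        weights = grouped.to_numpy(float)

    aa_ok = seqs.map(lambda s: set(s) <= set(STANDARD_AA)).to_numpy()
    n_excluded = int((~aa_ok).sum())
    if n_excluded:
        log.info("%s: excluded %d sequences with non-standard symbols",
                 rep.sample_name, n_excluded)
    seqs = seqs[aa_ok]
    weights = weights[aa_ok]
    if len(seqs) == 0:
        raise RepertoireError(
            f"{rep.sample_name}: all length-{length} sequences contain "
            "non-standard symbols")

    aa_index = {a: i for i, a in enumerate(STANDARD_AA)}
    mat = np.zeros((len(STANDARD_AA), length))
    for seq, w in zip(seqs, weights):
        for pos, a in enumerate(seq):
            mat[aa_index[a], pos] += w
    mat /= mat.sum(axis=0, keepdims=True)
    frame = pd.DataFrame(mat, index=list(STANDARD_AA),
                         columns=range(1, length + 1))
    return PositionalAAMatrix(rep.sample_name, length, frame,
                              n_sequences=len(seqs), n_excluded=n_excluded)


def information_content(matrix: PositionalAAMatrix) -> pd.Series:
    """Per-position information content in bits.

    IC_p = log2(20) - H_p with H_p the positional Shannon entropy; no
    small-sample correction is applied.  IC lies in [0, log2 20].
    """
    f = matrix.frame.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f), 0.0)
    entropy = -terms.sum(axis=0)
    ic = np.log2(len(STANDARD_AA)) - entropy
    return pd.Series(np.clip(ic, 0.0, None), index=matrix.frame.columns,
                     name="bits")


def letter_heights(matrix: PositionalAAMatrix) -> pd.DataFrame:
    """Logo letter heights: f_{a,p} * IC_p (bits)."""
    return matrix.frame * information_content(matrix)
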