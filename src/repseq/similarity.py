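"""Pairwise sample-overlap indices and the similarity matrix.

Four indices over the distinct amino-acid sequences of two samples
(A, B with per-sequence counts x_i, y_i):

- Jaccard          |A∩B| / |A∪B|
- Sørensen-Dice    2|A∩B| / (|A| + |B|)
- relative overlap |A∩B| / min(|A|, |B|)  (count-free "relative index")
- Morisita-Horn    2 Σ x_i y_i / [(Σx_i²/X² + Σy_i²/Y²) · X · Y]

All lie in [0, 1], are symmetric, equal 1 on identical inputs and 0 on
disjoint supports, and satisfy jaccard <= dice <= relative.  Morisita-Horn
is the abundance-weighted index and is invariant to rescaling one sample's
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ExperimentSet, Repertoire, RepertoireError


def _aa_counts(rep: Repertoire) -> pd.Series:
    if rep.n_clones == 0:
        raise RepertoireError(f"{rep.sample_name}: empty repertoire")
    return rep.df.groupby("aa_seq")["read_count"].sum()


def _aa_set(rep: Repertoire) -> set[str]:
    if rep.n_clones == 0:
        raise RepertoireError(f"{rep.sample_name}: empty repertoire")
    return set(rep.df["aa_seq"])


def jaccard(a: Repertoire, b: Repertoire) -> float:
    sa, sb = _aa_set(a), _aa_set(b)
    return len(sa & sb) / len(sa | sb)


def sorensen_dice(a: Repertoire, b: Repertoire) -> float:
    sa, sb = _aa_set(a), _aa_set(b)
    return 2 * len(sa & sb) / (len(sa) + len(sb))


def relative_overlap(a: Repertoire, b: Repertoire) -> float:
    """Count-free overlap: shared sequences over the smaller sample's
    distinct-sequence count (overlap coefficient)."""
    sa, sb = _aa_set(a), _aa_set(b)
    return len(sa & sb) / min(len(sa), len(sb))


def morisita_horn(a: Repertoire, b: Repertoire) -> float:
    ca, cb = _aa_counts(a), _aa_counts(b)
    x, y = ca.align(cb, fill_value=0)
    x = x.to_numpy(float)
    y = y.to_numpy(float)
    X, Y = x.sum(), y.sum()
    if X <= 0 or Y <= 0:
        raise RepertoireError("Morisita-Horn needs positive read totals")
    num = 2.0 * float((x * y).sum())
    if num == 0.0:
        return 0.0
    denom = ((x ** 2).sum() / X ** 2 + (y ** 2).sum() / Y ** 2) * X * Y
    return float(num / denom)


METHODS = {
    "relative": relative_overlap,
    "morisita_horn": morisita_horn,
    "jaccard": jaccard,
    "sorensen_dice": sorensen_dice,
}


@dataclass
class SimilarityMatrix:
    sample_names: list[str]
    values: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_names,
                            columns=self.sample_names)

    def to_tsv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index_label="sample_name",
                               float_format="%.12g")
        return path

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.sample_names):
            for j, b in enumerate(self.sample_names):
                if i < j:
                    rows.append({"sample_a": a, "sample_b": b,
                                 "value": self.values[i, j]})
        return pd.DataFrame(rows)


def pairwise_matrix(experiment: ExperimentSet, method: str = "morisita_horn"
                    ) -> SimilarityMatrix:
    """Full symmetric sample-by-sample matrix of the chosen index.

    Diagonal entries are 1 by construction for non-empty samples.
    """
    if method not in METHODS:
        raise RepertoireError(f"unknown method {method!r}; choose from {list(METHODS)}")
    if len(experiment) < 2:
        raise RepertoireError("pairwise_matrix needs at least 2 samples")
    for rep in experiment:
        if rep.n_clones == 0:
            raise RepertoireError(f"sample {rep.sample_name!r} is empty")
    fn = METHODS[method]
    names = experiment.sample_names
    n = len(names)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = fn(experiment[names[i]], experiment[names[j]])
            values[i, j] = values[j, i] = v
    return SimilarityMatrix(names, values, method)
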