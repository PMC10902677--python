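"""Sequencing QC summaries, rarefaction curves, and clonal diversity.

Rarefaction follows the binning procedure: the sample's reads are
shuffled, split into ``n_bins`` near-equal bins, and the cumulative number
of distinct sequences after each bin gives one curve point per bin (100 by
default).  A plateauing curve indicates sufficient sequencing depth.

Diversity uses the clone fraction of each sequence as the probability:
Shannon H = -sum p_i ln p_i (nats by default) and Inverse Simpson
D = 1 / sum p_i^2.  Falling values across successive panning rounds
indicate enrichment of a few clones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ExperimentSet, Repertoire, RepertoireError

log = logging.getLogger(__name__)


@dataclass
class RarefactionCurve:
    sample_name: str
    depths: np.ndarray        # cumulative reads after each bin
    unique_counts: np.ndarray  # cumulative distinct sequences
    n_bins: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_name": self.sample_name,
                             "depth": self.depths,
                             "unique_sequences": self.unique_counts})


def alignment_summary(experiment: ExperimentSet,
                      upstream_totals: dict[str, tuple[int, int]] | None = None
                      ) -> pd.DataFrame:
    """Per-sample total/aligned/retained read counts.

    ``upstream_totals`` maps sample name to (total_reads, aligned_reads)
    taken from the aligner's logs; without it, both default to the read sum
    of the loaded (typically post-trimming) table.
    """
    upstream_totals = upstream_totals or {}
    unknown = set(upstream_totals) - set(experiment.sample_names)
    if unknown:
        raise RepertoireError(f"upstream totals name unknown samples: {sorted(unknown)}")
    rows = []
    for rep in experiment:
        retained = rep.total_reads
        total, aligned = upstream_totals.get(rep.sample_name, (retained, retained))
        if not retained <= aligned <= total:
            raise RepertoireError(
                f"{rep.sample_name}: expected retained <= aligned <= total, "
                f"got {retained}, {aligned}, {total}")
        rows.append({"sample_name": rep.sample_name, "total_reads": total,
                     "aligned_reads": aligned, "retained_after_trim": retained})
    return pd.DataFrame(rows)


def rarefaction_curve(rep: Repertoire, n_bins: int = 100, seed: int = 0,
                      weighting: str = "by_read") -> RarefactionCurve:
    """Shuffle the sample's reads, split into near-equal bins and count
    distinct sequences cumulatively.

    ``by_read`` expands every clone to read_count copies (abundance
    weighted, the default); ``by_clone`` puts each distinct clone in the
    pool once.  Bin sizes differ by at most one read.  Deterministic for a
    fixed seed.
    """
    if rep.n_clones == 0:
        raise RepertoireError(f"{rep.sample_name}: empty repertoire")
    if n_bins < 1:
        raise RepertoireError("n_bins must be >= 1")
    if weighting not in ("by_read", "by_clone"):
        raise RepertoireError(f"unknown weighting {weighting!r}")

    codes, _ = pd.factorize(rep.df["aa_seq"])
    if weighting == "by_read":
        pool = np.repeat(codes, rep.df["read_count"].to_numpy())
    else:
        pool = np.unique(codes)
    n = len(pool)
    if n_bins > n:
        raise RepertoireError(
            f"{rep.sample_name}: n_bins={n_bins} exceeds the pool of {n} "
            f"reads; lower n_bins")

    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(pool)
    # position of each sequence's first appearance in the shuffled pool
    _, first_idx = np.unique(shuffled, return_index=True)
    first_idx.sort()

    base, extra = divmod(n, n_bins)
    sizes = np.full(n_bins, base, dtype=np.int64)
    sizes[:extra] += 1
    depths = np.cumsum(sizes)
    unique_counts = np.searchsorted(first_idx, depths, side="left")
    return RarefactionCurve(rep.sample_name, depths, unique_counts, n_bins, seed)


def _fractions(rep: Repertoire) -> np.ndarray:
    if rep.n_clones == 0:
        raise RepertoireError(f"{rep.sample_name}: empty repertoire")
    p = rep.df.loc[rep.df["read_count"] > 0, "read_fraction"].to_numpy(float)
    if len(p) == 0 or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise RepertoireError(
            f"{rep.sample_name}: clone fractions sum to {p.sum():.6f}, not 1; "
            "apply recompute_fractions first")
    return p


def shannon_index(rep: Repertoire, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over clone fractions.

    Natural log by default; pass ``base=2`` for bits.
    """
    p = _fractions(rep)
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return max(h, 0.0)


def inverse_simpson(rep: Repertoire) -> float:
    """Inverse Simpson diversity D = 1 / sum p_i^2 over clone fractions."""
    p = _fractions(rep)
    return float(1.0 / (p ** 2).sum())


_METRICS = {"shannon": shannon_index, "inverse_simpson": inverse_simpson}


def diversity_table(experiment: ExperimentSet, metric: str = "shannon"
                    ) -> pd.DataFrame:
    """One diversity value per sample, in set order."""
    if metric not in _METRICS:
        raise RepertoireError(f"unknown metric {metric!r}; choose from {list(_METRICS)}")
    fn = _METRICS[metric]
    rows = []
    for rep in experiment:
        try:
            value = fn(rep)
        except RepertoireError as err:
            raise RepertoireError(f"sample {rep.sample_name!r}: {err}") from err
        rows.append({"sample_name": rep.sample_name, "metric": metric,
                     "value": value})
    return pd.DataFrame(rows)
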