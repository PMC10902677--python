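"""Synthetic phage-display panning campaigns with known ground truth.

The generator emulates the data a biopanning experiment produces: a large,
diverse naive library (round 0) whose clone frequencies collapse toward a
few enriched binders over successive selection rounds.  Each clone i
carries a log-scale selection coefficient s_i; round t+1 frequencies are
proportional to f_t,i * exp(s_i) and read counts are multinomial
resamples at fixed sequencing depth.  With all coefficients zero the
process is neutral drift; a spike of strongly positive coefficients
produces the enrichment regime.  Binding assay values are a sigmoid of
the coefficient plus Gaussian noise, assigned to a configurable fraction
of clones, so every downstream stage — trimming, diversity, overlap,
clustering, binding overlay, candidate discovery — can be tested against
known truth.

Nucleotide sequences are obtained by reverse-translating the CDR3
peptides with uniformly chosen synonymous codons, so generated reads are
in frame, divisible by 3 and at least 18 nt whenever the peptide has 6 or
more residues — they survive the default trimming deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import STANDARD_AA
from .types import RepertoireError

# standard genetic code, grouped by amino acid (stop codons excluded)
CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}

MIXCR_COLUMNS = ("cloneId", "readCount", "readFraction", "nSeqCDR3", "aaSeqCDR3")


@dataclass
class PanningSimConfig:
    """Study conditions for one simulated campaign.

    Defaults describe a mid-sized campaign: a 5000-clone starting library
    sequenced at 100k reads per round over three selection rounds, mild
    background selection (sigma 0.5) and five strong binders (coefficient
    3, ~20x per-round advantage).  Half the final-round clones receive
    binding labels; assay noise has SD 0.05 on the 0-1 binding scale.
    """

    n_clones_initial: int = 5000
    n_rounds: int = 3
    reads_per_round: int = 100_000
    selection_sigma: float = 0.5
    n_strong_binders: int = 5
    strong_coefficient: float = 3.0
    cdr3_length_range: tuple[int, int] = (8, 20)
    dirichlet_alpha: float = 1.0
    fraction_with_binding_labels: float = 0.5
    binding_noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_clones_initial < 1 or self.n_rounds < 0 or self.reads_per_round < 1:
            raise RepertoireError("clone, round and read counts must be positive")
        lo, hi = self.cdr3_length_range
        if not (6 <= lo <= hi <= 30):
            raise RepertoireError("cdr3_length_range must lie within [6, 30]")
        if not 0.0 <= self.fraction_with_binding_labels <= 1.0:
            raise RepertoireError("fraction_with_binding_labels must be in [0, 1]")
        if self.selection_sigma < 0 or self.binding_noise_sd < 0:
            raise RepertoireError("sigma parameters must be >= 0")
        if self.n_strong_binders > self.n_clones_initial:
            raise RepertoireError("more strong binders than clones")


@dataclass
class PanningCampaign:
    """Simulated campaign: per-round clonotype tables plus ground truth."""

    config: PanningSimConfig
    truth: pd.DataFrame          # clone_id, aa_seq, nt_seq, coefficient
    counts: np.ndarray           # (n_rounds+1, n_clones) read counts

    @property
    def n_rounds(self) -> int:
        return self.counts.shape[0] - 1

    def round_table(self, round_idx: int) -> pd.DataFrame:
        """MiXCR-style clonotype table for one round (clones with reads)."""
        c = self.counts[round_idx]
        present = c > 0
        total = c[present].sum()
        return pd.DataFrame({
            "cloneId": self.truth.loc[present, "clone_id"].to_numpy(),
            "readCount": c[present],
            "readFraction": c[present] / total,
            "nSeqCDR3": self.truth.loc[present, "nt_seq"].to_numpy(),
            "aaSeqCDR3": self.truth.loc[present, "aa_seq"].to_numpy(),
        })

    def frequencies(self, round_idx: int) -> np.ndarray:
        c = self.counts[round_idx].astype(float)
        return c / c.sum()


def _random_peptides(n: int, length_range: tuple[int, int],
                     rng: np.random.Generator) -> list[str]:
    """n distinct random peptides with lengths uniform in the range."""
    aa = np.array(list(STANDARD_AA))
    lo, hi = length_range
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(aa[rng.integers(0, len(aa), size=length)])
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def reverse_translate(aa_seq: str, rng: np.random.Generator) -> str:
    """Back-translate a peptide with uniformly chosen synonymous codons."""
    return "".join(CODONS[a][rng.integers(0, len(CODONS[a]))] for a in aa_seq)


def simulate_panning(cfg: PanningSimConfig) -> PanningCampaign:
    """Run the multinomial selection-resampling process.

    Round 0 abundances come from a flat Dirichlet prior; each later round
    reweights the previous round's frequencies by exp(coefficient) and
    resamples ``reads_per_round`` reads.  Clones lost to drift stay lost.
    Fully deterministic for a fixed config seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_clones_initial

    peptides = _random_peptides(n, cfg.cdr3_length_range, rng)
    nt = [reverse_translate(p, rng) for p in peptides]
    coef = rng.normal(0.0, cfg.selection_sigma, size=n)
    if cfg.n_strong_binders:
        strong = rng.choice(n, size=cfg.n_strong_binders, replace=False)
        coef[strong] = cfg.strong_coefficient

    width = len(str(n))
    truth = pd.DataFrame({
        "clone_id": [f"c{i:0{width}d}" for i in range(n)],
        "aa_seq": peptides,
        "nt_seq": nt,
        "coefficient": coef,
    })

    counts = np.zeros((cfg.n_rounds + 1, n), dtype=np.int64)
    freq = rng.dirichlet(np.full(n, cfg.dirichlet_alpha))
    counts[0] = rng.multinomial(cfg.reads_per_round, freq)
    fitness = np.exp(coef)
    for t in range(1, cfg.n_rounds + 1):
        f = counts[t - 1].astype(float)
        w = f * fitness
        total = w.sum()
        if total <= 0:
            raise RepertoireError("campaign went extinct; raise reads_per_round")
        counts[t] = rng.multinomial(cfg.reads_per_round, w / total)
    return PanningCampaign(cfg, truth, counts)


def simulate_binding(campaign: PanningCampaign, round_idx: int = -1,
                     antigen: str = "antigen_1",
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Noisy immunoassay labels for a fraction of one round's clones.

    Binding value = sigmoid(selection coefficient) + N(0, noise_sd), so
    with zero noise the binding rank order equals the coefficient rank
    order.  Returns a frame (aa_seq, <antigen>) compatible with
    :func:`repseq.io.read_binding_table` once written as CSV.
    """
    cfg = campaign.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    c = campaign.counts[round_idx]
    present = np.flatnonzero(c > 0)
    if present.size == 0:
        raise RepertoireError("no clones present in the requested round")
    n_label = int(round(cfg.fraction_with_binding_labels * present.size))
    chosen = np.sort(rng.choice(present, size=n_label, replace=False))
    coef = campaign.truth.loc[chosen, "coefficient"].to_numpy()
    values = 1.0 / (1.0 + np.exp(-coef))
    if cfg.binding_noise_sd > 0:
        values = values + rng.normal(0.0, cfg.binding_noise_sd, size=n_label)
    return pd.DataFrame({
        "aa_seq": campaign.truth.loc[chosen, "aa_seq"].to_numpy(),
        antigen: values,
    })


def plant_unlabeled_neighbor(campaign: PanningCampaign, binding: pd.DataFrame,
                             antigen: str, rng: np.random.Generator,
                             round_idx: int = -1, top_n: int = 200
                             ) -> tuple[pd.DataFrame, str, str]:
    """Add a 1-substitution, unlabeled neighbor of the top labeled binder.

    Returns the modified round table, the planted sequence and its labeled
    parent.  The parent is the highest-binding labeled clone among the
    round's ``top_n`` most abundant (assayed antibodies are picked from
    abundant clones), and the planted clone inherits its read count — the
    situation candidate discovery is for: an abundant, untested
    near-relative of a known strong binder.
    """
    abundant_table = campaign.round_table(round_idx).nlargest(top_n, "readCount")
    abundant = set(abundant_table["aaSeqCDR3"])
    pool = binding[binding["aa_seq"].isin(abundant)]
    if pool.empty:
        pool = binding
    top = pool.loc[pool[antigen].idxmax(), "aa_seq"]
    existing = set(campaign.truth["aa_seq"]) | set(binding["aa_seq"])
    aa = list(STANDARD_AA)
    variant = None
    for _ in range(1000):
        pos = int(rng.integers(0, len(top)))
        sub = aa[int(rng.integers(0, len(aa)))]
        cand = top[:pos] + sub + top[pos + 1:]
        if cand != top and cand not in existing:
            variant = cand
            break
    if variant is None:
        raise RepertoireError("could not plant a novel 1-edit neighbor")
    table = campaign.round_table(round_idx)
    parent_count = int(table.loc[table["aaSeqCDR3"] == top, "readCount"].iloc[0])
    planted = pd.DataFrame([{
        "cloneId": "planted",
        "readCount": parent_count,
        "readFraction": 0.0,
        "nSeqCDR3": reverse_translate(variant, rng),
        "aaSeqCDR3": variant,
    }])
    table = pd.concat([table, planted], ignore_index=True)
    table["readFraction"] = table["readCount"] / table["readCount"].sum()
    return table, variant, top


def write_campaign(campaign: PanningCampaign, out_dir,
                   antigen: str = "antigen_1") -> dict[str, Path]:
    """Write round_0.tsv .. round_k.tsv, binding.csv and truth.tsv.

    Output is byte-reproducible for a fixed config (all randomness flows
    from the config seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for t in range(campaign.n_rounds + 1):
        p = out_dir / f"round_{t}.tsv"
        campaign.round_table(t).to_csv(p, sep="\t", index=False,
                                       float_format="%.12g")
        paths[f"round_{t}"] = p
    binding = simulate_binding(campaign, antigen=antigen)
    p = out_dir / "binding.csv"
    binding.to_csv(p, index=False, float_format="%.12g")
    paths["binding"] = p
    p = out_dir / "truth.tsv"
    campaign.truth.to_csv(p, sep="\t", index=False, float_format="%.12g")
    paths["truth"] = p
    return paths
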