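# Methods

## Input model and preprocessing

A clonotype table assigns each distinct CDR sequence (HCDR3 by default) a
read count within one sample; a campaign is an ordered set of such tables,
one per panning round. Two dialects are read: MiXCR export columns
(`readCount`, `readFraction`, `nSeq<REGION>`, `aaSeq<REGION>`) and AIRR
Rearrangement columns (`duplicate_count`, `junction`, `junction_aa`;
CDR3 only, since AIRR junction columns are defined for the junction).
Column matching is case-sensitive against these alias lists; files are
UTF-8, tab-delimited, `.` decimal. Sequences are upper-cased and `U→T`
mapped on ingest. Rows with an empty nucleotide sequence for the selected
region are dropped and counted in a load report (kept + dropped = total).

Read fractions present in the file are kept verbatim — the upstream
aligner computed them on pre-trimming totals and that provenance is worth
preserving — and `recompute_fractions` renormalizes when a probability
distribution is required. When AIRR files carry no `duplicate_count`,
each row is assigned one read and uniform fractions, flagged in the load
report.

Trimming removes nucleotide reads that are (i) not divisible by 3,
(ii) supported by fewer than 3 reads, or (iii) shorter than 18 nt;
defaults adjustable, each rule individually disableable. The keep/remove
decision is a conjunction and therefore order-independent; for reporting,
a multiply-failing row is attributed to the first failing rule in the
fixed order div3 → count → length so filter reports are deterministic.
Trimming always tests nucleotide length, even for amino-acid analyses,
because the rules are statements about reads. After trimming, analyses
run on amino-acid-aggregated repertoires (nucleotide clones sharing a
peptide are pooled; the lexicographically smallest clone id survives)
with fractions recomputed, so clone fractions form a probability
distribution over the analyzed set.

## Rarefaction

The sample's reads (each clone repeated `read_count` times) are shuffled
with a user-supplied seed, split into `n_bins` (default 100) bins whose
sizes differ by at most one, and the cumulative number of distinct
sequences after each bin is reported. The final point equals (total
reads, total distinct sequences) by construction. A `by_clone` mode puts
each distinct clone in the pool once, answering a different question
(order-of-discovery among clones rather than read-level depth); the
read-weighted variant is the default because depth sufficiency is a
read-level question. Curves are non-decreasing; concavity is not
guaranteed pointwise because of sampling noise.

## Diversity

Shannon H = −Σ pᵢ ln pᵢ (natural log; a `base` argument gives bits) and
Inverse Simpson D = 1/Σ pᵢ², with pᵢ the clone fraction. Both are
computed on trimmed, AA-aggregated, renormalized repertoires; an input
whose fractions do not sum to 1 is rejected rather than silently
renormalized. H ∈ [0, ln n] and D ∈ [1, n], both maximal at uniformity.

## Overlap indices

All four indices operate on distinct amino-acid sequence sets (exact
identity; no fuzziness): Jaccard, Sørensen–Dice, relative overlap, and
Morisita–Horn on count vectors over the union of sequences. The
"relative" index is implemented as the overlap coefficient
|A∩B|/min(|A|,|B|): it ignores abundance, as a count-free index must, and
differs from Jaccard by its denominator. The chain
jaccard ≤ dice ≤ relative holds because |A∪B| ≥ (|A|+|B|)/2 ≥ min(|A|,|B|).
Morisita–Horn is invariant to rescaling either sample's counts, hence
robust to unequal sequencing depth.

## Composition

Length histograms count distinct sequences (default) or reads. The
positional amino-acid matrix restricts to sequences of exactly one
length — pooling lengths over-represents terminal positions because
shorter loops end mid-way through longer ones. Sequences containing
symbols outside the 20 standard amino acids ('*', '_', 'X') are excluded
whole and counted, keeping every column an exact probability
distribution; per-position exclusion would break that invariant.
Unique-sequence weighting is the default so an enriched clone cannot
dominate the profile. Information content uses the logo convention
IC = log₂20 − H per column, letter heights f·IC, with no small-sample
correction.

## Levenshtein clustering

`levenshtein` is unit-cost edit distance, computed by edlib's exact
algorithm; the test suite pins it against the textbook recursive
definition exhaustively over all string pairs up to length 6 on a
3-letter alphabet, and property-checks the metric axioms on random
peptides. The all-pairs matrix is O(N²·L²), so inputs are capped at the
top N = 200 sequences by pooled read count (ties lexicographic; cap
overridable or disableable). Dendrograms use scipy hierarchical
clustering, average linkage (UPGMA) by default — a standard choice for
repertoire clustering — with scipy's deterministic merge order; Newick
export assigns each child a branch length of parent merge height minus
child merge height. Node graphs connect sequences at LD ≤ cutoff;
components are labeled deterministically by their lexicographically
smallest member and are nested as the cutoff grows.

## SGT embedding and projection

For a sequence s and ordered symbol pair (u, v), the Sequence Graph
Transform feature is

ψ(u,v) = ( Σ_{l<m, s_l=u, s_m=v} e^(−κ(m−l)) / Z )^(1/κ),

with Z the number of occurrences of u (length-insensitive default) or
additionally multiplied by the sequence length (length-sensitive).
κ (default 1) controls how fast influence decays with the gap; the
feature is 0 exactly when v never follows u. The alphabet is the 20
standard amino acids, giving 400-dimensional vectors; out-of-alphabet
symbols are dropped with a warning. The length-insensitive variant is the
default because CDR loops vary in length and the embedding exists
precisely to compare across lengths.

Projection to 2-D standardizes the vectors, applies PCA to
min(50, n, dim) components, then t-SNE with a fixed seed — the standard
composition when both are used together. Perplexity is lowered to just
under (n−1)/3 with a logged warning for small n. Identical sequences map
to identical vectors and near-coincident 2-D points. Any callable from a
sequence list to a vector array (e.g. a pretrained protein language
model) can replace `sgt_embed` upstream of the projection; none ships
with the package.

## Binding integration

Binding CSVs map amino-acid sequences to numeric per-antigen values;
non-numeric cells become missing, duplicate keys are an error.
`overlay_binding` is a left join onto analysis points (labeled sequences
absent from the points are reported, not an error). Candidate discovery
ranks unlabeled sequences within an LD cutoff of any labeled sequence
whose binding meets a threshold, each with its closest qualifying
neighbor (ties toward the higher-binding neighbor), sorted by ascending
LD then descending neighbor binding.

## Synthetic campaigns

The generator draws n distinct CDR3 peptides (lengths uniform on 8–20 aa
by default), round-0 abundances from a flat Dirichlet (α = 1), and
per-clone log-selection coefficients from Normal(0, σ = 0.5) with a spike
of 5 strong binders at coefficient 3 (~20-fold per-round advantage) —
producing both a neutral background and a clearly enriched regime. Each
round resamples reads multinomially with frequencies ∝ previous frequency
× e^coefficient at a fixed depth (default 100 000 reads over 3 selection
rounds from a 5000-clone library, a mid-sized campaign). Nucleotide
sequences are reverse-translated with uniform synonymous codons, so
simulated reads are in frame and survive default trimming by
construction. Binding labels are sigmoid(coefficient) + Gaussian noise
(SD 0.05) on a random half of a round's clones. All randomness flows from
one config seed; outputs are byte-reproducible.

What the simulator does not model: PCR amplification bias, sequencing
error, primer artifacts, V/J context around the CDR, paired chains, or
clone-dependent display efficiency. Passing tests therefore demonstrate
correct recovery of multinomial selection dynamics, not robustness to
platform noise.

For end-to-end recovery checks, a 1-substitution neighbor of the top
labeled binder is planted unlabeled with its parent's read count; the
parent is chosen among the round's 200 most abundant clones because
assayed antibodies are in practice picked from abundant clones, and the
candidate search operates on the same top-200 pool the clustering cap
defines. Smaller configurations (120–300 clones, a few thousand reads)
are used in unit tests where only structural properties are asserted;
the parameter-recovery suite runs 20 campaigns at the default
conditions.

## Numerical and determinism choices

Fractions are validated to 1e-6 and written with `%.12g`, giving 1e-9
round-trip accuracy on the master table. Every stochastic step
(rarefaction shuffle, simulation, t-SNE) takes an explicit seed, and
`run_all` records all seeds and parameters in `manifest.json`; two runs
with the same config produce byte-identical TSV outputs. Empty
repertoires, unnormalized fractions, unknown samples/antigens and
out-of-range parameters raise typed errors naming the offending sample
or column rather than propagating NaNs.

## Known limitations

- The LD cap (top 200 by count) means dendrograms and graphs describe the
  abundant repertoire, not its long tail.
- AIRR input is limited to the CDR3 junction; MiXCR input supports any
  exported region.
- The overlap indices have no depth-correction beyond Morisita–Horn's
  scale invariance; rare-clone overlap between shallowly sequenced
  samples is underestimated.
- t-SNE coordinates are seed-stable but not comparable across runs with
  different inputs; only neighborhood structure is meaningful.
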