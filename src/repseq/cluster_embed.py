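"""Sequence clustering by Levenshtein distance, SGT embedding with
PCA + t-SNE projection, and binding-data integration.

Levenshtein distance (LD) is the minimum number of unit-cost
substitutions, insertions and deletions turning one string into the
other; LD("CAT", "BAD") = 2 and LD("CAT", "CATS") = 1.  Applied to CDR
peptides it groups clonal families: dendrograms from the all-pairs LD
matrix, or node graphs connecting sequences within an LD cutoff.

The Sequence Graph Transform (SGT) embeds a variable-length sequence as a
fixed |alphabet|^2 vector: the feature for the ordered symbol pair (u, v)
summarises, with exponential decay e^(-kappa*gap), how closely v tends to
follow u.  It ignores residue chemistry but captures the characteristic
relative positioning of letters, so sequences of different lengths become
directly comparable.  Any callable mapping a sequence list to a 2-D array
(for example a pretrained protein language model) can be plugged in
instead of :func:`sgt_embed` wherever vectors are consumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib
import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.preprocessing import StandardScaler

from .composition import STANDARD_AA
from .types import BindingTable, RepertoireError

log = logging.getLogger(__name__)

DEFAULT_TOP_N = 200


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance between two strings (possibly empty)."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    return int(edlib.align(a, b, task="distance")["editDistance"])


def select_top_sequences(seqs: list[str], counts: list[int] | None,
                         top_n: int) -> list[str]:
    """Highest-count ``top_n`` sequences, ties broken lexicographically.

    Duplicate sequences are pooled first.  With no counts, sequences are
    ranked purely lexicographically after deduplication.
    """
    if counts is None:
        pooled = sorted(set(seqs))
    else:
        totals: dict[str, int] = {}
        for s, c in zip(seqs, counts):
            totals[s] = totals.get(s, 0) + int(c)
        pooled = sorted(totals, key=lambda s: (-totals[s], s))
    return pooled[:top_n]


@dataclass
class DistanceMatrix:
    sequences: list[str]
    values: np.ndarray
    metric: str = "levenshtein"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sequences,
                            columns=self.sequences)


def ld_matrix(seqs: list[str], counts: list[int] | None = None,
              top_n: int | None = DEFAULT_TOP_N) -> DistanceMatrix:
    """All-pairs Levenshtein matrix.

    The all-pairs cost is quadratic, so inputs larger than ``top_n``
    (default 200) are reduced to the highest-count sequences first; pass
    ``top_n=None`` to disable the cap.
    """
    if top_n is not None and len(set(seqs)) > top_n:
        seqs = select_top_sequences(seqs, counts, top_n)
        log.info("LD matrix capped to top %d sequences", top_n)
    else:
        seqs = list(dict.fromkeys(seqs))  # dedupe, keep order
    if len(seqs) < 2:
        raise RepertoireError("ld_matrix needs at least 2 distinct sequences")
    n = len(seqs)
    values = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d = levenshtein(seqs[i], seqs[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(list(seqs), values)


def dendrogram(mat: DistanceMatrix, method: str = "average") -> np.ndarray:
    """Hierarchical clustering of the LD matrix.

    Returns the scipy linkage matrix (rooted binary merge tree; row i
    merges two clusters at height Z[i, 2]).  Use :func:`to_newick` to
    export.  Average linkage (UPGMA) by default.
    """
    if method not in ("average", "single", "complete"):
        raise RepertoireError(f"unknown linkage {method!r}")
    condensed = squareform(mat.values.astype(float), checks=False)
    return linkage(condensed, method=method)


def to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Newick export of a linkage tree; a child's branch length is its
    parent's merge height minus its own (0 at leaves)."""
    root = to_tree(link)

    def fmt(node, parent_dist: float) -> str:
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = fmt(node.left, node.dist)
        right = fmt(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = fmt(root.left, root.dist)
    right = fmt(root.right, root.dist)
    return f"({left},{right}):0;"


def ld_graph(seqs: list[str], cutoff: int,
             samples: list[str] | None = None,
             counts: list[int] | None = None,
             binding: dict[str, float] | None = None) -> nx.Graph:
    """Undirected graph connecting sequences whose LD is <= ``cutoff``.

    Node attributes carry sample, count and binding value when provided;
    every node gets a deterministic ``component`` label (components are
    numbered by their lexicographically smallest member).  Components at
    cutoff k are nested within components at any larger cutoff.
    """
    if cutoff < 1:
        raise RepertoireError("cutoff must be >= 1")
    order = list(dict.fromkeys(seqs))
    g = nx.Graph(cutoff=cutoff)
    for idx, s in enumerate(seqs):
        if s in g:
            if counts is not None:
                g.nodes[s]["count"] += int(counts[idx])
            continue
        attrs = {}
        if samples is not None:
            attrs["sample"] = samples[idx]
        if counts is not None:
            attrs["count"] = int(counts[idx])
        if binding is not None and s in binding:
            attrs["binding"] = float(binding[s])
        g.add_node(s, **attrs)
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            d = levenshtein(order[i], order[j])
            if d <= cutoff:
                g.add_edge(order[i], order[j], ld=int(d))
    comps = sorted(nx.connected_components(g), key=min)
    for label, comp in enumerate(comps):
        for s in comp:
            g.nodes[s]["component"] = label
    return g


# ---------------------------------------------------------------------------
# SGT embedding


def _sgt_single(seq: str, alphabet: tuple[str, ...], kappa: float,
                length_sensitive: bool) -> np.ndarray:
    index = {a: i for i, a in enumerate(alphabet)}
    k = len(alphabet)
    positions: dict[int, list[int]] = {}
    for pos, ch in enumerate(seq):
        positions.setdefault(index[ch], []).append(pos)
    w = np.zeros((k, k))
    for u, pu in positions.items():
        pu_arr = np.asarray(pu, dtype=float)
        for v, pv in positions.items():
            gaps = np.subtract.outer(np.asarray(pv, dtype=float), pu_arr)
            ahead = gaps[gaps > 0]
            if ahead.size:
                w[u, v] = np.exp(-kappa * ahead).sum()
    z = np.zeros(k)
    for u, pu in positions.items():
        z[u] = len(pu)
    if length_sensitive:
        z = z * max(len(seq), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        psi = np.where((w > 0) & (z[:, None] > 0),
                       (w / z[:, None]) ** (1.0 / kappa), 0.0)
    return psi.ravel()


def sgt_embed(seqs: list[str], kappa: float = 1.0,
              alphabet: tuple[str, ...] = STANDARD_AA,
              length_sensitive: bool = False) -> np.ndarray:
    """SGT feature vectors, one row per sequence, dimension |alphabet|^2.

    For each ordered symbol pair (u, v) the feature is
    ``(sum_{l<m, s_l=u, s_m=v} exp(-kappa (m-l)) / Z)^(1/kappa)`` with
    Z the number of occurrences of u (times the sequence length in the
    length-sensitive variant).  Pairs never observed give 0.  kappa tunes
    how quickly influence decays with the gap; symbols outside the
    alphabet are dropped with a warning.  The length-insensitive default
    suits comparing CDR loops of different lengths.
    """
    if kappa <= 0:
        raise RepertoireError("kappa must be > 0")
    allowed = set(alphabet)
    cleaned = []
    n_dropped = 0
    for s in seqs:
        kept = "".join(ch for ch in s if ch in allowed)
        n_dropped += len(s) - len(kept)
        cleaned.append(kept)
    if n_dropped:
        log.warning("sgt_embed: dropped %d symbols outside the alphabet",
                    n_dropped)
    return np.vstack([_sgt_single(s, tuple(alphabet), kappa, length_sensitive)
                      for s in cleaned])


def reduce_to_2d(vectors: np.ndarray, pca_dims: int = 50,
                 perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """Project embedding vectors to 2-D: standardize, PCA, then t-SNE.

    PCA components are capped at min(pca_dims, n, dim); the t-SNE
    perplexity is lowered to just under (n-1)/3 with a logged warning when
    the sample is too small for the requested value.  Deterministic for a
    fixed seed.
    """
    vectors = np.asarray(vectors, dtype=float)
    n = len(vectors)
    if n < 4:
        raise RepertoireError("need at least 4 points for a 2-D projection")
    scaled = StandardScaler().fit_transform(vectors)
    n_comp = min(pca_dims, n, vectors.shape[1])
    reduced = PCA(n_components=n_comp, random_state=seed).fit_transform(scaled)
    max_perp = (n - 1) / 3.0
    if perplexity >= max_perp:
        new_perp = max(max_perp * 0.999, 1.0)
        log.warning("perplexity %.3g too large for n=%d; lowered to %.3g",
                    perplexity, n, new_perp)
        perplexity = new_perp
    tsne = TSNE(n_components=2, perplexity=perplexity, init="pca",
                random_state=seed)
    return tsne.fit_transform(reduced)


# ---------------------------------------------------------------------------
# binding-data integration


def overlay_binding(points: pd.DataFrame, binding: BindingTable,
                    antigen: str) -> tuple[pd.DataFrame, list[str]]:
    """Annotate a point table (column ``aa_seq``) with binding values.

    Returns the annotated copy (missing values NaN) plus the list of
    binding-table sequences that matched no point — reported, not an
    error, since assays typically cover only a subset.
    """
    values = binding.values_for(antigen)
    out = points.copy()
    out["binding"] = out["aa_seq"].map(values)
    unmatched = sorted(set(values.dropna().index) - set(points["aa_seq"]))
    if unmatched:
        log.info("overlay_binding: %d labeled sequences not among the points",
                 len(unmatched))
    return out, unmatched


def nearest_labeled_neighbors(seqs: list[str], binding: BindingTable,
                              antigen: str, ld_cutoff: int = 2,
                              min_binding: float = 0.0) -> pd.DataFrame:
    """Unlabeled sequences within ``ld_cutoff`` edits of a strong binder.

    A labeled sequence qualifies when its binding for ``antigen`` is at
    least ``min_binding``.  Each unlabeled sequence within the cutoff of
    any qualifying sequence is reported with its closest such neighbor
    (ties resolved toward the higher-binding neighbor), the LD and the
    neighbor's binding value; sorted by ascending LD, then descending
    neighbor binding.  This is the shortlist of untested antibodies most
    similar to known high-affinity binders.
    """
    values = binding.values_for(antigen).dropna()
    qualified = values[values >= min_binding]
    if qualified.empty:
        raise RepertoireError(
            f"no labeled sequence reaches min_binding={min_binding}")
    labeled_set = set(values.index)
    unlabeled = [s for s in dict.fromkeys(seqs) if s not in labeled_set]
    # tie-break order: for equal LD prefer higher binding, then lexicographic
    neighbors = sorted(qualified.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = []
    for s in unlabeled:
        best = None
        for nb, val in neighbors:
            d = levenshtein(s, nb)
            if d <= ld_cutoff and (best is None or d < best[1]):
                best = (nb, d, val)
                if d == 0:
                    break
        if best is not None:
            rows.append({"aa_seq": s, "neighbor": best[0], "ld": best[1],
                         "neighbor_binding": best[2]})
    out = pd.DataFrame(rows, columns=["aa_seq", "neighbor", "ld",
                                      "neighbor_binding"])
    if len(out):
        out = out.sort_values(["ld", "neighbor_binding", "aa_seq"],
                              ascending=[True, False, True],
                              ignore_index=True)
    return out
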