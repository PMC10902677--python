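"""End-to-end campaign analysis: load -> trim -> aggregate -> QC ->
diversity -> overlap -> composition -> clustering/embedding -> binding.

Every stage writes plain TSV tables into the output directory and
registers them in a machine-readable ``manifest.json`` (inputs,
parameters, seeds, per-stage outputs and row counts).  With fixed seeds
the directory contents are byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import cluster_embed, composition, io, preprocess, qc_diversity, similarity
from .types import ExperimentSet, RepertoireError

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    inputs: list[str]
    dialect: str = "mixcr"            # "mixcr" | "airr"
    region: str = "CDR3"
    min_count: int = 3
    min_nt_len: int = 18
    require_div3: bool = True
    n_bins: int = 100
    seed: int = 0
    methods: tuple[str, ...] = ("relative", "morisita_horn", "jaccard",
                                "sorensen_dice")
    top_n: int = 200
    ld_cutoff: int = 2
    linkage: str = "average"
    kappa: float = 1.0
    pca_dims: int = 50
    perplexity: float = 30.0
    binding_csv: str | None = None
    antigen: str | None = None
    min_binding: float = 0.5
    out_dir: str = "repseq_out"
    metadata: dict = field(default_factory=dict)


class _Manifest:
    def __init__(self, config: RunConfig):
        cfg = asdict(config)
        cfg["methods"] = list(config.methods)
        self.data = {"config": cfg, "stages": []}

    def add(self, stage: str, outputs: dict[str, int], **params) -> None:
        self.data["stages"].append(
            {"stage": stage, "outputs": outputs, "params": params})

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return len(df)


def _stage(name):
    """Re-raise stage failures with the stage name attached."""
    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r} failed: {exc}") from exc
            return False
    return _ctx()


class _StageError(RepertoireError):
    pass


def run_all(config: RunConfig) -> Path:
    """Run the full analysis and return the output directory."""
    if not config.inputs:
        raise RepertoireError("run_all needs at least one input file")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    reader = {"mixcr": io.read_mixcr_clones, "airr": io.read_airr}.get(config.dialect)
    if reader is None:
        raise RepertoireError(f"unknown dialect {config.dialect!r}")

    # load + preprocess -------------------------------------------------
    with _stage("load"):
        raw, reports = [], []
        for path in config.inputs:
            rep, rpt = reader(path, region=config.region, with_report=True)
            raw.append(rep)
            reports.append(rpt)
    with _stage("trim"):
        prepared, trim_rows = [], []
        for rep in raw:
            clean, fr = preprocess.standard_pipeline(
                rep, min_count=config.min_count, min_nt_len=config.min_nt_len,
                require_div3=config.require_div3)
            prepared.append(clean)
            trim_rows.append({"sample_name": fr.sample_name,
                              "input_rows": fr.input_rows,
                              "output_rows": fr.output_rows,
                              "not_div3": fr.not_div3,
                              "low_count": fr.low_count,
                              "short_nt": fr.short_nt})
        n = _write(pd.DataFrame(trim_rows), out / "filter_report.tsv")
        manifest.add("trim", {"filter_report.tsv": n},
                     min_count=config.min_count, min_nt_len=config.min_nt_len,
                     require_div3=config.require_div3)

    with _stage("master_table"):
        experiment = io.build_experiment(prepared)
        io.write_master_table(experiment, out / "master_table.tsv")
        manifest.add("master_table",
                     {"master_table.tsv": len(experiment.master_table)})

    # QC + diversity ----------------------------------------------------
    with _stage("alignment_summary"):
        summary = qc_diversity.alignment_summary(experiment)
        raw_totals = {r.sample_name: r.total_reads for r in raw}
        summary["total_reads"] = summary["sample_name"].map(raw_totals)
        summary["aligned_reads"] = summary["total_reads"]
        n = _write(summary, out / "alignment_summary.tsv")
        manifest.add("alignment_summary", {"alignment_summary.tsv": n})

    with _stage("rarefaction"):
        outputs = {}
        for rep in experiment:
            curve = qc_diversity.rarefaction_curve(
                rep, n_bins=min(config.n_bins, rep.total_reads),
                seed=config.seed)
            name = f"rarefaction_{rep.sample_name}.tsv"
            outputs[name] = _write(curve.to_frame(), out / name)
        manifest.add("rarefaction", outputs, n_bins=config.n_bins,
                     seed=config.seed)

    with _stage("diversity"):
        tables = [qc_diversity.diversity_table(experiment, metric=m)
                  for m in ("shannon", "inverse_simpson")]
        n = _write(pd.concat(tables, ignore_index=True), out / "diversity.tsv")
        manifest.add("diversity", {"diversity.tsv": n})

    # overlap + composition ---------------------------------------------
    with _stage("similarity"):
        outputs = {}
        if len(experiment) >= 2:
            for method in config.methods:
                mat = similarity.pairwise_matrix(experiment, method=method)
                name = f"similarity_{method}.tsv"
                mat.to_tsv(out / name)
                outputs[name] = len(mat.sample_names)
        manifest.add("similarity", outputs, methods=list(config.methods))

    with _stage("composition"):
        outputs = {}
        for rep in experiment:
            dist = composition.length_distribution(rep, unit="aa")
            name = f"lengths_{rep.sample_name}.tsv"
            outputs[name] = _write(dist.to_frame(), out / name)
            modal = max(dist.histogram, key=lambda l: (dist.histogram[l], -l))
            mat = composition.positional_aa_matrix(rep, modal)
            name = f"aa_matrix_{rep.sample_name}_L{modal}.tsv"
            frame = mat.frame.copy()
            frame.insert(0, "aa", frame.index)
            outputs[name] = _write(frame, out / name)
        manifest.add("composition", outputs)

    # clustering + embedding --------------------------------------------
    master = experiment.master_table
    pooled = master.groupby("aa_seq")["read_count"].sum()
    top_seqs = cluster_embed.select_top_sequences(
        list(pooled.index), list(pooled), config.top_n)

    with _stage("ld_cluster"):
        outputs = {}
        if len(top_seqs) >= 2:
            mat = cluster_embed.ld_matrix(top_seqs, top_n=None)
            link = cluster_embed.dendrogram(mat, method=config.linkage)
            newick = cluster_embed.to_newick(link, mat.sequences)
            (out / "dendrogram.nwk").write_text(newick + "\n")
            outputs["dendrogram.nwk"] = len(mat.sequences)
            graph = cluster_embed.ld_graph(
                top_seqs, cutoff=config.ld_cutoff,
                counts=[int(pooled[s]) for s in top_seqs])
            nodes = pd.DataFrame(
                [{"aa_seq": s, "count": d["count"], "component": d["component"]}
                 for s, d in sorted(graph.nodes(data=True))])
            edges = pd.DataFrame(
                [{"seq_a": min(a, b), "seq_b": max(a, b), "ld": d["ld"]}
                 for a, b, d in graph.edges(data=True)])
            if len(edges):
                edges = edges.sort_values(["seq_a", "seq_b"], ignore_index=True)
            outputs["graph_nodes.tsv"] = _write(nodes, out / "graph_nodes.tsv")
            outputs["graph_edges.tsv"] = _write(edges, out / "graph_edges.tsv")
        manifest.add("ld_cluster", outputs, cutoff=config.ld_cutoff,
                     top_n=config.top_n, linkage=config.linkage)

    with _stage("embedding"):
        outputs = {}
        points = None
        if len(top_seqs) >= 4:
            vectors = cluster_embed.sgt_embed(top_seqs, kappa=config.kappa)
            coords = cluster_embed.reduce_to_2d(
                vectors, pca_dims=config.pca_dims,
                perplexity=config.perplexity, seed=config.seed)
            points = pd.DataFrame({
                "aa_seq": top_seqs,
                "count": [int(pooled[s]) for s in top_seqs],
                "x": coords[:, 0].astype(float),
                "y": coords[:, 1].astype(float),
            })
            outputs["embedding.tsv"] = _write(points, out / "embedding.tsv")
        manifest.add("embedding", outputs, kappa=config.kappa,
                     pca_dims=config.pca_dims, perplexity=config.perplexity,
                     seed=config.seed)

    # binding integration -----------------------------------------------
    with _stage("binding"):
        outputs = {}
        if config.binding_csv:
            binding = io.read_binding_table(config.binding_csv)
            antigen = config.antigen or binding.antigens[0]
            if points is not None:
                annotated, unmatched = cluster_embed.overlay_binding(
                    points, binding, antigen)
                outputs["embedding_binding.tsv"] = _write(
                    annotated, out / "embedding_binding.tsv")
                if unmatched:
                    log.info("%d labeled sequences absent from embedding",
                             len(unmatched))
            candidates = cluster_embed.nearest_labeled_neighbors(
                top_seqs, binding, antigen, ld_cutoff=config.ld_cutoff,
                min_binding=config.min_binding)
            outputs["candidates.tsv"] = _write(candidates, out / "candidates.tsv")
            manifest.add("binding", outputs, antigen=antigen,
                         min_binding=config.min_binding,
                         ld_cutoff=config.ld_cutoff)
        else:
            manifest.data["stages"].append(
                {"stage": "binding", "outputs": {}, "params": {},
                 "binding": "absent"})

    manifest.data["load_reports"] = [
        {"path": r.path, "total_rows": r.total_rows, "kept_rows": r.kept_rows,
         "dropped_empty_seq": r.dropped_empty_seq,
         "assumed_unit_counts": r.assumed_unit_counts} for r in reports]
    manifest.write(out / "manifest.json")
    return out
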