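"""End-to-end orchestration: filter -> paired DE -> per-group networks ->
overlap -> Frobenius distances -> clustering -> optional enrichment.

The stages are the library functions of the sibling modules; this module only
wires them together, keeps a stage-by-stage size log, and (for the CLI)
serializes every intermediate to the output directory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as dio
from .coexpression import build_network, individual_correlations, individual_distance_profile
from .datatypes import CoexpressionNetwork, DEParams, ExpressionMatrix, NetworkParams
from .diffexpr import ContrastResult, de_gene_union, paired_contrast
from .network_analysis import ClusterAssignment, community_cluster, degree_report, ora, overlap_network
from .preprocess import filter_background, y_background_threshold

DEFAULT_CONTRASTS = ((2, 1), (3, 1))


@dataclass
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    threshold: float
    filtered: ExpressionMatrix
    contrasts: dict[str, dict[tuple[int, int], ContrastResult]]
    de_genes: dict[str, set[str]]
    networks: dict[str, CoexpressionNetwork]
    overlap: CoexpressionNetwork
    distances: dict[str, pd.Series]
    clusters: ClusterAssignment
    enrichment: pd.DataFrame | None = None
    log: list[str] = field(default_factory=list)


def run_pipeline(
    expr: ExpressionMatrix,
    chrom: dict[str, str],
    contrasts=DEFAULT_CONTRASTS,
    de_params: DEParams | None = None,
    net_params: NetworkParams | None = None,
    min_cluster_size: int = 3,
    cluster_seed: int = 0,
    threshold_method: str = "pooled",
    gene_sets=None,
    enrich_kwargs: dict | None = None,
) -> PipelineResult:
    """Run the full workflow on one two-group (or multi-group) study.

    ``contrasts`` are (tp_b, tp_a) pairs tested within every group;
    enrichment runs per overlap-network cluster when ``gene_sets`` is given,
    with the background-filtered gene list as the universe.
    """
    de_params = de_params or DEParams()
    net_params = net_params or NetworkParams()
    log: list[str] = []

    threshold = y_background_threshold(expr, chrom, method=threshold_method)
    filtered = filter_background(expr, threshold)
    log.append(
        f"background filter: threshold {threshold:.4f}, kept {filtered.n_genes}"
        f"/{expr.n_genes} genes"
    )

    groups = filtered.groups()
    contrast_results: dict[str, dict[tuple[int, int], ContrastResult]] = {}
    de_genes: dict[str, set[str]] = {}
    for grp in groups:
        contrast_results[grp] = {}
        for tp_b, tp_a in contrasts:
            res = paired_contrast(filtered, grp, tp_a, tp_b, de_params)
            contrast_results[grp][(tp_b, tp_a)] = res
            log.append(
                f"DE {grp} {tp_b}-{tp_a}: {int(res.table['significant'].sum())} significant "
                f"of {len(res.table)} genes (pi0 {res.pi0:.3f})"
            )
        de_genes[grp] = de_gene_union(contrast_results[grp].values(), de_params)
        log.append(f"DE union {grp}: {len(de_genes[grp])} genes")

    networks: dict[str, CoexpressionNetwork] = {}
    distances: dict[str, pd.Series] = {}
    for grp in groups:
        genes = sorted(de_genes[grp])
        if len(genes) < 2:
            networks[grp] = CoexpressionNetwork(None, provenance=grp)
            distances[grp] = pd.Series(dtype=float, name="frobenius_distance")
            log.append(f"network {grp}: fewer than 2 DE genes, empty network")
            continue
        stack = individual_correlations(filtered, genes, grp)
        networks[grp] = build_network(stack, net_params, provenance=grp)
        distances[grp] = individual_distance_profile(stack)
        log.append(
            f"network {grp}: {networks[grp].n_nodes} nodes, {networks[grp].n_edges} edges "
            f"({networks[grp].n_negative_edges} negative)"
        )

    if len(groups) >= 2:
        overlap = networks[groups[0]]
        for grp in groups[1:]:
            overlap = overlap_network(overlap, networks[grp])
    else:
        overlap = networks[groups[0]]
    log.append(
        f"overlap: {overlap.n_nodes} genes, {overlap.n_edges} edges "
        f"({overlap.n_negative_edges} negative)"
    )

    clusters = community_cluster(overlap, min_cluster_size=min_cluster_size, seed=cluster_seed)
    log.append(
        f"clusters: sizes {sorted(clusters.sizes().values(), reverse=True)}, "
        f"{len(clusters.unclustered)} unclustered genes"
    )

    enrichment = None
    if gene_sets is not None and len(gene_sets) and clusters.cluster_ids:
        enrich_kwargs = enrich_kwargs or {}
        universe = set(filtered.gene_ids)
        frames = []
        for cid in clusters.cluster_ids:
            res = ora(set(clusters.cluster(cid)), universe, gene_sets, **enrich_kwargs)
            if len(res):
                res.insert(0, "cluster", cid)
                frames.append(res)
        enrichment = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["cluster", "set_name", "description", "overlap_count",
                                       "set_size_in_universe", "p_value", "adjusted_p",
                                       "overlap_genes"])
        )
        log.append(f"enrichment: {len(enrichment)} reported rows over "
                   f"{len(clusters.cluster_ids)} clusters")

    return PipelineResult(
        threshold=threshold, filtered=filtered, contrasts=contrast_results,
        de_genes=de_genes, networks=networks, overlap=overlap,
        distances=distances, clusters=clusters, enrichment=enrichment, log=log,
    )


def write_pipeline_outputs(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dio.write_expression(result.filtered, out / "filtered_expression.tsv", out / "filtered_samples.tsv")
    for grp, by_contrast in result.contrasts.items():
        for (tp_b, tp_a), res in by_contrast.items():
            res.to_tsv(out / f"de_{grp}_{tp_b}{tp_a}.tsv")
        dio.write_gene_list(sorted(result.de_genes[grp]), out / f"de_union_{grp}.txt")
        dio.write_network(result.networks[grp], out / f"network_{grp}.tsv")
        result.distances[grp].rename_axis("individual").to_csv(
            out / f"distances_{grp}.tsv", sep="\t", float_format="%.10g"
        )
    dio.write_network(result.overlap, out / "overlap_network.tsv")
    result.clusters.to_tsv(out / "clusters.tsv")
    deg = degree_report(result.overlap)
    deg.rename_axis("gene").to_csv(out / "overlap_degrees.tsv", sep="\t")
    if result.enrichment is not None:
        result.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                                 float_format="%.6g")
    (out / "pipeline.log").write_text("\n".join(result.log) + "\n")
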