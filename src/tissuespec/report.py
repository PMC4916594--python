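"""Sample-level summaries and end-to-end pipeline orchestration.

PCA runs on transcript-centered log2(FPKM + pseudocount) values; sample
hierarchical clustering uses 1 - Pearson distance with average linkage.
``run_pipeline`` chains filter -> classify -> specificity -> network ->
enrichment -> report and writes a manifest (parameters, seeds, output
checksums) sufficient for an exact rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from . import __version__
from . import io as tio
from .biotypes import classify, default_rules, read_rules_tsv, tabulate_classes
from .enrich import hypergeometric_enrich, read_gmt
from .network import (
    NetworkParams,
    adjacency,
    detect_modules,
    extract_hubs,
    module_class_composition,
    topological_overlap,
    write_visant_edges,
)
from .preprocess import (
    TransformParams,
    aggregate_replicates,
    count_expressed,
    filter_low_expression,
    log_transform,
    replicate_concordance,
)
from .specificity import SpecificityParams, call_specific, count_specific, zscore_matrix

logger = logging.getLogger(__name__)

__all__ = ["pca_samples", "cluster_samples", "PipelineConfig", "run_pipeline"]


def pca_samples(expr_log: pd.DataFrame, n_components: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of samples from a log-scale matrix
    (transcripts x samples).

    Transcripts are centered (not z-scored); components are those of the
    sample covariance. The sign of each component is fixed by making its
    largest-magnitude transcript loading positive, so coordinates are
    fully deterministic. Returns (coordinates: samples x PCs,
    fraction of variance explained per PC, non-increasing).
    """
    if expr_log.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = expr_log.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    if not centered.any():
        raise ValueError("constant matrix: PCA undefined")
    # SVD of (samples x transcripts): rows are observations
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    k = min(n_components, len(s))
    # sign convention: largest-|loading| transcript positive per component
    for j in range(k):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    coords = u[:, :k] * s[:k]
    var = s**2
    explained = (var / var.sum())[:k]
    columns = [f"PC{j + 1}" for j in range(k)]
    return (
        pd.DataFrame(coords, index=expr_log.columns, columns=columns),
        explained,
    )


def cluster_samples(
    expr_log: pd.DataFrame,
    *,
    linkage_method: str = "average",
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage dendrogram of samples under 1 - Pearson distance.

    Samples are ordered lexicographically before clustering so ties in
    the merge sequence resolve deterministically. Returns (scipy linkage
    matrix, leaf labels in the clustered order).
    """
    if expr_log.shape[1] < 3:
        raise ValueError("sample clustering needs at least 3 samples")
    ordered = sorted(expr_log.columns.astype(str))
    x = expr_log[ordered].to_numpy(dtype=float).T
    cor = np.corrcoef(x)
    d = np.clip(1.0 - cor, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    link = linkage(squareform((d + d.T) / 2, checks=False), method=linkage_method)
    return link, ordered


@dataclass
class PipelineConfig:
    """Inputs, parameters and output location of an end-to-end run."""

    matrix_path: Path
    samples_path: Path
    annotation_path: Path
    out_dir: Path
    gmt_path: Path | None = None
    annotation_format: str = "tsv"
    rules_path: Path | None = None
    transform: TransformParams = field(default_factory=TransformParams)
    specificity: SpecificityParams = field(default_factory=SpecificityParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    run_enrichment: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("matrix_path", "samples_path", "annotation_path"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        self.out_dir = Path(self.out_dir)
        if self.run_enrichment and self.gmt_path is None:
            raise ValueError(
                "enrichment requested but no GMT gene-set file configured "
                "(set gmt_path or run_enrichment=False)"
            )
        if self.gmt_path is not None:
            self.gmt_path = Path(self.gmt_path)
            if not self.gmt_path.exists():
                raise FileNotFoundError(f"gmt_path: {self.gmt_path} does not exist")
        inputs = {self.matrix_path, self.samples_path, self.annotation_path}
        if self.out_dir.resolve() in {p.resolve().parent for p in inputs}:
            logger.warning("out_dir contains input files; outputs use distinct names")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _provenance(stage: str, params: object) -> str:
    return f"{stage} parameters: {params}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run manifest.

    Stages (in order): bind inputs, replicate concordance and expressed
    counts, replicate aggregation, low-expression filter, biotype
    classification, specificity calling, z-score heatmap matrix, weighted
    co-expression network with module/hub detection on the called
    transcripts, per-tissue TSCT enrichment (when a GMT is configured),
    PCA and sample clustering. Failures abort with the stage name.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "transform": vars(config.transform).copy(),
            "specificity": vars(config.specificity).copy(),
            "network": vars(config.network).copy(),
        },
        "inputs": {
            "matrix": str(config.matrix_path),
            "samples": str(config.samples_path),
            "annotation": str(config.annotation_path),
            "gmt": str(config.gmt_path) if config.gmt_path else None,
        },
        "stages": [],
        "outputs": {},
    }

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "load"
    try:
        expr = tio.read_expression_tsv(config.matrix_path)
        samples = tio.read_sample_table(config.samples_path)
        annot_raw = tio.read_annotation(config.annotation_path, format=config.annotation_format)
        rules = read_rules_tsv(config.rules_path) if config.rules_path else default_rules()
        annot = classify(annot_raw, rules)
        ds = tio.bind(expr, samples, annot)
        manifest["stages"].append({"stage": stage, "log": ds.log})

        stage = "qc"
        concordance = replicate_concordance(ds.expr, ds.samples, ds.annotation)
        concordance.to_csv(out / "replicate_concordance.tsv", sep="\t")
        emit("replicate_concordance", out / "replicate_concordance.tsv")
        expressed = count_expressed(ds.expr, config.transform, ds.annotation)
        expressed.to_csv(out / "expressed_counts.tsv", sep="\t")
        emit("expressed_counts", out / "expressed_counts.tsv")

        stage = "filter"
        tm = aggregate_replicates(ds.expr, ds.samples, config.transform)
        tm_filtered, removed = filter_low_expression(tm, config.transform)
        tio.write_expression_tsv(
            tm_filtered, out / "tissue_matrix_filtered.tsv",
            header_comment=_provenance("filter", config.transform),
        )
        emit("tissue_matrix", out / "tissue_matrix_filtered.tsv")
        pd.Series(removed, name="transcript_id").to_csv(
            out / "removed_low_expression.tsv", sep="\t", index=False
        )
        emit("removed_ids", out / "removed_low_expression.tsv")
        manifest["stages"].append(
            {"stage": stage, "retained": int(tm_filtered.shape[0]), "removed": int(len(removed))}
        )

        stage = "classify"
        split, noncoding = tabulate_classes(ds.annotation, restrict_to=tm_filtered.index)
        split.to_csv(out / "class_split.tsv", sep="\t")
        noncoding.to_csv(out / "noncoding_classes.tsv", sep="\t")
        emit("class_split", out / "class_split.tsv")
        emit("noncoding_classes", out / "noncoding_classes.tsv")

        stage = "specificity"
        calls = call_specific(tm_filtered, config.specificity, ds.annotation)
        called = calls[calls["specific_tissue"].notna()]
        calls_out = called.rename_axis("transcript_id")
        calls_out.to_csv(out / "specificity_calls.tsv", sep="\t")
        emit("specificity_calls", out / "specificity_calls.tsv")
        counts = count_specific(calls)
        counts.to_csv(out / "specificity_counts.tsv", sep="\t")
        emit("specificity_counts", out / "specificity_counts.tsv")
        tm_log = log_transform(tm_filtered, config.transform)
        if not called.empty:
            z, blocks = zscore_matrix(tm_log, calls)
            tio.write_expression_tsv(z, out / "heatmap_zscores.tsv")
            blocks.rename("block_tissue").rename_axis("transcript_id").to_csv(
                out / "heatmap_row_blocks.tsv", sep="\t"
            )
            emit("heatmap_zscores", out / "heatmap_zscores.tsv")
            emit("heatmap_row_blocks", out / "heatmap_row_blocks.tsv")
        manifest["stages"].append({"stage": stage, "n_called": int(len(called))})

        stage = "network"
        expr_log = log_transform(ds.expr, config.transform)
        net_input = expr_log.loc[expr_log.index.intersection(called.index)]
        net_input = net_input[net_input.std(axis=1) > 0]
        n_modules = 0
        if net_input.shape[0] >= 3:
            adj = adjacency(net_input, config.network)
            tom, dissim = topological_overlap(adj)
            modules, _ = detect_modules(dissim, config.network)
            modules.rename_axis("transcript_id").to_csv(out / "modules.tsv", sep="\t")
            emit("modules", out / "modules.tsv")
            n_modules = int((modules["module"].unique() != 0).sum())
            if n_modules:
                hubs, edges = extract_hubs(adj, modules, config.network, weights=tom)
                hubs.to_csv(out / "hubs.tsv", sep="\t")
                write_visant_edges(edges, out / "hub_edges_visant.txt")
                emit("hubs", out / "hubs.tsv")
                emit("hub_edges", out / "hub_edges_visant.txt")
                composition = module_class_composition(modules, calls)
                composition.to_csv(out / "module_composition.tsv", sep="\t")
                emit("module_composition", out / "module_composition.tsv")
        manifest["stages"].append({"stage": stage, "n_modules": n_modules})

        stage = "enrichment"
        if config.run_enrichment and config.gmt_path is not None:
            sets = read_gmt(config.gmt_path)
            universe = set(tm_filtered.index)
            results = []
            for tissue, grp in called.groupby("specific_tissue", observed=True):
                tscts = set(grp.index[grp["cls"] == "TSCT"]) or set(grp.index)
                res = hypergeometric_enrich(tscts, sets, universe)
                res.insert(0, "tissue", tissue)
                results.append(res)
            if results:
                enr = pd.concat(results, ignore_index=True)
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                emit("enrichment", out / "enrichment.tsv")

        stage = "report"
        coords, explained = pca_samples(expr_log)
        coords.assign().to_csv(out / "pca_coordinates.tsv", sep="\t")
        pd.Series(explained, index=coords.columns, name="variance_fraction").to_csv(
            out / "pca_variance.tsv", sep="\t"
        )
        emit("pca_coordinates", out / "pca_coordinates.tsv")
        emit("pca_variance", out / "pca_variance.tsv")
        link, labels = cluster_samples(expr_log)
        np.savetxt(out / "sample_linkage.tsv", link, delimiter="\t")
        (out / "sample_linkage_labels.txt").write_text("\n".join(labels) + "\n")
        emit("sample_linkage", out / "sample_linkage.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
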