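"""End-to-end orchestration: data -> filter -> PCA -> loadings -> clustering.

Runs the full concordance analysis on either a synthetic experiment or
TSV inputs: expression filtering, log1p transform, PCA, per-PC ANOVA on
the focus contrast, PC selection (max ANOVA F by default, or a fixed
index), empirical-null loading significance on the selected PC,
weighted-correlation concordance over the significant transcripts,
hierarchical clustering with dendsort ordering, optional k-cut and
optional enrichment of the selected transcripts. Every table is written
as TSV with a provenance header (version, config hash, seed), so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from txconcord import __version__ as _version
from txconcord.clusterviz import (
    cut_clusters,
    dendsort_order,
    hierarchical_cluster,
    ordered_matrix,
)
from txconcord.enrich import enrichment_table, hypergeometric_enrichment, read_gmt
from txconcord.exprio import (
    ExpressionMatrix,
    filter_by_expression,
    log1p_tpm,
    read_expression,
)
from txconcord.infoconcord import concordance_matrix
from txconcord.pcload import (
    association_table,
    loading_significance,
    pc_group_association,
    pca_decompose,
    select_significant,
    significance_table,
)
from txconcord.syndata import SyntheticConfig, generate_experiment, write_truth

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("txconcord")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run; exactly one input source.

    Either ``synthetic`` (a SyntheticConfig) or the three TSV paths
    (``tpm_path``, ``counts_path``, ``metadata_path``) must be given.
    ``pc_selection`` is "max_anova_F" or "fixed:<k>" (1-based).
    """

    output_dir: str | Path = "txconcord_out"
    synthetic: SyntheticConfig | None = None
    tpm_path: str | Path | None = None
    counts_path: str | Path | None = None
    metadata_path: str | Path | None = None
    cpm_threshold: float = 10.0
    alpha_loadings: float = 0.05
    pc_selection: str = "max_anova_F"
    exclude_self: bool = True
    weight_combiner: str = "product"
    linkage: str = "complete"
    k_clusters: int | None = None
    gmt_path: str | Path | None = None
    enrich_fdr: float = 0.05
    enrich_min_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        from_files = self.tpm_path is not None
        if self.synthetic is None and not from_files:
            raise ValueError(
                "config needs exactly one input source: a synthetic block "
                "or input paths"
            )
        if self.synthetic is not None and from_files:
            raise ValueError("config must name exactly one input source")
        if from_files and self.metadata_path is None:
            raise ValueError("file input requires metadata_path")
        if not 0 <= self.alpha_loadings <= 1:
            raise ValueError("alpha_loadings must lie in [0, 1]")
        if self.cpm_threshold < 0:
            raise ValueError("cpm_threshold must be >= 0")
        if self.pc_selection != "max_anova_F":
            if not self.pc_selection.startswith("fixed:"):
                raise ValueError("pc_selection must be 'max_anova_F' or 'fixed:<k>'")
            int(self.pc_selection.split(":", 1)[1])

    def config_hash(self) -> str:
        # hash of the analysis parameters; the destination directory is
        # excluded so reruns into different places stay byte-identical
        d = asdict(self)
        d.pop("output_dir")
        for key in ("tpm_path", "counts_path", "metadata_path", "gmt_path"):
            d[key] = None if d[key] is None else str(d[key])
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, *, index=True,
               index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# txconcord {_version} config={cfg.config_hash()} "
                 f"seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


@dataclass
class PipelineResult:
    """In-memory results of a run plus the manifest of written files."""

    matrix: ExpressionMatrix
    filtered: ExpressionMatrix
    selected_pc: int
    associations: pd.DataFrame
    significance: pd.DataFrame
    selected_transcripts: set[str]
    concordance: object
    dendrogram: object
    clusters: dict[str, int] | None
    enrichment: pd.DataFrame | None
    manifest: dict[str, str] = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute all stages in order; returns results and the file manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame, **kw) -> None:
        path = out / name
        _write_tsv(df, path, cfg, **kw)
        manifest[name] = str(path)

    # --- input stage
    truth = None
    if cfg.synthetic is not None:
        log.info("generating synthetic experiment (seed=%d)", cfg.synthetic.seed)
        matrix, truth = generate_experiment(cfg.synthetic)
        emit("counts.tsv", matrix.counts, index_label="gene_id")
        emit("tpm.tsv", matrix.tpm, index_label="gene_id")
        emit("metadata.tsv", matrix.metadata, index_label="sample_id")
        truth_path = out / "truth.tsv"
        write_truth(truth, truth_path)
        manifest["truth.tsv"] = str(truth_path)
    else:
        try:
            matrix = read_expression(
                cfg.tpm_path, cfg.metadata_path, kind="tpm",
                counts_path=cfg.counts_path,
            )
        except Exception as err:
            raise RuntimeError(f"stage 'ingest' failed on {cfg.tpm_path}: {err}") from err

    # --- expression filter (needs counts; TPM-only inputs skip it)
    if matrix.counts is not None:
        filtered = filter_by_expression(matrix, cfg.cpm_threshold)
    else:
        filtered = matrix
    log.info("filter kept %d/%d genes", len(filtered.gene_ids), len(matrix.gene_ids))

    # --- PCA + ANOVA on the focus contrast
    logtpm = log1p_tpm(filtered)
    pca = pca_decompose(logtpm)
    emit("pca_scores.tsv", pca.scores, index_label="sample_id")
    emit("pca_loadings.tsv", pca.loadings, index_label="transcript_id")
    assocs = pc_group_association(pca.scores, filtered.metadata["is_focus"])
    assoc_df = association_table(assocs)
    emit("pc_anova.tsv", assoc_df, index=False)

    if cfg.pc_selection == "max_anova_F":
        selected_pc = int(assoc_df.loc[assoc_df["F"].idxmax(), "pc"])
    else:
        selected_pc = int(cfg.pc_selection.split(":", 1)[1])
        if not 1 <= selected_pc <= pca.n_components:
            raise RuntimeError(
                f"stage 'pc-selection' failed: fixed PC {selected_pc} out of "
                f"range 1..{pca.n_components}"
            )
    log.info("selected PC%d", selected_pc)

    # --- loading significance on the selected PC
    sig = loading_significance(pca.loadings, selected_pc,
                               exclude_self=cfg.exclude_self)
    sig_df = significance_table(sig)
    emit("loading_significance.tsv", sig_df, index=False)
    selected = select_significant(sig, cfg.alpha_loadings)
    if not selected:
        raise RuntimeError(
            f"stage 'loading-significance' failed: no transcript passed "
            f"alpha={cfg.alpha_loadings} on PC{selected_pc}"
        )
    keep = [g for g in filtered.gene_ids if g in selected]

    # --- weighted-correlation concordance over the significant transcripts
    conc = concordance_matrix(
        logtpm.loc[keep], filtered.tpm.loc[keep], combiner=cfg.weight_combiner
    )
    for name, mat in (
        ("pearson", conc.pearson_r),
        ("jaccard", conc.jaccard),
        ("completeness", conc.completeness),
        ("weight", conc.weight),
        ("weighted_r", conc.weighted_r),
        ("distance", conc.pseudo_distance),
    ):
        emit(f"concord_{name}.tsv", mat, index_label="sample_id")

    # --- clustering + dendsort ordering
    dend = dendsort_order(hierarchical_cluster(conc.pseudo_distance, cfg.linkage))
    merge_df = pd.DataFrame(dend.merges, columns=["left", "right", "height"])
    emit("cluster_merges.tsv", merge_df, index=False)
    (out / "leaf_order.txt").write_text("\n".join(dend.leaf_order) + "\n")
    manifest["leaf_order.txt"] = str(out / "leaf_order.txt")
    (out / "tree.nwk").write_text(dend.to_newick() + "\n")
    manifest["tree.nwk"] = str(out / "tree.nwk")
    emit("distance_ordered.tsv", ordered_matrix(conc, dend),
         index_label="sample_id")
    emit("weighted_r_ordered.tsv", ordered_matrix(conc.weighted_r, dend),
         index_label="sample_id")

    clusters = None
    if cfg.k_clusters is not None:
        clusters = cut_clusters(dend, cfg.k_clusters)
        cl_df = pd.DataFrame(
            {"sample_id": list(clusters), "cluster": list(clusters.values())}
        )
        emit("clusters.tsv", cl_df, index=False)

    # --- optional enrichment of the selected transcripts
    enr_df = None
    if cfg.gmt_path is not None:
        annotations = read_gmt(cfg.gmt_path)
        universe = set(filtered.gene_ids)
        results = hypergeometric_enrichment(
            set(keep), universe, annotations,
            fdr_cut=cfg.enrich_fdr, min_count=cfg.enrich_min_count,
        )
        enr_df = enrichment_table(results)
        emit("enrichment.tsv", enr_df, index=False)

    manifest_df = pd.DataFrame(sorted(manifest.items()), columns=["name", "path"])
    manifest_df.to_csv(out / "manifest.tsv", sep="\t", index=False)

    return PipelineResult(
        matrix=matrix,
        filtered=filtered,
        selected_pc=selected_pc,
        associations=assoc_df,
        significance=sig_df,
        selected_transcripts=selected,
        concordance=conc,
        dendrogram=dend,
        clusters=clusters,
        enrichment=enr_df,
        manifest=manifest,
    )


def config_from_toml(path) -> PipelineConfig:
    """Build a PipelineConfig from a TOML file.

    Top-level keys map to PipelineConfig fields; a ``[synthetic]`` table
    maps to SyntheticConfig (its ``groups`` is a list of
    ``[label, n_samples, is_focus]`` triples).
    """
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    syn = None
    if "synthetic" in raw:
        sd = dict(raw.pop("synthetic"))
        if "groups" in sd:
            sd["groups"] = tuple(
                (str(g[0]), int(g[1]), bool(g[2])) for g in sd["groups"]
            )
        if "gene_length_range" in sd:
            sd["gene_length_range"] = tuple(int(v) for v in sd["gene_length_range"])
        syn = SyntheticConfig(**sd)
    return PipelineConfig(synthetic=syn, **raw)
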