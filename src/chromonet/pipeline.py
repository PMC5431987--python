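"""End-to-end driver: simulate/load -> preprocess -> DE -> networks -> topology.

One :class:`PipelineConfig` (JSON/YAML round-trippable) governs every stage;
one seed governs every stochastic step, stream-split per stage. Each stage
writes its artifacts as TSV (JSON for the manifest and report) so any stage
can be re-run from its predecessor's files; a failure aborts with a
stage-tagged error while earlier outputs remain on disk.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, network, preprocess, topology
from .simulate import GroundTruth, SimulationConfig, make_annotation, simulate_counts

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


def configure_logging(level: int = logging.INFO, logfile: str | None = None) -> None:
    """Log to stderr, and to ``logfile`` when given."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        handlers=handlers,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        force=True,
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds, estimator choice and input source of one pipeline run.

    Either the three input paths are set (counts/annotation/samples TSV) or
    the built-in simulation supplies them. Defaults follow the analysis this
    package implements: mean-count and mean-CPM filters at 10, DEGs at
    FDR < 1e-5 with |log2FC| > 1, networks from the top 0.01% of MI values.
    """

    counts_path: str | None = None
    annotation_path: str | None = None
    samples_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_mean: float = 10.0
    min_cpm: float = 10.0
    fdr_max: float = 1e-5
    lfc_min: float = 1.0
    top_fraction: float = 1e-4
    estimator: str = "binning"
    dpi: bool = False
    n_fq_bins: int = 10
    var_explained: float = 0.75
    seed: int = 0
    outdir: str = "chromonet_out"

    def validate(self) -> None:
        if min(self.min_mean, self.min_cpm) < 0 or min(self.fdr_max, self.lfc_min) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        self.simulation.validate()

    # -- serialization (lossless round-trip) -------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["depth_range"] = list(self.simulation.depth_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if "depth_range" in sim:
            sim["depth_range"] = tuple(sim["depth_range"])
        return cls(simulation=SimulationConfig(**sim), **d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class PipelineResult:
    config: PipelineConfig
    annotation: pd.DataFrame
    de: diffexpr.DEResult
    networks: dict
    classifications: dict
    summaries: dict
    truth: GroundTruth | None = None

    @property
    def report(self) -> dict:
        rep = {"conditions": {}}
        for cond in self.summaries:
            rep["conditions"][cond] = {
                "topology": self.summaries[cond].to_dict(),
                "inter_fraction": self.classifications[cond].inter_fraction,
                "mi_cutoff": self.networks[cond].graph["mi_cutoff"],
            }
        rep["n_degs"] = int(self.de.table["is_deg"].sum())
        rep["n_genes_tested"] = len(self.de.table)
        rep["expected_false_degs"] = diffexpr.expected_false_degs(
            len(self.de.table), self.config.fdr_max
        )
        return rep


def _versions() -> dict:
    import networkx
    import scipy

    from . import __version__

    return {
        "chromonet": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
    }


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute every stage in order and return the assembled result.

    Stages: acquire (simulate or load) -> integrate -> mean-count filter ->
    within full-quantile normalization (%GC, then gene length) -> TMM ->
    CPM filter -> log2 -> denoise -> differential expression -> per-condition
    MI network -> chromosomal classification and topology -> report.
    """
    cfg.validate()
    out = Path(cfg.outdir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    stage = "acquire"
    try:
        truth = None
        if cfg.counts_path:
            cm = preprocess.CountMatrix.from_tsv(cfg.counts_path, cfg.samples_path)
            ann_raw = preprocess.load_annotation(cfg.annotation_path)
        else:
            sim = replace(cfg.simulation, seed=cfg.seed)
            ann_raw = make_annotation(sim)
            counts, samples, truth = simulate_counts(sim, ann_raw)
            cm = preprocess.CountMatrix(
                values=counts, conditions=samples.set_index("sample")["condition"]
            )
            if write:
                counts.to_csv(out / "counts_raw.tsv", sep="\t", index_label="gene_id")
                ann_raw.to_csv(out / "annotation_raw.tsv", sep="\t", index=False)
                samples.to_csv(out / "samples.tsv", sep="\t", index=False)
                truth.to_frame().to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        logger.info("acquire: %d genes x %d samples", cm.n_genes, cm.n_samples)

        stage = "integrate"
        cm, ann = preprocess.integrate(ann_raw, cm)

        stage = "filter_mean_count"
        cm = preprocess.filter_mean_count(cm, cfg.min_mean)
        ann = ann[ann["gene_id"].isin(cm.genes)].reset_index(drop=True)
        logger.info("filters: %d genes after mean-count filter", cm.n_genes)

        stage = "within_fq_normalize"
        gc = ann.set_index("gene_id")["gc"]
        length = (ann["end"] - ann["start"] + 1).set_axis(ann["gene_id"])
        cm = preprocess.within_fq_normalize(cm, gc, cfg.n_fq_bins)
        cm = preprocess.within_fq_normalize(cm, length, cfg.n_fq_bins)

        stage = "tmm"
        factors = preprocess.tmm_factors(cm)
        cm = preprocess.tmm_normalize(cm, factors)
        if write:
            factors.to_csv(out / "tmm_factors.tsv", sep="\t", header=True)

        stage = "filter_cpm"
        cm = preprocess.filter_cpm(cm, cfg.min_cpm)
        ann = ann[ann["gene_id"].isin(cm.genes)].reset_index(drop=True)
        logger.info("filters: %d genes after CPM filter", cm.n_genes)

        stage = "log2"
        cm = preprocess.log2_transform(cm)

        # The ANOVA+PCA denoised layer feeds the design-based DE test only.
        # Co-expression networks are inferred on the normalized log2 layer:
        # within-condition covariance IS the signal MI estimation measures,
        # and the residual-structure subtraction would remove it.
        stage = "denoise"
        cm_denoised = preprocess.arsyn_denoise(cm, var_explained=cfg.var_explained)
        if write:
            cm.to_tsv(out / "expression_log2.tsv")
            cm_denoised.to_tsv(out / "expression_denoised.tsv")
            ann.to_csv(out / "annotation_clean.tsv", sep="\t", index=False)

        stage = "diffexpr"
        de = diffexpr.fit_gene_models(cm_denoised, reference="healthy", treatment="cancer")
        de = diffexpr.moderate(de)
        diffexpr.select_degs(de, cfg.fdr_max, cfg.lfc_min)
        if write:
            de.to_tsv(out / "diffexpr.tsv")

        nets, classes, summaries = {}, {}, {}
        for cond in ("healthy", "cancer"):
            stage = f"network_{cond}"
            expr = cm.values[cm.condition_samples(cond)]
            mi = network.estimate_mi(expr, estimator=cfg.estimator, seed=cfg.seed)
            if cfg.dpi:
                mi = network.dpi_prune(mi)
            net = network.threshold_top_fraction(mi, cfg.top_fraction, condition=cond)
            network.annotate_network(net, ann=ann, de=de)
            nets[cond] = net
            if write:
                network.write_edge_list(net, out / f"edges_{cond}.tsv")
                network.write_sif(net, out / f"network_{cond}.sif")

            stage = f"topology_{cond}"
            ec = topology.classify_edges(net, ann)
            classes[cond] = ec
            summaries[cond] = topology.topology_summary(net)
            if write:
                ec.edges.to_csv(out / f"edge_classification_{cond}.tsv", sep="\t", index=False)
                topology.write_topology_summary(summaries[cond], out / f"topology_{cond}.tsv")
                topology.write_degree_table(net, out / f"degrees_{cond}.tsv")
                topology.write_component_profiles(
                    topology.component_profiles(net), out / f"components_{cond}.tsv"
                )
                topology.write_circos_links(ec, ann, out / f"circos_{cond}.links")

        stage = "report"
        result = PipelineResult(
            config=cfg,
            annotation=ann,
            de=de,
            networks=nets,
            classifications=classes,
            summaries=summaries,
            truth=truth,
        )
        if write:
            manifest = {
                "config": cfg.to_dict(),
                "seed": cfg.seed,
                "versions": _versions(),
                "stages": [
                    "acquire", "integrate", "filter_mean_count", "within_fq_normalize",
                    "tmm", "filter_cpm", "log2", "denoise", "diffexpr",
                    "network_healthy", "network_cancer", "topology_healthy",
                    "topology_cancer", "report",
                ],
            }
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
            (out / "report.json").write_text(json.dumps(result.report, indent=2) + "\n")
        return result
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
        raise PipelineError(stage, str(exc)) from exc
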