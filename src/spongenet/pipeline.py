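"""End-to-end orchestration of the sponge-network and isoform analyses.

The library entry points (:func:`infer_network`, :func:`run_isoform_analysis`)
operate on in-memory objects; the file-based wrappers load a dataset
directory in the formats :mod:`spongenet.io` defines and write TSV/JSON/
GraphML outputs plus a manifest echoing the effective configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from . import isoforms as siso
from . import network as snet
from . import seeds as sseed
from . import stats as sstats
from .simulate import SynthParams, simulate_sponge_dataset, write_sponge_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and paths steering the pipeline.

    Defaults are the canonical operating point of the method: top-pair
    selection at the 99th percentile of the correlation distribution,
    sensitivity correlation S > 0.3, seed-match enrichment p < 0.01,
    isoform t-test p < 0.05, 3'UTRs of at least 500 nt and at most 10%
    missing values per entity.
    """

    dataset_dir: str = "."
    output_dir: str = "out"
    condition: str = "normal"
    percentile: float = 99.0
    s_threshold: float = 0.3
    enrichment_alpha: float = 0.01
    ttest_alpha: float = 0.05
    utr_min: int = 500
    missing_max: float = 0.10
    log_transform: bool = False  # correlate log1p(FPKM) instead of raw FPKM
    random_seed: int = 0
    overwrite: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ValueError(f"percentile must be in (0, 100), got {self.percentile}")
        for name in ("enrichment_alpha", "ttest_alpha", "missing_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.utr_min < 0:
            raise ValueError("utr_min must be non-negative")
        if self.condition not in sio.VALID_CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class InferenceResult:
    pairs: list[tuple[str, str, float]]
    sensitivity_matrix: pd.DataFrame
    triplets: list[sstats.SpongeTriplet]
    network: snet.MMINetwork
    stage_counts: dict = field(default_factory=dict)


def infer_network(
    mrna: sio.ExpressionMatrix,
    lncrna: sio.ExpressionMatrix,
    mirna: sio.ExpressionMatrix,
    utr_sequences: Sequence[sio.TranscriptSequence],
    lnc_sequences: Sequence[sio.TranscriptSequence],
    mirna_seeds: Sequence[sseed.MiRNASeed],
    utr_lengths: Mapping[str, int],
    config: PipelineConfig | None = None,
) -> InferenceResult:
    """Run preprocess -> top pairs -> triplet scan -> enrichment -> network.

    Matrices must carry both conditions; the analysis is restricted to
    ``config.condition`` samples.  Halts with :class:`~spongenet.io.
    EmptyResultError` naming the stage when any stage yields nothing.
    """
    cfg = config or PipelineConfig()
    counts: dict[str, int] = {}

    mrna_f = sio.preprocess(mrna, utr_lengths, cfg.missing_max, cfg.utr_min)
    lnc_f = sio.preprocess(lncrna, None, cfg.missing_max)
    mir_f = sio.preprocess(mirna, None, cfg.missing_max)
    mrna_c = mrna_f.subset_condition(cfg.condition)
    lnc_c = lnc_f.subset_condition(cfg.condition)
    mir_c = mir_f.subset_condition(cfg.condition)
    if cfg.log_transform:
        mrna_c, lnc_c, mir_c = (
            sio.ExpressionMatrix(np.log1p(m.values), m.role, m.samples)
            for m in (mrna_c, lnc_c, mir_c)
        )
    counts["mrna_retained"] = len(mrna_c.entity_ids)
    counts["lncrna_retained"] = len(lnc_c.entity_ids)
    counts["mirna_retained"] = len(mir_c.entity_ids)

    pairs = sstats.select_top_pairs(mrna_c, lnc_c, cfg.percentile)
    counts["pairs_selected"] = len(pairs)
    if not pairs:
        raise sio.EmptyResultError("stage top-pair selection produced no pairs")

    matrix, triplets = sstats.triplet_scan(
        pairs, mrna_c, lnc_c, mir_c, cfg.s_threshold
    )
    counts["triplets_passing_s"] = len(triplets)
    if not triplets:
        raise sio.EmptyResultError("stage triplet scan produced no triplets")

    retained_utrs = [t for t in utr_sequences if t.id in set(mrna_f.entity_ids)]
    retained_lncs = [t for t in lnc_sequences if t.id in set(lnc_f.entity_ids)]
    retained_mirs = set(mir_f.entity_ids)
    index = sseed.build_index(
        list(retained_utrs) + list(retained_lncs),
        [s for s in mirna_seeds if s.mirna_id in retained_mirs],
    )
    sstats.add_enrichment(triplets, index)
    counts["triplets_passing_enrichment"] = sum(
        1 for t in triplets if t.enrichment_p < cfg.enrichment_alpha
    )

    net = snet.build_network(
        triplets,
        enrichment_alpha=cfg.enrichment_alpha,
        provenance={
            "condition": cfg.condition,
            "percentile": cfg.percentile,
            "s_threshold": cfg.s_threshold,
        },
    )
    counts["nodes"] = net.n_nodes
    counts["edges"] = net.n_edges
    if net.n_edges == 0:
        raise sio.EmptyResultError("stage network build produced no edges")
    for stage, value in counts.items():
        logger.info("stage %s: %d", stage, value)
    return InferenceResult(pairs, matrix, triplets, net, counts)


# ---------------------------------------------------------------------------
# file-based commands
# ---------------------------------------------------------------------------

def _prepare_outdir(outdir: Path, overwrite: bool) -> None:
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {outdir} is not empty (use overwrite)"
        )
    outdir.mkdir(parents=True, exist_ok=True)


def _write_manifest(outdir: Path, config: PipelineConfig, extra: dict) -> None:
    manifest = {"config": config.to_dict(), **extra}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def load_sponge_dataset_dir(dataset_dir: str | Path):
    """Load the matrices, sequences and miRNAs of a dataset directory."""
    d = Path(dataset_dir)
    samples = sio.read_sample_table(d / "samples.tsv")
    mrna = sio.read_expression(d / "mrna_fpkm.tsv", samples, "mRNA")
    lnc = sio.read_expression(d / "lncrna_fpkm.tsv", samples, "lncRNA")
    mir = sio.read_expression(d / "mirna_fpkm.tsv", samples, "miRNA")
    utrs = sio.read_fasta(d / "mrna_3utr.fa", role="mRNA-3'UTR")
    lncs = sio.read_fasta(d / "lncrna_cdna.fa", role="lncRNA-cDNA")
    seeds = sseed.read_mirnas(d / "mature_mirnas.tsv")
    return mrna, lnc, mir, utrs, lncs, seeds


def cmd_simulate(config: PipelineConfig, params: SynthParams | None = None) -> dict:
    """Write a synthetic sponge dataset plus ground truth and manifest."""
    outdir = Path(config.output_dir)
    _prepare_outdir(outdir, config.overwrite)
    params = params or SynthParams(random_seed=config.random_seed)
    dataset = simulate_sponge_dataset(params)
    manifest = write_sponge_dataset(dataset, outdir)
    manifest["params"] = dataclasses.asdict(params)
    _write_manifest(outdir, config, manifest)
    return manifest


def cmd_infer(config: PipelineConfig) -> InferenceResult:
    """Run the full network inference on a dataset directory and export."""
    outdir = Path(config.output_dir)
    _prepare_outdir(outdir, config.overwrite)
    mrna, lnc, mir, utrs, lncs, seeds = load_sponge_dataset_dir(config.dataset_dir)
    utr_lengths = {t.id: t.length for t in utrs}
    result = infer_network(mrna, lnc, mir, utrs, lncs, seeds, utr_lengths, config)
    result.sensitivity_matrix.to_csv(outdir / "sensitivity_matrix.tsv", sep="\t")
    sstats.triplets_to_frame(result.triplets).to_csv(
        outdir / "triplets.tsv", sep="\t", index=False
    )
    snet.export_network(result.network, outdir / "network_edges.tsv", "edgelist")
    snet.export_network(result.network, outdir / "network.graphml", "graphml")
    snet.write_summary(result.network, outdir / "network_summary.json")
    _write_manifest(outdir, config, {"stage_counts": result.stage_counts})
    return result


def run_isoform_analysis(
    table: siso.IsoformTable,
    mirna: siso.PairedProfile | None,
    config: PipelineConfig | None = None,
    reference_mirna: str = "mirna",
    pca_scope: str = "filtered",
) -> dict:
    """Run t-test filter -> shares -> variation -> PCA -> ratios -> report.

    ``pca_scope`` chooses whether the PCA sees the t-test-filtered isoform
    set (default) or the variations of all isoforms.
    """
    cfg = config or PipelineConfig()
    filtered = siso.filter_isoforms(table, cfg.ttest_alpha)
    if pca_scope not in ("filtered", "all"):
        raise ValueError(f"unknown pca_scope {pca_scope!r}")
    variation = siso.variation_matrix(
        filtered if pca_scope == "filtered" else table
    )
    pca_res = siso.pca(variation)
    report = siso.titration_report(filtered, mirna, reference_mirna)
    return {
        "filtered_table": filtered,
        "variation": variation,
        "pca": pca_res,
        "report": report,
        "n_retained": len(filtered.isoform_ids),
    }


def cmd_isoform(
    config: PipelineConfig,
    normal_path: str | Path,
    cancer_path: str | Path,
    mirna_normal_path: str | Path | None = None,
    mirna_cancer_path: str | Path | None = None,
) -> dict:
    """File-based isoform analysis: reads S1-style per-condition tables."""
    outdir = Path(config.output_dir)
    _prepare_outdir(outdir, config.overwrite)
    table = siso.read_isoform_table(normal_path, cancer_path)
    mirna = None
    reference = "mirna"
    if mirna_normal_path is not None:
        mn = pd.read_csv(mirna_normal_path, sep="\t", index_col=0)
        mc = pd.read_csv(mirna_cancer_path, sep="\t", index_col=0)
        reference = str(mn.index[0])
        mirna = siso.PairedProfile(mn.iloc[0], mc.iloc[0])
    result = run_isoform_analysis(table, mirna, config, reference)
    siso.write_titration_report(
        result["report"], outdir / "titration_report.tsv",
        outdir / "titration_report.json",
    )
    result["pca"].scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    result["pca"].factors.to_csv(outdir / "pca_factors.tsv", sep="\t")
    pd.Series(
        result["pca"].explained_variance_ratio,
        index=result["pca"].scores.columns,
        name="explained_variance_ratio",
    ).to_csv(outdir / "pca_explained.tsv", sep="\t")
    _write_manifest(outdir, config, {"n_retained": result["n_retained"]})
    return result


def cmd_compare(
    config: PipelineConfig, edges_a: str | Path, edges_b: str | Path
) -> dict:
    """Rewiring summary of two exported edge-list networks."""
    outdir = Path(config.output_dir)
    _prepare_outdir(outdir, config.overwrite)
    net_a = snet.read_network(edges_a)
    net_b = snet.read_network(edges_b)
    result = snet.compare_networks(net_a, net_b)
    with open(outdir / "rewiring.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
    _write_manifest(outdir, config, {})
    return result
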