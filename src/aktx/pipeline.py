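"""End-to-end orchestration of the analysis on synthetic or file inputs.

``run_pipeline`` composes the stages in study order — simulate (or load),
normalize, differential expression (paired pre/post; CR vs IR; AE vs no-AE),
DE-count enrichment, heatmap clustering, pathFinder subnetwork extraction,
key-driver analysis and gene-set ORA — and writes every intermediate table
to a run directory together with a JSON summary. Identical configuration
and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import build_heatmap_matrix
from .diffexpr import (
    de_count_enrichment,
    group_de,
    lesion_reduction_from_annotations,
    paired_de,
)
from .enrichment import ora, overlap_pathways
from .io import write_counts_tsv, write_edge_list, write_gmt
from .kda import KDAConfig, key_driver_analysis
from .network import BackgroundNetwork, Edge
from .normalization import normalize
from .pathfinder import PathFinderConfig, extract_subnetwork
from .synthetic import (
    PanelConfig,
    SimulationConfig,
    generate_background_network,
    generate_gene_sets,
    generate_panel,
    simulate_counts,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration of one full run (synthetic inputs)."""

    panel: PanelConfig = field(default_factory=PanelConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha_gene: float = 0.05
    alpha_adj: float = 0.05
    pathfinder_k: int = 2
    kda_k_max: int = 3
    network_nodes: int = 400
    network_directed: int = 900
    network_undirected: int = 300
    n_gene_sets: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_gene", "alpha_adj"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        panel = PanelConfig(**raw.pop("panel", {}))
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(panel=panel, simulation=sim, **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if out[col].map(lambda v: isinstance(v, tuple)).any():
            out[col] = out[col].map(lambda v: ";".join(v) if isinstance(v, tuple) else v)
    out.to_csv(path, sep="\t")


def run_pipeline(config: PipelineConfig, outdir: str | os.PathLike) -> dict:
    """Run every stage and write artifacts under ``outdir``.

    Returns the JSON-serializable summary that is also written to
    ``summary.json``. Stage failures raise :class:`PipelineError` naming the
    stage; artifacts written before the failure are retained.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
    }
    stage = "simulate"
    try:
        panel = generate_panel(dataclasses.replace(config.panel, seed=config.seed))
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        counts, annotations, truth = simulate_counts(panel, sim)
        write_counts_tsv(counts, out / "raw_counts.tsv")
        annot_df = pd.DataFrame([dataclasses.asdict(a) for a in annotations]).set_index(
            "sample_id"
        )
        annot_df.to_csv(out / "annotations.tsv", sep="\t")
        summary["n_samples"] = len(annotations)
        summary["n_measured_genes"] = len(panel.measured_genes)
        logger.info("stage %s: %d samples, %d probes", stage, len(annotations), counts.shape[0])

        stage = "efficacy"
        eff = lesion_reduction_from_annotations(annotations)
        summary["lesion_reduction_t"] = round(eff.statistic, 4)
        summary["lesion_reduction_p"] = float(eff.p_value)

        stage = "normalize"
        norm = normalize(counts, panel, log_transform=True)
        norm.values.to_csv(out / "normalized_log2.tsv", sep="\t")
        summary["n_lod_zeroed"] = len(norm.lod_zeroed)
        logger.info("stage %s: %d genes below detection limit", stage, len(norm.lod_zeroed))

        stage = "de_paired"
        de_pre_post = paired_de(norm, annotations, genes=panel.measured_genes)
        _write_table(de_pre_post, out / "de_pre_post.tsv")
        sig_paired = de_pre_post[de_pre_post["adj_p"] < config.alpha_adj]
        summary["n_de_pre_post_adj"] = int(len(sig_paired))

        stage = "de_response"
        de_resp = group_de(norm, annotations, grouping="response", genes=panel.measured_genes)
        _write_table(de_resp, out / "de_cr_vs_ir.tsv")
        resp_sig = de_resp[de_resp["p_value"] < config.alpha_gene]
        summary["n_de_cr_ir_raw"] = int(len(resp_sig))
        summary["de_count_enrichment_p"] = de_count_enrichment(
            len(resp_sig), len(panel.measured_genes), config.alpha_gene
        )

        stage = "de_adverse_event"
        de_ae = group_de(norm, annotations, grouping="adverse_event", genes=panel.measured_genes)
        _write_table(de_ae, out / "de_ae_vs_no_ae.tsv")
        ae_sig = de_ae[de_ae["p_value"] < config.alpha_gene]
        summary["n_de_ae_raw"] = int(len(ae_sig))

        stage = "cluster"
        heat = build_heatmap_matrix(norm, list(resp_sig.index), annotations)
        heat.matrix.to_csv(out / "heatmap_matrix.tsv", sep="\t")
        orders = pd.DataFrame(
            {"kind": ["gene"] * len(heat.gene_order) + ["sample"] * len(heat.sample_order),
             "id": list(heat.gene_order) + list(heat.sample_order)}
        )
        orders.to_csv(out / "heatmap_orders.tsv", sep="\t", index=False)

        stage = "network"
        network, net_truth = generate_background_network(
            n_nodes=config.network_nodes,
            n_directed=config.network_directed,
            n_undirected=config.network_undirected,
            seed=config.seed,
        )
        # ground the network in panel gene space so DE genes appear in it
        rename = dict(zip(sorted(network.nodes), panel.measured_genes))
        network = BackgroundNetwork(
            [rename[n] for n in network.nodes],
            [
                Edge(e.edge_id, rename[e.source], rename[e.target], e.origin, e.pair_id)
                for e in network.edges
            ],
        )
        write_edge_list(network, out / "background_network.tsv")

        stage = "pathfinder"
        pf_cfg = PathFinderConfig(k=config.pathfinder_k)
        pf_results = {}
        for label, table in (("cr_ir", resp_sig), ("ae", ae_sig)):
            genes = [g for g in table.index if g in network]
            if genes:
                ext = extract_subnetwork(network, genes, pf_cfg)
                pf_results[label] = ext
                pd.Series(sorted(ext.node_set)).to_csv(
                    out / f"pathfinder_{label}_nodes.tsv", sep="\t", index=False, header=["gene_id"]
                )
                summary[f"pathfinder_{label}_nodes"] = len(ext.node_set)
                summary[f"pathfinder_{label}_density"] = round(ext.density, 6)

        stage = "kda"
        kda_targets = [g for g in resp_sig.index if g in network]
        if kda_targets:
            kda_table = key_driver_analysis(
                network, kda_targets, KDAConfig(k_max=config.kda_k_max)
            )
            _write_table(kda_table, out / "key_drivers_cr_ir.tsv")
            summary["n_key_drivers_adj"] = int((kda_table["adj_p"] < config.alpha_adj).sum())

        stage = "enrichment"
        planted = {"RESPONSE_SIGNATURE": sorted(truth.response_effects)}
        sets = generate_gene_sets(
            panel.measured_genes,
            n_sets=config.n_gene_sets,
            planted=planted,
            seed=config.seed,
        )
        write_gmt(sets, out / "gene_sets.gmt")
        universe = panel.measured_genes
        ora_resp = ora([g for g in resp_sig.index], universe, sets)
        _write_table(ora_resp, out / "ora_cr_ir.tsv")
        ora_ae = ora([g for g in ae_sig.index], universe, sets)
        _write_table(ora_ae, out / "ora_ae.tsv")
        shared = overlap_pathways(ora_resp, ora_ae, config.alpha_adj)
        summary["n_pathways_cr_ir"] = int((ora_resp["adj_p"] < config.alpha_adj).sum())
        summary["n_pathways_ae"] = int((ora_ae["adj_p"] < config.alpha_adj).sum())
        summary["shared_pathways"] = sorted(shared)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary
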