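"""End-to-end reconstruction: expression -> prior -> NCA -> network -> motifs.

Every stage logs its funnel counts (genes in/out), every artifact is written
to the output directory, and a JSON manifest records the configuration, the
per-stage seeds (all derived from one master seed) and a content hash of
each file, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .config import PipelineConfig
from .expression import ExpressionMatrix, load_expression
from .motifs import motif_significance
from .nca import NCAModel
from .network import (assemble_dynamic_network, infer_combinatorial_pairs,
                      tfa_expression_agreement, write_graphml, write_sif)
from .prior import build_prior, check_identifiability, reduce_to_identifiable, save_prior

__all__ = ["run_pipeline", "derive_seeds"]

logger = logging.getLogger(__name__)

_STAGE_NAMES = ["prior", "nca", "bootstrap", "motifs"]


def derive_seeds(master_seed: int, names: list[str] | None = None) -> dict[str, int]:
    """Deterministic per-stage seeds from one master seed."""
    names = names if names is not None else _STAGE_NAMES
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    E: ExpressionMatrix | None = None,
    tf_ids: list[str] | None = None,
) -> dict:
    """Execute the full reconstruction and return the run manifest.

    Inputs may be passed in memory (``E``, ``tf_ids``) or read from the paths
    in the config. Stage order: DEG filter -> prior construction (clustering
    + correlation rule) -> identifiability reduction -> NCA fit -> gauge
    normalization -> signed network assembly + strength clustering ->
    TF-pair inference -> motif census. A failure aborts with the stage name;
    artifacts written so far are retained.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)
    manifest: dict = {"config": config.to_dict(), "seeds": seeds,
                      "stages": {}, "files": {}}

    def fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
            encoding="utf-8")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    def record(path: Path):
        manifest["files"][path.name] = _sha256(path)

    # ---- inputs -----------------------------------------------------------
    try:
        if E is None:
            E = load_expression(config.expression_path, config.control_stage)
        if tf_ids is None:
            tf_ids = [
                line.strip() for line in
                Path(config.tf_list_path).read_text(encoding="utf-8").splitlines()
                if line.strip()
            ]
    except Exception as exc:  # noqa: BLE001
        fail("inputs", exc)

    # ---- DEG filter + prior ----------------------------------------------
    try:
        from .expression import filter_degs, save_expression

        degs = filter_degs(E, config.fc_threshold)
        kept_tfs = [t for t in tf_ids if t in set(degs)]
        logger.info("DEG filter: %d/%d genes pass (|FC| > %g); %d/%d TFs",
                    len(degs), E.n_genes, config.fc_threshold,
                    len(kept_tfs), len(tf_ids))
        E_deg = E.subset(degs)
        save_expression(E_deg, outdir / "expression_degs.tsv")
        record(outdir / "expression_degs.tsv")
        prior = build_prior(E_deg, kept_tfs, r_threshold=config.r_threshold,
                            cut_height=config.cut_height)
        save_prior(prior, outdir / "prior_full.tsv")
        record(outdir / "prior_full.tsv")
        reduced, removed = reduce_to_identifiable(prior, E.n_stages,
                                                  seed=seeds["prior"])
        save_prior(reduced, outdir / "prior_identifiable.tsv")
        record(outdir / "prior_identifiable.tsv")
        report = check_identifiability(reduced, E.n_stages, seed=seeds["prior"])
        manifest["stages"]["prior"] = {
            "n_degs": len(degs), "n_tfs_in": len(kept_tfs),
            "prior_edges": prior.n_edges,
            "reduced_tfs": reduced.n_tfs, "reduced_genes": reduced.n_genes,
            "reduced_edges": reduced.n_edges, "removed_tfs": removed,
            "identifiable": report.passed,
        }
        logger.info("prior: %d edges -> identifiable subnetwork of %d TFs, "
                    "%d genes (%d removed)", prior.n_edges, reduced.n_tfs,
                    reduced.n_genes, len(removed))
    except Exception as exc:  # noqa: BLE001
        fail("prior", exc)

    # ---- NCA fit ----------------------------------------------------------
    try:
        model = NCAModel(E_deg, reduced)
        result = model.fit(max_iter=config.max_iter, tol=config.tol,
                           n_restarts=config.n_restarts,
                           seed=seeds["nca"]).normalize("control-zero")
        resid, _ = result.reconstruction_error()
        pd.DataFrame(result.strengths, index=result.gene_ids,
                     columns=result.tf_ids).to_csv(
            outdir / "strengths.tsv", sep="\t", float_format="%.17g")
        record(outdir / "strengths.tsv")
        pd.DataFrame(result.activities, index=result.tf_ids,
                     columns=result.stage_labels).to_csv(
            outdir / "activities.tsv", sep="\t", float_format="%.17g")
        record(outdir / "activities.tsv")
        manifest["stages"]["nca"] = {
            "objective": result.objective, "residual": resid,
            "iterations": result.n_iterations, "converged": result.converged,
        }
        if config.n_boot:
            boot = model.bootstrap(n_boot=config.n_boot,
                                   seed=seeds["bootstrap"], reference=result)
            manifest["stages"]["bootstrap"] = {
                "n_successful": boot.n_successful, "level": boot.level,
            }
    except Exception as exc:  # noqa: BLE001
        fail("nca", exc)

    # ---- network assembly -------------------------------------------------
    try:
        agreement = tfa_expression_agreement(result, E_deg)
        agreement.to_csv(outdir / "tfa_agreement.tsv", sep="\t", index=False)
        record(outdir / "tfa_agreement.tsv")
        pairs = infer_combinatorial_pairs(result.activities, result.tf_ids,
                                          threshold=config.tf_corr_threshold)
        pairs.to_csv(outdir / "tf_pairs.tsv", sep="\t", index=False)
        record(outdir / "tf_pairs.tsv")
        net = assemble_dynamic_network(
            result, E_deg, curated_edges=config.curated_edges_path,
        )
        write_sif(net, outdir / "network.sif")
        record(outdir / "network.sif")
        write_graphml(net, outdir / "network.graphml")
        record(outdir / "network.graphml")
        pd.Series(net.cluster_ids, name="cluster_id").rename_axis("gene_id") \
            .to_csv(outdir / "clusters.tsv", sep="\t")
        record(outdir / "clusters.tsv")
        manifest["stages"]["network"] = {
            "n_nodes": net.graph.number_of_nodes(),
            "n_edges": net.n_edges,
            "n_tf_pairs": int(len(pairs)),
            "n_clusters": len(set(net.cluster_ids.values())),
        }
    except Exception as exc:  # noqa: BLE001
        fail("network", exc)

    # ---- motif census -----------------------------------------------------
    try:
        G = nx.DiGraph()
        for u, v, d in net.graph.edges(data=True):
            G.add_edge(u, v, sign=d.get("sign", 1))
        motif_stats = {}
        for k in config.motif_sizes:
            census = motif_significance(G, k, n_random=config.n_random,
                                        seed=seeds["motifs"] + k)
            census.table.to_csv(outdir / f"motifs_k{k}.tsv", sep="\t",
                                index=False, float_format="%.17g")
            record(outdir / f"motifs_k{k}.tsv")
            motif_stats[str(k)] = {
                "total_subgraphs": census.total_subgraphs,
                "n_classes": census.n_classes,
            }
        manifest["stages"]["motifs"] = motif_stats
    except Exception as exc:  # noqa: BLE001
        fail("motifs", exc)

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return manifest
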