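"""Assembly of the signed, stage-annotated regulatory network from an NCA fit.

Because the decomposition itself cannot orient regulation as activating or
repressing, edge signs come from the sign of the TF-gene expression
correlation: positive coexpression is read as positive regulation, negative
as repression. Target genes are clustered on the rows of the adjusted
strength matrix (their regulator profiles), which separates groups that pure
expression clustering cannot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .expression import ExpressionMatrix
from .nca import NCAResults

__all__ = [
    "RegulatoryNetwork",
    "assign_edge_signs",
    "cluster_by_strength",
    "tfa_expression_agreement",
    "infer_combinatorial_pairs",
    "assemble_dynamic_network",
    "write_sif",
    "write_graphml",
]

logger = logging.getLogger(__name__)


@dataclass
class RegulatoryNetwork:
    """Signed TF -> gene digraph with stage annotations and clusters."""

    graph: nx.DiGraph
    cluster_ids: dict[str, int] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def tfs(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d.get("role") in ("TF", "both"))

    @property
    def targets(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d.get("role") in ("target", "both"))

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"tf": u, "gene": v, "sign": d["sign"], "strength": d.get("strength"),
             "provenance": d.get("provenance", "NCA")}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["tf", "gene", "sign", "strength",
                                           "provenance"])


def assign_edge_signs(result: NCAResults, E: ExpressionMatrix) -> pd.DataFrame:
    """Sign each supported edge by the TF-gene expression correlation.

    Sign = sign(r(TF expression row, gene expression row)); an exact zero
    correlation falls back to the sign of the fitted strength (logged).
    Signs are invariant to positive rescaling of expression rows since
    Pearson r is scale-invariant.
    """
    missing = [t for t in result.tf_ids if t not in set(E.gene_ids)]
    if missing:
        raise ValueError(f"TF expression rows missing: {missing[:5]}")
    support = result.model.prior.support
    rows = []
    for j, tf in enumerate(result.tf_ids):
        x = E.row(tf)
        for i in np.flatnonzero(support[:, j]):
            gene = result.gene_ids[i]
            y = E.row(gene)
            if x.std() == 0 or y.std() == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            if r != 0.0:
                sign = 1 if r > 0 else -1
            else:
                sign = 1 if result.strengths[i, j] >= 0 else -1
                logger.info("zero correlation for edge %s->%s; "
                            "using fitted-strength sign %+d", tf, gene, sign)
            rows.append({"tf": tf, "gene": gene, "sign": sign,
                         "correlation": r,
                         "strength": float(result.strengths[i, j])})
    return pd.DataFrame(rows, columns=["tf", "gene", "sign", "correlation",
                                       "strength"])


def cluster_by_strength(
    strengths: np.ndarray,
    gene_ids: list[str],
    n_clusters: int | None = None,
    cut_height: float | None = None,
) -> dict[str, int]:
    """Hierarchical clustering of genes on their regulator-profile rows.

    Correlation distance, complete linkage; deterministic labels (scipy's
    fcluster numbering). Exactly one of ``n_clusters`` / ``cut_height``
    must be given. Genes with identical strength rows always co-cluster.
    """
    strengths = np.asarray(strengths, dtype=float)
    if (n_clusters is None) == (cut_height is None):
        raise ValueError("give exactly one of n_clusters or cut_height")
    if n_clusters is not None and n_clusters > len(gene_ids):
        raise ValueError(f"n_clusters={n_clusters} > {len(gene_ids)} genes")
    # correlation distance is undefined for constant rows (including the
    # length-1 rows of a single-TF model); treat undefined pairs as maximally
    # distant, except that bit-identical rows are always at distance 0
    with np.errstate(invalid="ignore", divide="ignore"):
        D = squareform(pdist(strengths, metric="correlation"))
    D = np.clip(np.nan_to_num(D, nan=1.0), 0.0, None)
    keys = [row.tobytes() for row in strengths]
    groups: dict[bytes, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    for idx in groups.values():
        if len(idx) > 1:
            D[np.ix_(idx, idx)] = 0.0
    Z = linkage(squareform(D, checks=False), method="complete")
    if n_clusters is not None:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        labels = fcluster(Z, t=cut_height, criterion="distance")
    return {g: int(c) for g, c in zip(gene_ids, labels)}


def tfa_expression_agreement(result: NCAResults, E: ExpressionMatrix) -> pd.DataFrame:
    """Pearson r of each TF's inferred activity vs its own gene expression.

    Classified into strong-positive (r > 0.5), strong-negative (r < -0.5)
    and weak (|r| <= 0.5); a constant trajectory yields an undefined r,
    reported as NaN with class "undefined".
    """
    rows = []
    for j, tf in enumerate(result.tf_ids):
        a = result.activities[j]
        if tf not in set(E.gene_ids):
            raise ValueError(f"TF {tf!r} has no expression row")
        x = E.row(tf)
        if a.std() == 0 or x.std() == 0:
            r, cls = float("nan"), "undefined"
        else:
            r = float(np.corrcoef(a, x)[0, 1])
            cls = ("strong-positive" if r > 0.5
                   else "strong-negative" if r < -0.5 else "weak")
        rows.append({"tf": tf, "r": r, "class": cls})
    return pd.DataFrame(rows, columns=["tf", "r", "class"])


def infer_combinatorial_pairs(
    activities: np.ndarray, tf_ids: list[str], threshold: float = 0.5,
) -> pd.DataFrame:
    """TF pairs whose activity trajectories are strongly correlated.

    All unordered pairs with |Pearson r| > threshold, signed r retained —
    candidate combinatorial regulators (not physical interactions).
    """
    activities = np.asarray(activities, dtype=float)
    L = activities.shape[0]
    if L < 2:
        raise ValueError("need at least 2 TFs")
    rows = []
    for j in range(L):
        for k in range(j + 1, L):
            a, b = activities[j], activities[k]
            if a.std() == 0 or b.std() == 0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            if abs(r) > threshold:
                rows.append({"tf1": tf_ids[j], "tf2": tf_ids[k], "r": r})
    return pd.DataFrame(rows, columns=["tf1", "tf2", "r"])


def assemble_dynamic_network(
    result: NCAResults,
    E: ExpressionMatrix,
    curated_edges: str | Path | pd.DataFrame | None = None,
    expressed_threshold: float | None = None,
    expressed_flags: pd.DataFrame | None = None,
    n_clusters: int | None = None,
    cut_height: float | None = 0.5,
) -> RegulatoryNetwork:
    """Merge signed NCA edges with optional curated edges into one digraph.

    Curated edges (TSV with columns tf, gene, or a DataFrame) are unweighted
    and provenance-tagged; an edge present in both sources gets provenance
    "both". Per-stage "expressed" flags default to |log2 ratio| exceeding
    ``expressed_threshold`` when given (external detection flags may be
    supplied instead); with neither, every observed stage counts as
    expressed. Node roles: a TF that is also someone's target gets "both".
    """
    signed = assign_edge_signs(result, E)
    G = nx.DiGraph()
    for rec in signed.itertuples(index=False):
        G.add_edge(rec.tf, rec.gene, sign=int(rec.sign),
                   strength=float(rec.strength), provenance="NCA")
    if curated_edges is not None:
        if isinstance(curated_edges, pd.DataFrame):
            cur = curated_edges
        else:
            cur = pd.read_csv(curated_edges, sep="\t", dtype=str)
        for rec in cur.itertuples(index=False):
            tf, gene = str(rec.tf), str(rec.gene)
            for node in (tf, gene):
                if node not in G:
                    logger.warning("curated edge names unknown node %r; "
                                   "adding with provenance 'curated'", node)
            if G.has_edge(tf, gene):
                G[tf][gene]["provenance"] = "both"
            else:
                G.add_edge(tf, gene, sign=0, strength=None,
                           provenance="curated")
    # node roles and provenance
    tf_nodes = {u for u, _ in G.edges()}
    target_nodes = {v for _, v in G.edges()}
    fitted = set(result.tf_ids) | set(result.gene_ids)
    for n in G.nodes():
        if n in tf_nodes and n in target_nodes:
            role = "both"
        elif n in tf_nodes:
            role = "TF"
        else:
            role = "target"
        G.nodes[n]["role"] = role
        G.nodes[n]["provenance"] = "NCA" if n in fitted else "curated"
    # per-stage expressed flags
    gene_set = set(E.gene_ids)
    for n in G.nodes():
        if expressed_flags is not None and n in expressed_flags.index:
            flags = [bool(expressed_flags.loc[n, s]) for s in E.stage_labels]
        elif n in gene_set:
            row = E.row(n)
            if expressed_threshold is not None:
                flags = [bool(abs(v) > expressed_threshold) for v in row]
            else:
                flags = [True] * len(E.stage_labels)
        else:
            flags = [False] * len(E.stage_labels)
        for s, f in zip(E.stage_labels, flags):
            G.nodes[n][f"expressed_{s}"] = f
    clusters = cluster_by_strength(
        result.strengths, result.gene_ids,
        n_clusters=n_clusters, cut_height=cut_height,
    )
    for g, c in clusters.items():
        if g in G:
            G.nodes[g]["cluster_id"] = c
    return RegulatoryNetwork(graph=G, cluster_ids=clusters)


def write_sif(net: RegulatoryNetwork, path: str | Path) -> None:
    """Simple interaction format: tf <sign> gene, one edge per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, d in sorted(net.graph.edges(data=True)):
            fh.write(f"{u}\t{d['sign']:+d}\t{v}\n")


def write_graphml(net: RegulatoryNetwork, path: str | Path) -> None:
    """GraphML with node/edge attributes (None strengths dropped)."""
    G = net.graph.copy()
    for _, _, d in G.edges(data=True):
        if d.get("strength") is None:
            del d["strength"]
    nx.write_graphml(G, path)
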