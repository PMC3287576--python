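"""Coexpression-derived prior connectivity and NCA identifiability.

The prior fixes the sparsity pattern Z0 of the control-strength matrix: an
edge (TF j, gene i) is admitted when the two expression trajectories are
strongly correlated (|r| above a threshold) *and* the gene falls in the TF's
sub-tree of a hierarchical clustering of the expression profiles. The signed
correlation coefficient serves as the initial control strength.

Identifiability of the constrained decomposition [E] = [S][A] requires three
topology criteria: (i) the support pattern has full column rank (generically);
(ii) removing any one regulator together with all genes it regulates leaves a
pattern of full column rank L-1; (iii) there are no more regulators than
conditions, so the activity matrix can have full row rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix

__all__ = [
    "ConnectivityPrior",
    "Dendrogram",
    "IdentifiabilityReport",
    "correlation_matrix",
    "cluster_genes",
    "build_prior",
    "check_identifiability",
    "reduce_to_identifiable",
    "load_prior",
    "save_prior",
]


@dataclass
class ConnectivityPrior:
    """Sparse signed TF-to-gene connectivity constraining the decomposition.

    ``support`` is the boolean N x L pattern Z0; ``initial_strengths`` holds
    the starting control strengths (Pearson r of TF vs gene expression when
    built from data), zero exactly off-support.
    """

    tf_ids: list[str]
    gene_ids: list[str]
    support: np.ndarray
    initial_strengths: np.ndarray

    def __post_init__(self) -> None:
        self.tf_ids = list(self.tf_ids)
        self.gene_ids = list(self.gene_ids)
        self.support = np.asarray(self.support, dtype=bool)
        self.initial_strengths = np.asarray(self.initial_strengths, dtype=float)
        N, L = len(self.gene_ids), len(self.tf_ids)
        if self.support.shape != (N, L) or self.initial_strengths.shape != (N, L):
            raise ValueError(
                f"support/strength shape must be ({N}, {L}); got "
                f"{self.support.shape} and {self.initial_strengths.shape}"
            )
        if len(set(self.tf_ids)) != L or len(set(self.gene_ids)) != N:
            raise ValueError("tf_ids and gene_ids must be unique")
        if np.any((self.initial_strengths != 0) != self.support):
            raise ValueError("strengths must be nonzero exactly on the support")
        if N and L:
            if not self.support.any(axis=0).all():
                j = int(np.argmin(self.support.any(axis=0)))
                raise ValueError(f"TF {self.tf_ids[j]!r} regulates no gene")
            if not self.support.any(axis=1).all():
                i = int(np.argmin(self.support.any(axis=1)))
                raise ValueError(f"gene {self.gene_ids[i]!r} has no regulator")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    @property
    def n_edges(self) -> int:
        return int(self.support.sum())

    def edges(self) -> list[tuple[str, str, float]]:
        """(tf_id, gene_id, strength) triples in deterministic order."""
        out = []
        for j, tf in enumerate(self.tf_ids):
            for i in np.flatnonzero(self.support[:, j]):
                out.append((tf, self.gene_ids[i], float(self.initial_strengths[i, j])))
        return out

    def drop_tfs(self, remove: set[str]) -> "ConnectivityPrior":
        """Remove TFs and any genes left without a regulator."""
        keep_j = [j for j, t in enumerate(self.tf_ids) if t not in remove]
        sub = self.support[:, keep_j]
        keep_i = np.flatnonzero(sub.any(axis=1))
        return ConnectivityPrior(
            tf_ids=[self.tf_ids[j] for j in keep_j],
            gene_ids=[self.gene_ids[i] for i in keep_i],
            support=sub[keep_i],
            initial_strengths=self.initial_strengths[np.ix_(keep_i, keep_j)],
        )


@dataclass
class Dendrogram:
    """Agglomerative merge tree over genes on a correlation-distance scale."""

    gene_ids: list[str]
    merges: np.ndarray  # scipy linkage matrix, heights nondecreasing

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be nondecreasing")

    @property
    def leaf_order(self) -> list[str]:
        return [self.gene_ids[i] for i in leaves_list(self.merges)]

    def cut(self, height: float) -> dict[str, int]:
        """Flat clusters from cutting at the given distance."""
        labels = fcluster(self.merges, t=height, criterion="distance")
        return {g: int(c) for g, c in zip(self.gene_ids, labels)}


def correlation_matrix(
    E: ExpressionMatrix, gene_subset: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlation of gene trajectories.

    Constant rows have undefined correlation; those pairs are reported as 0
    (and flagged via ``attrs['constant_genes']``). The diagonal is exactly 1.
    """
    genes = list(gene_subset) if gene_subset is not None else list(E.gene_ids)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for a correlation matrix")
    if E.n_stages < 3:
        raise ValueError("need at least 3 stages for meaningful correlations")
    X = E.subset(genes).values
    sd = X.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R[np.isnan(R)] = 0.0
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    out = pd.DataFrame(R, index=genes, columns=genes)
    out.attrs["constant_genes"] = [g for g, c in zip(genes, constant) if c]
    return out


def cluster_genes(
    E: ExpressionMatrix,
    genes: list[str] | None = None,
    linkage_method: str = "complete",
    distance: str = "abs_correlation",
) -> Dendrogram:
    """Hierarchical clustering of gene trajectories.

    Default distance is ``1 - |r|`` so that the cut height lines up with the
    correlation threshold of the prior rule (cut at 0.1 <-> |r| > 0.9);
    ``distance='correlation'`` gives the signed ``1 - r`` variant. scipy's
    agglomeration is deterministic with ties broken by index order.
    """
    genes = list(genes) if genes is not None else list(E.gene_ids)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to cluster")
    R = correlation_matrix(E, genes).to_numpy()
    if distance == "abs_correlation":
        D = 1.0 - np.abs(R)
    elif distance == "correlation":
        D = 1.0 - R
    else:
        raise ValueError(f"unknown distance {distance!r}")
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)  # symmetrize away round-off
    Z = linkage(squareform(D, checks=False), method=linkage_method)
    Z[:, 2] = np.maximum.accumulate(np.maximum(Z[:, 2], 0.0))
    return Dendrogram(gene_ids=genes, merges=Z)


def build_prior(
    E: ExpressionMatrix,
    tf_ids: list[str],
    r_threshold: float = 0.9,
    cut_height: float = 0.1,
    linkage_method: str = "complete",
) -> ConnectivityPrior:
    """Coexpression prior: |r| > threshold AND co-cluster membership.

    An edge (tf, gene) enters the support iff the Pearson correlation of
    their trajectories exceeds ``r_threshold`` in absolute value and the
    gene co-occurs with the TF in the flat clustering obtained by cutting
    the dendrogram at ``cut_height`` (on the 1 - |r| scale). The signed
    correlation becomes the initial control strength. A TF's trivial
    self-pair is excluded; TFs may still appear as targets of other TFs.
    """
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must be in (0, 1)")
    missing = [t for t in tf_ids if t not in set(E.gene_ids)]
    if missing:
        raise ValueError(f"TFs absent from expression matrix: {missing[:5]}")
    genes = list(E.gene_ids)
    R = correlation_matrix(E, genes)
    clusters = cluster_genes(E, genes, linkage_method=linkage_method).cut(cut_height)
    tf_set = list(dict.fromkeys(tf_ids))
    Rm = R.to_numpy()
    gidx = {g: i for i, g in enumerate(genes)}
    strengths = np.zeros((len(genes), len(tf_set)))
    for j, tf in enumerate(tf_set):
        ti = gidx[tf]
        for i, g in enumerate(genes):
            if g == tf:
                continue
            r = Rm[ti, i]
            if abs(r) > r_threshold and clusters[g] == clusters[tf]:
                strengths[i, j] = r
    support = strengths != 0
    keep_j = np.flatnonzero(support.any(axis=0))
    keep_i = np.flatnonzero(support[:, keep_j].any(axis=1))
    if keep_i.size == 0:
        raise ValueError("empty support: no TF-gene pair passes the prior rule")
    return ConnectivityPrior(
        tf_ids=[tf_set[j] for j in keep_j],
        gene_ids=[genes[i] for i in keep_i],
        support=support[np.ix_(keep_i, keep_j)],
        initial_strengths=strengths[np.ix_(keep_i, keep_j)],
    )


@dataclass
class IdentifiabilityReport:
    """Per-criterion verdict for the three NCA topology conditions."""

    full_column_rank: bool
    reduced_rank_ok: bool
    conditions_ok: bool
    violating_tfs: list[str] = field(default_factory=list)
    detail: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return self.full_column_rank and self.reduced_rank_ok and self.conditions_ok

    def __bool__(self) -> bool:
        return self.passed


def _generic_rank(pattern: np.ndarray, rng: np.random.Generator,
                  n_fillings: int = 3) -> int:
    """Generic (structural) rank of a zero/nonzero pattern.

    Fills the support with random nonzero values several times and takes the
    maximum numerical rank: for a generic filling this equals the structural
    rank with probability one.
    """
    if pattern.size == 0:
        return 0
    best = 0
    for _ in range(n_fillings):
        M = np.zeros(pattern.shape)
        vals = rng.uniform(0.5, 1.5, size=int(pattern.sum()))
        vals *= rng.choice([-1.0, 1.0], size=vals.size)
        M[pattern] = vals
        best = max(best, int(np.linalg.matrix_rank(M)))
    return best


def check_identifiability(
    prior: ConnectivityPrior, n_conditions: int, seed: int = 0,
    n_fillings: int = 3,
) -> IdentifiabilityReport:
    """Test the three NCA identifiability criteria on the support pattern.

    (i) full generic column rank L; (ii) for every TF, deleting its column
    and every gene it regulates leaves generic rank L-1; (iii) the number of
    regulators does not exceed the number of conditions (so the activity
    matrix can have full row rank).
    """
    rng = np.random.default_rng(seed)
    Z = prior.support
    L = prior.n_tfs
    crit1 = _generic_rank(Z, rng, n_fillings) == L
    violators: list[str] = []
    for j, tf in enumerate(prior.tf_ids):
        keep_rows = ~Z[:, j]
        sub = np.delete(Z[keep_rows], j, axis=1)
        if _generic_rank(sub, rng, n_fillings) < L - 1:
            violators.append(tf)
    crit2 = not violators
    crit3 = L <= n_conditions
    return IdentifiabilityReport(
        full_column_rank=crit1,
        reduced_rank_ok=crit2,
        conditions_ok=crit3,
        violating_tfs=violators,
        detail={"n_tfs": L, "n_genes": prior.n_genes,
                "n_conditions": n_conditions},
    )


def reduce_to_identifiable(
    prior: ConnectivityPrior, n_conditions: int, seed: int = 0,
) -> tuple[ConnectivityPrior, list[str]]:
    """Greedy TF pruning until the identifiability criteria hold.

    At each step the TF whose removal most reduces the number of criterion
    violations is dropped (ties: fewest targets, then lexicographic ID), and
    genes orphaned by the removal go with it. Returns the reduced prior and
    the removal log. Raises if nothing identifiable remains.
    """

    def n_violations(p: ConnectivityPrior) -> int:
        rep = check_identifiability(p, n_conditions, seed=seed)
        v = len(rep.violating_tfs)
        if not rep.full_column_rank:
            v += p.n_tfs - _generic_rank(p.support, np.random.default_rng(seed))
        if not rep.conditions_ok:
            v += p.n_tfs - n_conditions
        return v

    current = prior
    removed: list[str] = []
    while current.n_tfs > 0:
        if check_identifiability(current, n_conditions, seed=seed).passed:
            return current, removed
        # score each candidate removal
        best: tuple[int, int, str] | None = None
        for j, tf in enumerate(current.tf_ids):
            try:
                cand = current.drop_tfs({tf})
            except ValueError:
                continue
            if cand.n_tfs == 0:
                continue
            key = (n_violations(cand), int(current.support[:, j].sum()), tf)
            if best is None or key < best:
                best = key
        if best is None:
            break
        current = current.drop_tfs({best[2]})
        removed.append(best[2])
    raise ValueError(
        f"no identifiable subnetwork found (removed {len(removed)} TFs)"
    )


def save_prior(prior: ConnectivityPrior, path: str | Path) -> None:
    """Edge-list TSV: tf_id, gene_id, strength."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tf_id\tgene_id\tstrength\n")
        for tf, gene, s in prior.edges():
            fh.write(f"{tf}\t{gene}\t{s:.17g}\n")


def load_prior(path: str | Path) -> ConnectivityPrior:
    """Read the edge-list TSV written by :func:`save_prior`."""
    df = pd.read_csv(path, sep="\t", dtype={"tf_id": str, "gene_id": str},
                     float_precision="round_trip")
    tfs = list(dict.fromkeys(df["tf_id"]))
    genes = list(dict.fromkeys(df["gene_id"]))
    strengths = np.zeros((len(genes), len(tfs)))
    gi = {g: i for i, g in enumerate(genes)}
    tj = {t: j for j, t in enumerate(tfs)}
    for tf, gene, s in df.itertuples(index=False):
        strengths[gi[gene], tj[tf]] = float(s)
    return ConnectivityPrior(
        tf_ids=tfs, gene_ids=genes,
        support=strengths != 0, initial_strengths=strengths,
    )
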