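"""Synthetic ground truth for the full reconstruction pipeline.

Generates an identifiable sparse signed connectivity matrix, stage-specific
TF-activity trajectories on the log2 scale (control stage pinned to zero),
and noisy expression via the log-linear model E = S A + noise. Noise is
additive Gaussian on the log2 scale (multiplicative log-normal on the linear
scale) and is applied only to non-control stages, so the control column of
the emitted expression matrix is exactly zero, as a ratio to itself must be.

The default stage panel mirrors a seven-stage pollen developmental course
(uninucleate microspore through 4-hour germinated tube) with mature pollen
as the control, but any ordered label set works.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .expression import ExpressionMatrix, save_expression
from .prior import ConnectivityPrior, check_identifiability, save_prior

__all__ = [
    "SyntheticTruth",
    "DEFAULT_STAGES",
    "DEFAULT_CONTROL",
    "generate_prior_topology",
    "generate_tf_activities",
    "generate_expression",
    "generate_truth",
    "save_truth",
    "load_truth",
]

DEFAULT_STAGES = ["UNM", "BCP", "TCP", "MP", "HP", "0.5hr", "4hr"]
DEFAULT_CONTROL = "MP"

_MAX_TOPOLOGY_ATTEMPTS = 1000


@dataclass
class SyntheticTruth:
    """A complete simulated dataset with known generating parameters."""

    prior: ConnectivityPrior
    activities: np.ndarray  # L x M, log2 scale, control column zero
    expression: ExpressionMatrix
    noise_sd: float
    seed: int
    stage_labels: list[str]
    control_stage: str


def generate_prior_topology(
    n_genes: int,
    n_tfs: int,
    edges_per_gene: int = 2,
    strength_range: tuple[float, float] = (0.5, 1.0),
    sign_fraction: float = 0.3,
    seed: int = 0,
    n_conditions: int | None = None,
) -> ConnectivityPrior:
    """Random sparse signed connectivity satisfying the identifiability criteria.

    Each gene receives ``edges_per_gene`` regulators drawn without replacement;
    every TF is guaranteed at least one exclusive target (required by the
    reduced-rank criterion). Nonzero strengths are uniform on
    ``+-strength_range`` with ``sign_fraction`` of them negative. Rejection
    sampling against :func:`check_identifiability` caps out at 1000 attempts
    and raises, which signals infeasible parameters (e.g. every gene regulated
    by every TF).
    """
    if not (n_genes >= n_tfs >= 1):
        raise ValueError("need n_genes >= n_tfs >= 1")
    if not (1 <= edges_per_gene <= n_tfs):
        raise ValueError("need 1 <= edges_per_gene <= n_tfs")
    lo, hi = strength_range
    if not (0 < lo <= hi):
        raise ValueError("strength_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    n_cond = n_conditions if n_conditions is not None else n_tfs
    tf_ids = [f"TF{j:03d}" for j in range(n_tfs)]
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    for _ in range(_MAX_TOPOLOGY_ATTEMPTS):
        support = np.zeros((n_genes, n_tfs), dtype=bool)
        for i in range(n_genes):
            regs = rng.choice(n_tfs, size=edges_per_gene, replace=False)
            support[i, regs] = True
        if not support.any(axis=0).all():
            continue  # a TF with no target can never be identifiable
        strengths = np.zeros((n_genes, n_tfs))
        k = int(support.sum())
        mag = rng.uniform(lo, hi, size=k)
        neg = rng.random(k) < sign_fraction
        vals = np.where(neg, -mag, mag)
        strengths[support] = vals
        prior = ConnectivityPrior(tf_ids, gene_ids, support, strengths)
        if check_identifiability(prior, n_cond, seed=int(rng.integers(2**31))).passed:
            return prior
    raise RuntimeError(
        f"no identifiable topology found in {_MAX_TOPOLOGY_ATTEMPTS} attempts; "
        "parameters are likely infeasible (try fewer edges per gene)"
    )


def generate_tf_activities(
    n_tfs: int,
    stage_labels: list[str] | None = None,
    control_stage: str = DEFAULT_CONTROL,
    peak_model: str = "single-peak",
    amplitude: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Stage-specific log2 TF-activity trajectories, control column zero.

    ``single-peak`` gives each TF one smooth interior bump (a stage-specific
    activation peak); ``monotone`` a steadily rising or falling course;
    ``flat`` all zeros. Every row satisfies max |value| <= amplitude.
    """
    stages = list(stage_labels) if stage_labels is not None else list(DEFAULT_STAGES)
    if control_stage not in stages:
        raise ValueError(f"unknown control stage {control_stage!r}")
    M = len(stages)
    c = stages.index(control_stage)
    rng = np.random.default_rng(seed)
    A = np.zeros((n_tfs, M))
    if peak_model == "flat":
        return A
    t = np.arange(M, dtype=float)
    for j in range(n_tfs):
        if peak_model == "single-peak":
            interior = [k for k in range(1, M - 1)]
            if not interior:
                raise ValueError("single-peak needs at least 3 stages")
            mu = float(rng.choice(interior)) + rng.uniform(-0.3, 0.3)
            sigma = rng.uniform(max(0.8, M / 8.0), M / 4.0)
            row = amplitude * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
        elif peak_model == "monotone":
            direction = 1.0 if rng.random() < 0.5 else -1.0
            steps = rng.uniform(0.2, 1.0, size=M - 1)
            row = direction * np.concatenate([[0.0], np.cumsum(steps)])
            row *= amplitude / np.abs(row).max()
        else:
            raise ValueError(f"unknown peak_model {peak_model!r}")
        row = row - row[c]  # pin control stage to zero (log2 ratio convention)
        A[j] = row
    return A


def generate_expression(
    prior: ConnectivityPrior,
    activities: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    stage_labels: list[str] | None = None,
    control_stage: str = DEFAULT_CONTROL,
) -> ExpressionMatrix:
    """Noisy log-linear expression: values = S @ A + Gaussian log2 noise.

    The control column receives no noise and is exactly zero whenever the
    activities' control column is zero (a ratio of the control to itself).
    """
    activities = np.asarray(activities, dtype=float)
    if activities.shape[0] != prior.n_tfs:
        raise ValueError(
            f"activity rows ({activities.shape[0]}) != prior TFs ({prior.n_tfs})"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    M = activities.shape[1]
    stages = list(stage_labels) if stage_labels is not None else list(DEFAULT_STAGES)
    if len(stages) != M:
        raise ValueError(f"{len(stages)} stage labels for {M} activity columns")
    c = stages.index(control_stage)
    vals = prior.initial_strengths @ activities
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=vals.shape)
        noise[:, c] = 0.0
        vals = vals + noise
    vals[:, c] = prior.initial_strengths @ activities[:, c]  # stays exact
    return ExpressionMatrix(prior.gene_ids, stages, vals, control_stage)


def generate_truth(
    n_genes: int = 100,
    n_tfs: int = 5,
    stage_labels: list[str] | None = None,
    control_stage: str | None = None,
    edges_per_gene: int = 2,
    noise_sd: float = 0.1,
    amplitude: float = 2.0,
    peak_model: str = "single-peak",
    seed: int = 0,
    include_tf_expression: bool = True,
) -> SyntheticTruth:
    """One-call simulation of a full ground-truth bundle.

    With ``include_tf_expression`` (the default) the expression matrix also
    carries one row per TF gene whose log2 ratios track that TF's activity
    (plus the same log2-scale noise), emulating the fact that a regulator's
    own transcript is measured alongside its targets — prior construction
    and edge-sign assignment both need those rows.
    """
    stages = list(stage_labels) if stage_labels is not None else list(DEFAULT_STAGES)
    control = control_stage if control_stage is not None else (
        DEFAULT_CONTROL if DEFAULT_CONTROL in stages else stages[0])
    rng = np.random.default_rng(seed)
    s1, s2, s3, s4 = (int(x) for x in rng.integers(2**31, size=4))
    prior = generate_prior_topology(
        n_genes, n_tfs, edges_per_gene=edges_per_gene, seed=s1,
        n_conditions=len(stages),
    )
    A = generate_tf_activities(
        n_tfs, stages, control, peak_model=peak_model,
        amplitude=amplitude, seed=s2,
    )
    E = generate_expression(prior, A, noise_sd=noise_sd, seed=s3,
                            stage_labels=stages, control_stage=control)
    if include_tf_expression:
        c = stages.index(control)
        tf_vals = A.copy()
        if noise_sd > 0:
            noise = np.random.default_rng(s4).normal(0.0, noise_sd, size=A.shape)
            noise[:, c] = 0.0
            tf_vals = tf_vals + noise
        E = ExpressionMatrix(
            gene_ids=list(prior.gene_ids) + list(prior.tf_ids),
            stage_labels=stages,
            values=np.vstack([E.values, tf_vals]),
            control_stage=control,
        )
    return SyntheticTruth(
        prior=prior, activities=A, expression=E, noise_sd=noise_sd,
        seed=seed, stage_labels=stages, control_stage=control,
    )


def planted_ffl_network(
    n_nodes: int = 50,
    n_background_edges: int = 40,
    n_ffls: int = 15,
    seed: int = 0,
):
    """Random digraph with feed-forward loops planted on top.

    Background edges are drawn uniformly among ordered node pairs (no
    self-loops); then ``n_ffls`` node triples (a, b, c) each receive the
    full loop a->b, a->c, b->c. Used to validate motif over-representation
    scoring: the FFL class should dominate the size-3 z-scores.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    G = nx.DiGraph()
    G.add_nodes_from(range(n_nodes))
    while G.number_of_edges() < n_background_edges:
        u, v = rng.integers(0, n_nodes, size=2)
        if u != v:
            G.add_edge(int(u), int(v))
    for _ in range(n_ffls):
        a, b, c = rng.choice(n_nodes, size=3, replace=False)
        G.add_edge(int(a), int(b))
        G.add_edge(int(a), int(c))
        G.add_edge(int(b), int(c))
    return G


def save_truth(truth: SyntheticTruth, outdir: str | Path) -> dict:
    """Write a truth bundle: expression TSV, prior edge-list TSV,
    activities TSV and a JSON manifest recording seed and parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_expression(truth.expression, outdir / "expression.tsv")
    save_prior(truth.prior, outdir / "prior.tsv")
    with open(outdir / "activities.tsv", "w", encoding="utf-8") as fh:
        fh.write("tf_id\t" + "\t".join(truth.stage_labels) + "\n")
        for j, tf in enumerate(truth.prior.tf_ids):
            row = "\t".join(f"{v:.17g}" for v in truth.activities[j])
            fh.write(f"{tf}\t{row}\n")
    manifest = {
        "seed": truth.seed,
        "noise_sd": truth.noise_sd,
        "n_genes": truth.prior.n_genes,
        "n_tfs": truth.prior.n_tfs,
        "stage_labels": truth.stage_labels,
        "control_stage": truth.control_stage,
        "files": ["expression.tsv", "prior.tsv", "activities.tsv"],
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def load_truth(outdir: str | Path) -> SyntheticTruth:
    """Read back a bundle written by :func:`save_truth`."""
    import pandas as pd

    from .expression import load_expression
    from .prior import load_prior

    outdir = Path(outdir)
    with open(outdir / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    control = manifest["control_stage"]
    E = load_expression(outdir / "expression.tsv", control)
    prior = load_prior(outdir / "prior.tsv")
    act = pd.read_csv(outdir / "activities.tsv", sep="\t", index_col=0)
    A = act.loc[prior.tf_ids].to_numpy(dtype=float)
    return SyntheticTruth(
        prior=prior, activities=A, expression=E,
        noise_sd=float(manifest["noise_sd"]), seed=int(manifest["seed"]),
        stage_labels=manifest["stage_labels"], control_stage=control,
    )
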