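"""Network Component Analysis: constrained decomposition of expression.

The model is log-linear: each gene's log2 expression ratio is a weighted sum
of hidden log2 TF-activity ratios,

    [E] = [S][A],   S constrained to the prior support Z0,

with [E] the N x M log-ratio matrix, [S] the N x L control strengths and [A]
the L x M activities. When the prior satisfies the identifiability criteria
the factorisation is unique up to a diagonal scaling gauge
[S][A] = [S][X][X^-1][A], which :meth:`NCAResults.normalize` fixes.

The estimator is alternating least squares (ALS): with A fixed, each gene's
supported strength entries solve an ordinary least-squares problem on its own
row; with S fixed, A solves a single unconstrained least-squares problem.
Both half-steps minimise the same Frobenius objective, so the objective
trajectory is nonincreasing. Multiple restarts (the first from the prior's
correlation-valued strengths, the rest from random activities) guard against
local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionMatrix
from .prior import ConnectivityPrior, check_identifiability

__all__ = ["NCAModel", "NCAResults", "BootstrapResult"]


def _solve_strengths(E: np.ndarray, A: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Per-gene least squares for S restricted to the support pattern."""
    N, L = support.shape
    S = np.zeros((N, L))
    for i in range(N):
        cols = np.flatnonzero(support[i])
        sol, *_ = np.linalg.lstsq(A[cols].T, E[i], rcond=None)
        S[i, cols] = sol
    return S


def _objective(E: np.ndarray, S: np.ndarray, A: np.ndarray) -> float:
    return float(np.linalg.norm(E - S @ A, "fro"))


@dataclass
class NCAResults:
    """Fitted strengths, activities and diagnostics of an NCA decomposition.

    Attributes
    ----------
    strengths : ndarray (N, L)
        Adjusted control strengths [S]; exactly zero off the prior support.
    activities : ndarray (L, M)
        log2 TF activity ratios [A].
    objective_trajectory : ndarray
        Frobenius residual after each full ALS iteration (nonincreasing).
    converged : bool
        Whether the relative objective change fell below tolerance.
    normalization : str
        Gauge convention applied ("raw" until :meth:`normalize` is called).
    """

    model: "NCAModel"
    strengths: np.ndarray
    activities: np.ndarray
    objective_trajectory: np.ndarray
    converged: bool
    n_iterations: int
    normalization: str = "raw"
    restart_objectives: list[float] = field(default_factory=list)

    @property
    def tf_ids(self) -> list[str]:
        return self.model.prior.tf_ids

    @property
    def gene_ids(self) -> list[str]:
        return self.model.prior.gene_ids

    @property
    def stage_labels(self) -> list[str]:
        return self.model.E.stage_labels

    @property
    def objective(self) -> float:
        return float(self.objective_trajectory[-1])

    def reconstruction_error(self) -> tuple[float, np.ndarray]:
        """Frobenius residual ||E - S A||_F and per-gene row residuals."""
        R = self.model.E.subset(self.gene_ids).values - self.strengths @ self.activities
        return float(np.linalg.norm(R, "fro")), np.linalg.norm(R, axis=1)

    def normalize(self, convention: str = "control-zero") -> "NCAResults":
        """Fix the diagonal scaling gauge of the decomposition.

        Both conventions scale each activity row to unit L2 norm (the inverse
        scale goes into the strength column, so S @ A is unchanged) and pick
        the sign so each strength column correlates nonnegatively with the
        prior's initial strengths. "control-zero" additionally pins the
        control-stage activity entry to zero: at any least-squares optimum
        this entry is already exactly zero (the control column of E is zero),
        so the shift only cleans up externally perturbed inputs, and raises
        if a genuinely nonzero control entry would have to be moved.
        """
        if convention not in ("control-zero", "unit-activity-norm"):
            raise ValueError(f"unknown normalization convention {convention!r}")
        S = self.strengths.copy()
        A = self.activities.copy()
        c = self.model.E.control_index
        if convention == "control-zero":
            ctl = A[:, c]
            scale = np.linalg.norm(A, axis=1)
            bad = np.abs(ctl) > 1e-8 * np.maximum(scale, 1e-300)
            if np.any(bad):
                j = int(np.argmax(bad))
                raise ValueError(
                    f"activity row {self.tf_ids[j]!r} has nonzero control-stage "
                    f"entry {ctl[j]:.3g}; cannot zero it within the gauge"
                )
            A[:, c] = 0.0
        norms = np.linalg.norm(A, axis=1)
        if np.any(norms == 0):
            j = int(np.argmax(norms == 0))
            raise ValueError(f"activity row {self.tf_ids[j]!r} is zero; cannot normalize")
        prior_s = self.model.prior.initial_strengths
        signs = np.ones(len(norms))
        for j in range(len(norms)):
            dot = float(S[:, j] @ prior_s[:, j])
            if dot < 0:
                signs[j] = -1.0
            elif dot == 0:
                # tie-break: make the largest-|.| strength entry positive
                k = int(np.argmax(np.abs(S[:, j])))
                if S[k, j] < 0:
                    signs[j] = -1.0
        # diagonal gauge: A_j -> x_j A_j, S_:,j -> S_:,j / x_j  (RMS-1 rows)
        root_m = np.sqrt(len(self.stage_labels))
        A = A * (signs / norms)[:, None] * root_m
        S = S * (norms * signs)[None, :] / root_m
        return NCAResults(
            model=self.model,
            strengths=S,
            activities=A,
            objective_trajectory=self.objective_trajectory,
            converged=self.converged,
            n_iterations=self.n_iterations,
            normalization=convention,
            restart_objectives=self.restart_objectives,
        )

    def summary(self) -> str:
        """Human-readable fit report."""
        resid, _ = self.reconstruction_error()
        Enorm = np.linalg.norm(self.model.E.subset(self.gene_ids).values, "fro")
        lines = [
            "Network Component Analysis Results",
            "==================================",
            f"genes (N):            {len(self.gene_ids)}",
            f"TFs (L):              {len(self.tf_ids)}",
            f"stages (M):           {len(self.stage_labels)}",
            f"prior edges:          {self.model.prior.n_edges}",
            f"iterations:           {self.n_iterations}",
            f"converged:            {self.converged}",
            f"Frobenius residual:   {resid:.6g}",
            f"relative residual:    {resid / Enorm if Enorm else 0.0:.6g}",
            f"normalization:        {self.normalization}",
            "",
            f"{'TF':<16}{'targets':>8}{'|strength| mean':>18}{'activity range':>22}",
        ]
        for j, tf in enumerate(self.tf_ids):
            col = self.strengths[:, j]
            nz = col[col != 0]
            arow = self.activities[j]
            lines.append(
                f"{tf:<16}{nz.size:>8}{np.abs(nz).mean():>18.4f}"
                f"{'[%.3f, %.3f]' % (arow.min(), arow.max()):>22}"
            )
        return "\n".join(lines)


@dataclass
class BootstrapResult:
    """Percentile intervals from gene-resampling bootstrap."""

    strength_low: np.ndarray
    strength_high: np.ndarray
    activity_low: np.ndarray
    activity_high: np.ndarray
    n_successful: int
    level: float


class NCAModel:
    """Constrained matrix decomposition of staged expression data.

    Parameters
    ----------
    E : ExpressionMatrix
        log2 expression ratios; must contain every gene of the prior.
    prior : ConnectivityPrior
        Support pattern Z0 with initial control strengths.
    check : bool
        Verify the identifiability criteria before allowing a fit.
    """

    def __init__(self, E: ExpressionMatrix, prior: ConnectivityPrior,
                 check: bool = True):
        missing = [g for g in prior.gene_ids if g not in set(E.gene_ids)]
        if missing:
            raise ValueError(f"prior genes absent from expression: {missing[:5]}")
        self.E = E
        self.prior = prior
        self.identifiability = check_identifiability(prior, E.n_stages)
        if check and not self.identifiability.passed:
            rep = self.identifiability
            raise ValueError(
                "prior fails identifiability: "
                f"full_column_rank={rep.full_column_rank}, "
                f"reduced_rank_ok={rep.reduced_rank_ok} "
                f"(violating TFs: {rep.violating_tfs[:5]}), "
                f"conditions_ok={rep.conditions_ok}"
            )

    @classmethod
    def from_dataframe(cls, frame, control_stage: str, prior: ConnectivityPrior,
                       **kw) -> "NCAModel":
        """Build from a genes x stages DataFrame of log2 ratios."""
        E = ExpressionMatrix(
            gene_ids=[str(g) for g in frame.index],
            stage_labels=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            control_stage=control_stage,
        )
        return cls(E, prior, **kw)

    def _als(self, Emat: np.ndarray, S0: np.ndarray | None, A0: np.ndarray | None,
             max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, list[float], bool, int]:
        support = self.prior.support
        if A0 is None:
            S = S0
            A, *_ = np.linalg.lstsq(S, Emat, rcond=None)
        else:
            A = A0
            S = _solve_strengths(Emat, A, support)
            A, *_ = np.linalg.lstsq(S, Emat, rcond=None)
        traj = [_objective(Emat, S, A)]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            S = _solve_strengths(Emat, A, support)
            A, *_ = np.linalg.lstsq(S, Emat, rcond=None)
            f = _objective(Emat, S, A)
            traj.append(f)
            prev = traj[-2]
            if prev - f <= tol * max(prev, 1e-300):
                converged = True
                break
        return S, A, traj, converged, it

    def fit(self, max_iter: int = 1000, tol: float = 1e-8, n_restarts: int = 10,
            seed: int = 0) -> NCAResults:
        """Alternating least squares, best of several restarts.

        Restart 0 initialises S at the prior's initial strengths (the
        correlation coefficients); subsequent restarts draw A from a standard
        normal. The best final objective wins; the returned trajectory is the
        winner's and is guaranteed nonincreasing.
        """
        if not self.identifiability.passed:
            raise ValueError("refusing to fit a non-identifiable prior; "
                             "see model.identifiability")
        rng = np.random.default_rng(seed)
        Emat = self.E.subset(self.prior.gene_ids).values
        L, M = self.prior.n_tfs, self.E.n_stages
        best = None
        restart_objectives: list[float] = []
        for r in range(max(1, n_restarts)):
            if r == 0:
                out = self._als(Emat, self.prior.initial_strengths.copy(), None,
                                max_iter, tol)
            else:
                A0 = rng.standard_normal((L, M))
                out = self._als(Emat, None, A0, max_iter, tol)
            restart_objectives.append(out[2][-1])
            if best is None or out[2][-1] < best[2][-1]:
                best = out
        S, A, traj, converged, iters = best
        return NCAResults(
            model=self,
            strengths=S,
            activities=A,
            objective_trajectory=np.asarray(traj),
            converged=converged,
            n_iterations=iters,
            restart_objectives=restart_objectives,
        )

    def bootstrap(self, n_boot: int = 100, seed: int = 0, level: float = 0.95,
                  max_iter: int = 200, tol: float = 1e-8,
                  reference: NCAResults | None = None,
                  max_redraws: int = 20) -> BootstrapResult:
        """Gene-resampling bootstrap with gauge alignment.

        Each replicate resamples gene rows with replacement; draws whose
        support pattern breaks identifiability are redrawn (bounded). Each
        refit is aligned to the reference solution by the per-TF diagonal
        gauge (least-squares scale of activity rows), then strengths for all
        original genes are re-solved against the aligned activities so every
        replicate yields a complete strength matrix. Percentile intervals
        are returned. Raises if fewer than half the replicates succeed.
        """
        rng = np.random.default_rng(seed)
        if reference is None:
            reference = self.fit(max_iter=max_iter, tol=tol, n_restarts=1,
                                 seed=seed).normalize()
        Emat = self.E.subset(self.prior.gene_ids).values
        N = self.prior.n_genes
        S_samples, A_samples = [], []
        for _ in range(n_boot):
            fit_out = None
            for _try in range(max_redraws):
                idx = np.sort(rng.integers(0, N, size=N))
                sub_support = self.prior.support[idx]
                # dedup rows for the rank test: duplicates add no rank
                uniq = np.unique(idx)
                test_prior_ok = True
                try:
                    sub_prior = ConnectivityPrior(
                        tf_ids=self.prior.tf_ids,
                        gene_ids=[f"g{k}" for k in range(len(uniq))],
                        support=self.prior.support[uniq],
                        initial_strengths=self.prior.initial_strengths[uniq],
                    )
                except ValueError:
                    test_prior_ok = False
                if test_prior_ok and check_identifiability(
                        sub_prior, self.E.n_stages).passed:
                    boot_prior = ConnectivityPrior(
                        tf_ids=self.prior.tf_ids,
                        gene_ids=[f"b{k}" for k in range(N)],
                        support=sub_support,
                        initial_strengths=self.prior.initial_strengths[idx],
                    )
                    boot_E = ExpressionMatrix(
                        gene_ids=[f"b{k}" for k in range(N)],
                        stage_labels=self.E.stage_labels,
                        values=Emat[idx],
                        control_stage=self.E.control_stage,
                    )
                    model = NCAModel(boot_E, boot_prior, check=False)
                    fit_out = model.fit(max_iter=max_iter, tol=tol,
                                        n_restarts=1, seed=int(rng.integers(2**31)))
                    break
            if fit_out is None:
                continue
            A_b = fit_out.activities
            # gauge-align each activity row to the reference by least squares
            scales = np.empty(self.prior.n_tfs)
            for j in range(self.prior.n_tfs):
                denom = float(A_b[j] @ A_b[j])
                scales[j] = (float(A_b[j] @ reference.activities[j]) / denom
                             if denom > 0 else 1.0)
            A_aligned = A_b * scales[:, None]
            S_full = _solve_strengths(Emat, A_aligned, self.prior.support)
            S_samples.append(S_full)
            A_samples.append(A_aligned)
        if len(S_samples) < max(1, n_boot // 2):
            raise ValueError(
                f"only {len(S_samples)}/{n_boot} bootstrap draws were identifiable"
            )
        Ss = np.stack(S_samples)
        As = np.stack(A_samples)
        alpha = (1.0 - level) / 2.0
        return BootstrapResult(
            strength_low=np.quantile(Ss, alpha, axis=0),
            strength_high=np.quantile(Ss, 1 - alpha, axis=0),
            activity_low=np.quantile(As, alpha, axis=0),
            activity_high=np.quantile(As, 1 - alpha, axis=0),
            n_successful=len(S_samples),
            level=level,
        )
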