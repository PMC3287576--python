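"""Staged expression tables on the log2-ratio scale.

All downstream machinery works on log2 expression ratios relative to a
designated control stage (e.g. mature pollen, "MP"): the control column of a
valid :class:`ExpressionMatrix` is identically zero by construction, because
a ratio of a stage to itself is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "load_expression",
    "save_expression",
    "compute_log_ratios",
    "filter_degs",
]


@dataclass
class ExpressionMatrix:
    """N genes x M stages of log2 expression ratios relative to a control stage.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers (row labels).
    stage_labels : list of str
        Ordered, unique condition labels (column labels).
    values : ndarray of shape (N, M)
        log2 fold changes versus the control stage. Must be finite.
    control_stage : str
        The reference stage; its column, if present, must be identically zero.
    """

    gene_ids: list[str]
    stage_labels: list[str]
    values: np.ndarray
    control_stage: str
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.stage_labels = list(self.stage_labels)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        if len(set(self.stage_labels)) != len(self.stage_labels):
            raise ValueError("duplicate stage labels")
        if self.control_stage not in self.stage_labels:
            raise ValueError(
                f"control stage {self.control_stage!r} not among stages "
                f"{self.stage_labels}"
            )
        if self.values.shape != (len(self.gene_ids), len(self.stage_labels)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.stage_labels)} stages"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"stage {self.stage_labels[j]!r}"
            )
        ctl = self.values[:, self.control_index]
        if np.any(ctl != 0.0):
            i = int(np.argmax(ctl != 0.0))
            raise ValueError(
                f"control-stage column {self.control_stage!r} must be zero; "
                f"gene {self.gene_ids[i]!r} has {ctl[i]!r}"
            )
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)

    @property
    def control_index(self) -> int:
        return self.stage_labels.index(self.control_stage)

    def row(self, gene_id: str) -> np.ndarray:
        """Return the log2-ratio trajectory of one gene."""
        return self.values[self._index[gene_id]]

    def subset(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Row-subset preserving the requested order."""
        idx = [self._index[g] for g in gene_ids]
        return ExpressionMatrix(
            gene_ids=list(gene_ids),
            stage_labels=self.stage_labels,
            values=self.values[idx].copy(),
            control_stage=self.control_stage,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.stage_labels,
        )


def load_expression(path: str | Path, control_stage: str) -> ExpressionMatrix:
    """Read a tab-delimited expression table of log2 ratios.

    Layout: header row of stage labels, first column gene IDs, tab-separated,
    UTF-8. Duplicate gene rows, non-numeric cells and a nonzero control column
    are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     float_precision="round_trip")
    vals = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            vals[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            row = df.index[bad.isna().to_numpy().argmax()]
            raise ValueError(
                f"non-numeric cell at gene {row!r}, stage {col!r} in {path}"
            ) from exc
    if np.isnan(vals).any():
        i, j = np.argwhere(np.isnan(vals))[0]
        raise ValueError(
            f"missing value at gene {df.index[i]!r}, stage {df.columns[j]!r} "
            f"in {path}"
        )
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        stage_labels=[str(c) for c in df.columns],
        values=vals,
        control_stage=control_stage,
    )


def save_expression(E: ExpressionMatrix, path: str | Path) -> None:
    """Write the same tab-delimited dialect :func:`load_expression` reads."""
    E.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def compute_log_ratios(
    raw: pd.DataFrame | np.ndarray,
    control_stage: str,
    gene_ids: list[str] | None = None,
    stage_labels: list[str] | None = None,
) -> ExpressionMatrix:
    """log2(stage / control) ratios from a positive linear-scale matrix.

    ``values[i, t] = log2(raw[i, t] / raw[i, control])``; the control column
    comes out exactly zero.
    """
    if isinstance(raw, pd.DataFrame):
        gene_ids = [str(g) for g in raw.index]
        stage_labels = [str(c) for c in raw.columns]
        mat = raw.to_numpy(dtype=float)
    else:
        mat = np.asarray(raw, dtype=float)
        if gene_ids is None or stage_labels is None:
            raise ValueError("gene_ids and stage_labels required for array input")
    if np.any(mat <= 0):
        i, j = np.argwhere(mat <= 0)[0]
        raise ValueError(
            f"nonpositive linear expression at gene {gene_ids[i]!r}, "
            f"stage {stage_labels[j]!r}: {mat[i, j]}"
        )
    if control_stage not in stage_labels:
        raise ValueError(f"control stage {control_stage!r} not in columns")
    c = stage_labels.index(control_stage)
    vals = np.log2(mat / mat[:, [c]])
    vals[:, c] = 0.0  # exact zero, not round-off
    return ExpressionMatrix(gene_ids, stage_labels, vals, control_stage)


def filter_degs(
    E: ExpressionMatrix, fc_threshold: float = 1.6, min_stages: int = 1,
    log_scale_threshold: bool = False,
) -> list[str]:
    """Differentially expressed genes by fold-change threshold.

    A gene passes when ``|log2 ratio| > log2(fc_threshold)`` in at least
    ``min_stages`` stages. ``fc_threshold`` is a linear-scale fold change
    (the conventional reading of "FC > 1.6"); set ``log_scale_threshold``
    to interpret it directly on the log2 scale instead. Input gene order is
    preserved.
    """
    if not log_scale_threshold and fc_threshold <= 1:
        raise ValueError("linear fold-change threshold must exceed 1")
    if log_scale_threshold and fc_threshold <= 0:
        raise ValueError("log-scale threshold must be positive")
    cut = fc_threshold if log_scale_threshold else np.log2(fc_threshold)
    hits = (np.abs(E.values) > cut).sum(axis=1)
    return [g for g, h in zip(E.gene_ids, hits) if h >= min_stages]
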