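"""Expression-level calls and fold-change direction calls on FPKM matrices.

The high/low call applies the magnitude rule literally to log2(FPKM): a gene
is "high" in a condition when |log2(FPKM)| >= threshold, so both strongly
expressed (FPKM >= 2) and barely expressed (0 < FPKM <= 0.5) genes qualify.
The interpretation is selectable (``mode='literal'`` vs ``'positive_only'``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation_io import round2

__all__ = [
    "ExpressionMatrix",
    "ExpressionCallSet",
    "FoldChangeCalls",
    "call_expression",
    "fold_change_calls",
    "heatmap_matrix",
    "read_expression_tsv",
    "render_heatmap",
]

NOT_EXPRESSED = "not_expressed"
LOW = "low"
HIGH = "high"
UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"

FC_FLOOR = 10.0  # |log2FC| cap when one side is zero


@dataclass
class ExpressionMatrix:
    """FPKM values (genes x samples) plus a sample -> condition mapping.

    Samples of the same condition are biological replicates and are averaged
    (arithmetic mean of FPKM) before any log transform.
    """

    values: pd.DataFrame
    sample_conditions: dict[str, str]

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("FPKM values must be nonnegative")
        if self.values.index.duplicated().any():
            raise ValueError("gene names must be unique")
        missing = [c for c in self.values.columns if c not in self.sample_conditions]
        if missing:
            raise ValueError(f"samples without condition metadata: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            c = self.sample_conditions[s]
            if c not in seen:
                seen.append(c)
        return seen

    def condition_means(self) -> pd.DataFrame:
        """Replicate-averaged FPKM, genes x conditions."""
        cols = {}
        for cond in self.conditions:
            samples = [s for s in self.values.columns if self.sample_conditions[s] == cond]
            cols[cond] = self.values[samples].mean(axis=1)
        return pd.DataFrame(cols, index=self.values.index)


@dataclass
class ExpressionCallSet:
    status: pd.DataFrame  # genes x conditions, values in {not_expressed, low, high}
    log2_values: pd.DataFrame  # NaN where not expressed

    def condition_summary(self) -> pd.DataFrame:
        """Per condition: expressed count and high percentage (2 decimals)."""
        rows = []
        for cond in self.status.columns:
            col = self.status[cond]
            expressed = int((col != NOT_EXPRESSED).sum())
            high = int((col == HIGH).sum())
            pct = round2(100.0 * high / expressed) if expressed else 0.0
            rows.append({"condition": cond, "expressed": expressed,
                         "high": high, "high_pct": pct})
        return pd.DataFrame(rows).set_index("condition")


def call_expression(
    mat: ExpressionMatrix, high_threshold: float = 1.0, mode: str = "literal"
) -> ExpressionCallSet:
    """Classify each gene x condition cell as not_expressed / low / high.

    FPKM = 0 -> not_expressed; otherwise log2(FPKM) is taken with no
    pseudocount and compared to the threshold (``literal``: absolute value;
    ``positive_only``: signed value).
    """
    if high_threshold <= 0:
        raise ValueError("high_threshold must be positive")
    if mode not in ("literal", "positive_only"):
        raise ValueError(f"unknown mode {mode!r}")
    means = mat.condition_means()
    log2_vals = np.full(means.shape, np.nan)
    np.log2(means.values, out=log2_vals, where=means.values > 0)
    log2 = pd.DataFrame(log2_vals, index=means.index, columns=means.columns)
    magnitude = log2.abs() if mode == "literal" else log2
    status = pd.DataFrame(
        np.where(
            means.values == 0,
            NOT_EXPRESSED,
            np.where(magnitude.values >= high_threshold, HIGH, LOW),
        ),
        index=means.index,
        columns=means.columns,
    )
    return ExpressionCallSet(status=status, log2_values=log2)


@dataclass
class FoldChangeCalls:
    direction: pd.DataFrame  # genes x non-baseline conditions
    log2_fc: pd.DataFrame

    def summary(self) -> dict[str, float]:
        """Percentages of up/down genes among expressed genes.

        A gene counts as up (down) when any timepoint calls it up (down);
        percentages use the expressed-gene count as denominator.
        """
        expressed = self.direction.apply(
            lambda row: not (row == NOT_EXPRESSED).all(), axis=1
        )
        n_exp = int(expressed.sum())
        up = int(((self.direction == UP).any(axis=1) & expressed).sum())
        down = int(((self.direction == DOWN).any(axis=1) & expressed).sum())
        return {
            "expressed": n_exp,
            "up": up,
            "down": down,
            "up_pct": round2(100.0 * up / n_exp) if n_exp else 0.0,
            "down_pct": round2(100.0 * down / n_exp) if n_exp else 0.0,
        }


def fold_change_calls(
    mat: ExpressionMatrix,
    baseline: str,
    fc_threshold: float = 1.0,
    floor: float = FC_FLOOR,
) -> FoldChangeCalls:
    """Per-gene, per-condition regulation direction against a baseline.

    Replicates are averaged before the ratio.  Zero handling: condition 0
    with baseline > 0 is down at the cap (-floor); baseline 0 with condition
    > 0 is newly expressed, up at the cap; both zero is not_expressed at that
    timepoint.
    """
    means = mat.condition_means()
    if baseline not in means.columns:
        raise ValueError(f"baseline condition {baseline!r} not in matrix")
    others = [c for c in means.columns if c != baseline]
    base = means[baseline]
    direction = {}
    log2fc = {}
    for cond in others:
        cur = means[cond]
        fc = pd.Series(np.nan, index=means.index)
        call = pd.Series(UNCHANGED, index=means.index)
        both_zero = (cur == 0) & (base == 0)
        new_expr = (cur > 0) & (base == 0)
        lost_expr = (cur == 0) & (base > 0)
        ok = (cur > 0) & (base > 0)
        fc[ok] = np.log2(cur[ok] / base[ok])
        fc[new_expr] = floor
        fc[lost_expr] = -floor
        call[both_zero] = NOT_EXPRESSED
        call[(fc >= fc_threshold) & ~both_zero] = UP
        call[(fc <= -fc_threshold) & ~both_zero] = DOWN
        direction[cond] = call
        log2fc[cond] = fc
    return FoldChangeCalls(
        direction=pd.DataFrame(direction, index=means.index),
        log2_fc=pd.DataFrame(log2fc, index=means.index),
    )


def heatmap_matrix(values: pd.DataFrame, gene_order: Iterable[str]) -> pd.DataFrame:
    """Reorder matrix rows by a phylogeny-derived gene ordering."""
    order = list(gene_order)
    if sorted(order) != sorted(values.index):
        raise ValueError("gene_order is not a permutation of the matrix genes")
    return values.loc[order]


def read_expression_tsv(
    path: str | Path, conditions: Mapping[str, str] | None = None
) -> ExpressionMatrix:
    """Load a genes-by-samples FPKM TSV; first column is the gene name.

    Without explicit metadata, each sample is its own condition.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = dict(conditions) if conditions else {c: c for c in df.columns}
    return ExpressionMatrix(values=df, sample_conditions=meta)


def render_heatmap(values: pd.DataFrame, path: str | Path, cmap: str = "RdBu_r") -> None:
    """Plain heatmap export of a (possibly reordered) log2 matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * values.shape[1] + 2), max(4, 0.18 * values.shape[0] + 1))
    )
    im = ax.imshow(np.nan_to_num(values.values), aspect="auto", cmap=cmap)
    ax.set_xticks(range(values.shape[1]), labels=values.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(values.shape[0]), labels=values.index, fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
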