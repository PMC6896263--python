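"""Marker statistics for cell groups over the gene-level matrix.

For a gene and a group of nuclei, with

    x+ : nuclei in the group with a peak for the gene
    Y+ : all nuclei with a peak for the gene
    x- : nuclei in the group without a peak for the gene
    Y- : all nuclei without a peak for the gene

the two marker statistics are

    top score       =  x+/Y+  -  (x- + 1)/Y-
    specific score  = (x+/Y+) / ((x- + 1)/Y-)

ranked descending within each group, considering only genes with x+ > 10
(strict).  The +1 pseudocount keeps a group with no negatives from
dividing by zero; Y- is likewise guarded with max(Y-, 1) for genes open
in every cell.  These are descriptive enrichment scores, not tests — no
p-values are attached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class UndefinedScoreError(ValueError):
    """Gene open in no cell: both scores are undefined (Y+ = 0)."""


@dataclass(frozen=True)
class MarkerCounts:
    """The four tallies behind the marker scores for one (gene, group)."""

    x_pos: int
    y_pos: int
    x_neg: int
    y_neg: int

    def __post_init__(self) -> None:
        if not (0 <= self.x_pos <= self.y_pos and 0 <= self.x_neg <= self.y_neg):
            raise ValueError(f"inconsistent marker counts: {self}")

    @property
    def group_size(self) -> int:
        return self.x_pos + self.x_neg

    @property
    def total_cells(self) -> int:
        return self.y_pos + self.y_neg


def marker_counts(gene_view: pd.DataFrame, group: list[str], gene: str) -> MarkerCounts:
    """Tally x+/Y+/x-/Y- for one gene and one cell group by direct count."""
    if len(group) == 0:
        raise ValueError("empty group")
    col = gene_view[gene]
    in_group = col.loc[list(group)]
    return MarkerCounts(
        x_pos=int(in_group.sum()),
        y_pos=int(col.sum()),
        x_neg=int(len(in_group) - in_group.sum()),
        y_neg=int(len(col) - col.sum()),
    )


def passes_gate(c: MarkerCounts, gate: int = 10) -> bool:
    """Strict minimum-support gate: the group must hold more than ``gate``
    peak-positive nuclei for the gene."""
    return c.x_pos > gate


def top_score(c: MarkerCounts) -> float:
    """x+/Y+ - (x-+1)/Y-, with Y- guarded by max(Y-, 1)."""
    if c.y_pos == 0:
        raise UndefinedScoreError("gene open in no cell (Y+ = 0)")
    return c.x_pos / c.y_pos - (c.x_neg + 1) / max(c.y_neg, 1)


def specific_score(c: MarkerCounts) -> float:
    """(x+/Y+) / ((x-+1)/Y-): the top-score terms composed as a ratio."""
    if c.y_pos == 0:
        raise UndefinedScoreError("gene open in no cell (Y+ = 0)")
    return (c.x_pos / c.y_pos) / ((c.x_neg + 1) / max(c.y_neg, 1))


def rank_markers(
    gene_view: pd.DataFrame, grouping: dict[str, str], gate: int = 10
) -> pd.DataFrame:
    """Score every (group, gene) pair and rank within groups.

    ``grouping`` maps cell id -> group label over a subset of the matrix's
    cells; counts always contrast the group against *all* cells in the
    view.  Gated genes (x+ <= gate) and genes with Y+ = 0 stay in the
    table with NaN ranks; ranks are descending per score, ties broken by
    gene id.  Rows come back sorted by (group, top score desc, gene).
    """
    cells = [c for c in gene_view.index if c in grouping]
    if not cells:
        raise ValueError("grouping covers no cells of the matrix")
    mat = gene_view.to_numpy(dtype=np.int64)
    y_pos = mat.sum(axis=0)
    y_neg = len(gene_view) - y_pos
    records = []
    for label in sorted(set(grouping[c] for c in cells)):
        members = [c for c in cells if grouping[c] == label]
        idx = gene_view.index.get_indexer(members)
        x_pos = mat[idx].sum(axis=0)
        x_neg = len(members) - x_pos
        with np.errstate(divide="ignore", invalid="ignore"):
            top = x_pos / y_pos - (x_neg + 1) / np.maximum(y_neg, 1)
            spec = (x_pos / y_pos) / ((x_neg + 1) / np.maximum(y_neg, 1))
        top = np.where(y_pos == 0, np.nan, top)
        spec = np.where(y_pos == 0, np.nan, spec)
        gated = x_pos > gate
        df = pd.DataFrame(
            {
                "group": label,
                "gene": gene_view.columns,
                "x_pos": x_pos,
                "y_pos": y_pos,
                "x_neg": x_neg,
                "y_neg": y_neg,
                "top_score": top,
                "specific_score": spec,
                "passes_gate": gated,
            }
        )
        for score in ("top_score", "specific_score"):
            eligible = df[df["passes_gate"] & df[score].notna()].sort_values(
                [score, "gene"], ascending=[False, True], kind="stable"
            )
            rank_col = score.replace("_score", "_rank")
            df[rank_col] = np.nan
            df.loc[eligible.index, rank_col] = np.arange(1, len(eligible) + 1)
        records.append(
            df.sort_values(
                ["top_score", "gene"], ascending=[False, True], kind="stable", na_position="last"
            )
        )
    return pd.concat(records, ignore_index=True)
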