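"""Co-accessibility: peaks whose open/closed pattern tracks a query region.

The Pearson correlation between two binary accessibility vectors across
cells equals the phi coefficient of their 2x2 contingency table, so this
is a contingency screen in correlation clothing.  Hits are peaks whose
coefficient strictly exceeds the threshold (default 0.2); peaks constant
across cells have no defined coefficient and are dropped, and the query
never reports itself.  The screen is genome-wide by default — restrict to
a neighborhood by subsetting the matrix first if wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accessibility import AccessibilityMatrix


@dataclass
class CoaccessResult:
    query: str
    correlations: pd.Series  # per-peak Pearson r, NaN for constant peaks
    hits: pd.Series  # r > threshold, sorted descending
    threshold: float

    def to_tsv(self, path) -> None:
        out = self.correlations.rename("pearson_r").to_frame()
        out["hit"] = out.index.isin(self.hits.index)
        out.to_csv(path, sep="\t", index_label="peak")


def binary_pearson(query: np.ndarray, columns: np.ndarray) -> np.ndarray:
    """Pearson r of one binary vector against each column of a binary matrix.

    Constant columns get NaN.  Computed from centered sums, which for 0/1
    data is exactly the phi coefficient.
    """
    q = query.astype(float)
    x = columns.astype(float)
    n = len(q)
    qc = q - q.mean()
    xc = x - x.mean(axis=0)
    denom = np.sqrt((qc**2).sum() * (xc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (qc @ xc) / denom
    r[(xc**2).sum(axis=0) == 0] = np.nan
    return r


def coaccessible_regions(
    m: AccessibilityMatrix,
    query: str,
    threshold: float = 0.2,
    use_gene_view: bool = False,
) -> CoaccessResult:
    """Correlate a query peak (or gene, with ``use_gene_view``) against every
    other column of the binary matrix over all retained cells.

    Returns all defined coefficients and the hits with r > ``threshold``
    (strict), sorted descending (ties by column name).  A query constant
    across cells has no defined correlation and raises.
    """
    table = m.gene_view if use_gene_view else m.values
    if table is None:
        raise ValueError("matrix has no gene view; run collapse_to_genes first")
    if query not in table.columns:
        raise KeyError(f"query {query!r} not in matrix columns")
    qvec = table[query].to_numpy()
    if qvec.min() == qvec.max():
        raise ValueError(f"query {query!r} is constant across cells; correlation undefined")
    others = table.drop(columns=[query])
    r = binary_pearson(qvec, others.to_numpy())
    corr = pd.Series(r, index=others.columns).dropna()
    hits = corr[corr > threshold]
    hits = hits.iloc[
        np.lexsort((hits.index.to_numpy(), -hits.to_numpy()))
    ]
    return CoaccessResult(query=query, correlations=corr, hits=hits, threshold=threshold)
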