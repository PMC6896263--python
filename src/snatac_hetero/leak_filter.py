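"""Cross-well contamination removal and chip-level QC diagnostics.

Clean-up runs in two stages, in this order:

1. ``dedup_within_well`` — collapse PCR duplicates (and optionally mutant
   amplicons within a Hamming radius) inside each well independently;
2. ``purge_cross_well`` — remove every read whose exact sequence occurs in
   two or more wells, from *all* wells carrying it.  No donor is inferred:
   a sequence seen twice across the chip is treated as contamination
   everywhere.

``leakage_diagnostics`` quantifies the chip geometry of the contamination:
the shared-sequence fraction of a well pair is |shared| / min(|a|, |b|)
(so a small, heavily contaminated well registers strongly), and row/column
enrichment compares same-row and same-column pairs against pairs sharing
neither coordinate.  ``tss_profile`` gives the standard signal-quality
check: the fraction of reads whose midpoint lies within +-2 kb of a TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .readstore import ChipReadStore, well_id


@dataclass
class LeakageReport:
    """Pairwise shared-sequence statistics plus purge accounting.

    ``pairwise_shared`` is a symmetric DataFrame over occupied wells;
    ``row_enrichment``/``col_enrichment`` are ratios of the mean shared
    fraction among same-row (same-column) pairs to the mean among pairs
    sharing neither row nor column; 0/0 is reported as 1 (no structure).
    ``removed_count``/``removed_fraction`` are zero until a purge fills
    them in; ``removed_read_ids`` and ``removed_sequences`` support
    validation against simulation ground truth.
    """

    pairwise_shared: pd.DataFrame
    row_enrichment: float
    col_enrichment: float
    mean_shared: float
    removed_count: int = 0
    removed_fraction: float = 0.0
    removed_read_ids: frozenset = field(default_factory=frozenset)
    removed_sequences: frozenset = field(default_factory=frozenset)

    def to_dict(self) -> dict:
        return {
            "row_enrichment": self.row_enrichment,
            "col_enrichment": self.col_enrichment,
            "mean_shared": self.mean_shared,
            "removed_count": self.removed_count,
            "removed_fraction": self.removed_fraction,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def _hamming_groups(seqs: list[str], max_substitutions: int) -> list[list[int]]:
    """Connected components of equal-length sequences under Hamming <= k."""
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    parent = list(range(len(seqs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for idx in by_len.values():
        if len(idx) < 2:
            continue
        arr = np.frombuffer("".join(seqs[i] for i in idx).encode("ascii"), dtype=np.uint8)
        arr = arr.reshape(len(idx), -1)
        dists = squareform(pdist(arr, metric="hamming")) * arr.shape[1]
        close = np.argwhere(np.triu(dists <= max_substitutions + 0.5, k=1))
        for a, b in close:
            ra, rb = find(idx[a]), find(idx[b])
            if ra != rb:
                parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for i in range(len(seqs)):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def dedup_within_well(store: ChipReadStore, max_substitutions: int = 0) -> ChipReadStore:
    """Collapse duplicate reads inside each well independently.

    With ``max_substitutions=0`` only exact sequence copies collapse.  With
    k > 0, reads of equal length within Hamming distance k are grouped
    (transitively) and one representative survives: the lexicographically
    smallest sequence, ties broken by smallest read id.  Cross-well copies
    are untouched here; that is the purge's job.
    """
    out = ChipReadStore.empty(store.n_rows, store.n_cols)
    for coord in store.coords():
        df = store.wells[coord]
        if len(df) == 0:
            continue
        if max_substitutions == 0:
            kept = (
                df.sort_values(["sequence", "read_id"], kind="stable")
                .drop_duplicates("sequence")
                .sort_index()
            )
        else:
            seqs = list(df["sequence"])
            ids = list(df["read_id"])
            keep_rows = []
            for group in _hamming_groups(seqs, max_substitutions):
                keep_rows.append(min(group, key=lambda i: (seqs[i], ids[i])))
            kept = df.iloc[sorted(keep_rows)]
        out.wells[coord] = kept.reset_index(drop=True)
    return out


def leakage_diagnostics(store: ChipReadStore) -> LeakageReport:
    """Shared-sequence fractions over all occupied well pairs.

    Pair fraction = |sequences in both wells| / min(|a|, |b|); wells with
    zero reads are excluded.  Row (column) enrichment is the mean fraction
    among same-row (same-column) pairs divided by the mean among pairs
    sharing neither; an undefined 0/0 ratio is reported as 1.
    """
    occupied = [coord for coord in store.coords() if len(store.wells[coord]) > 0]
    seq_sets = {coord: store.sequences(coord) for coord in occupied}
    labels = [well_id(*coord) for coord in occupied]
    n = len(occupied)
    shared = np.zeros((n, n))
    row_vals, col_vals, other_vals = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = occupied[i], occupied[j]
            frac = len(seq_sets[a] & seq_sets[b]) / min(len(seq_sets[a]), len(seq_sets[b]))
            shared[i, j] = shared[j, i] = frac
            if a[0] == b[0]:
                row_vals.append(frac)
            elif a[1] == b[1]:
                col_vals.append(frac)
            else:
                other_vals.append(frac)

    def _ratio(vals: list[float], base: list[float]) -> float:
        m = float(np.mean(vals)) if vals else 0.0
        b = float(np.mean(base)) if base else 0.0
        if b == 0.0:
            return 1.0 if m == 0.0 else float("inf")
        return m / b

    all_vals = row_vals + col_vals + other_vals
    return LeakageReport(
        pairwise_shared=pd.DataFrame(shared, index=labels, columns=labels),
        row_enrichment=_ratio(row_vals, other_vals),
        col_enrichment=_ratio(col_vals, other_vals),
        mean_shared=float(np.mean(all_vals)) if all_vals else 0.0,
    )


def purge_cross_well(store: ChipReadStore) -> tuple[ChipReadStore, LeakageReport]:
    """Remove every read whose exact sequence occurs in >= 2 distinct wells.

    The read is removed from all wells carrying the sequence, so surviving
    sequences are unique to one well.  The returned report carries the
    pre-purge pairwise statistics plus the removal accounting (fraction of
    pre-purge reads removed).  Expects within-well deduplication to have
    run already; idempotent either way.
    """
    report = leakage_diagnostics(store)
    wells_of_seq: dict[str, set] = {}
    for coord in store.coords():
        for seq in store.sequences(coord):
            wells_of_seq.setdefault(seq, set()).add(coord)
    contaminated = {seq for seq, ws in wells_of_seq.items() if len(ws) >= 2}

    out = ChipReadStore.empty(store.n_rows, store.n_cols)
    removed_ids: list[str] = []
    total = store.n_reads()
    for coord in store.coords():
        df = store.wells[coord]
        if len(df) == 0:
            continue
        bad = df["sequence"].isin(contaminated)
        removed_ids.extend(df.loc[bad, "read_id"])
        out.wells[coord] = df.loc[~bad].reset_index(drop=True)
    report.removed_count = len(removed_ids)
    report.removed_fraction = len(removed_ids) / total if total else 0.0
    report.removed_read_ids = frozenset(removed_ids)
    report.removed_sequences = frozenset(contaminated)
    return out, report


def tss_profile(
    store: ChipReadStore,
    tss_table: pd.DataFrame,
    window: int = 2000,
    hist_range: int = 5000,
    n_bins: int = 100,
) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Distance of read midpoints to the nearest TSS, and the +-2 kb fraction.

    Distance is signed by the strand of the nearest TSS (downstream
    positive).  Reads on chromosomes absent from the annotation count in
    the denominator with infinite distance.  Returns the histogram
    (counts, bin edges over +-``hist_range``) and the fraction of reads
    with |distance| <= ``window``.
    """
    if len(tss_table) == 0:
        raise ValueError("empty TSS table")
    reads = store.all_reads()
    reads = reads[reads["chrom"] != "."]
    if len(reads) == 0:
        raise ValueError("store carries no placed reads")
    dists = np.full(len(reads), np.inf)
    mids = ((reads["start"].to_numpy() + reads["end"].to_numpy()) // 2).astype(float)
    chroms = reads["chrom"].to_numpy()
    for chrom, ann in tss_table.groupby("chrom"):
        on = chroms == chrom
        if not on.any():
            continue
        ann = ann.sort_values("tss", kind="stable")
        tss = ann["tss"].to_numpy(dtype=float)
        strand = ann["strand"].to_numpy()
        pos = mids[on]
        right = np.clip(np.searchsorted(tss, pos), 0, len(tss) - 1)
        left = np.clip(right - 1, 0, len(tss) - 1)
        pick = np.where(np.abs(pos - tss[left]) <= np.abs(pos - tss[right]), left, right)
        signed = pos - tss[pick]
        signed[strand[pick] == "-"] *= -1
        dists[on] = signed
    finite = dists[np.isfinite(dists)]
    hist = np.histogram(finite, bins=n_bins, range=(-hist_range, hist_range))
    fraction = float(np.sum(np.abs(dists) <= window) / len(dists))
    return hist, fraction
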