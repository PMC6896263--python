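"""Arm-level copy-number inference from ATAC coverage.

Chromosomes are tiled into large overlapping windows; per-cell mean read
depth in each window is normalized against GC-matched background windows:

    CovNorm(w0) = mean_i  log( (cov(w0) + 1) / (cov(w_i) + 1) )

over the ``n_background`` windows whose GC content is closest to w0's,
never drawn from w0 itself, masked windows, or excluded arms (the arms
being tested for loss, e.g. 1p/19q).  Under a hemizygous deletion coverage
halves, so the arm-mean CovNorm approaches -ln 2 ~ -0.693 once depth is
well above the +1 pseudocount; arm loss is called below a fixed threshold.

Logarithms are natural by default (``log_base`` is configurable); window
size, overlap and the background count default to 10 Mb / 2 Mb / 100.
Segmentation and focal events are out of scope: this is a whole-arm caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .readstore import ChipReadStore, well_id

GenomeModel = list[tuple[str, int, int]]  # (chromosome, length, arm boundary)

WINDOW_COLUMNS = ["chrom", "start", "end", "arm", "gc"]


def arm_name(chrom: str, is_p: bool) -> str:
    return f"{chrom}{'p' if is_p else 'q'}"


def tile_windows(
    genome_model: GenomeModel,
    window_bp: int = 10_000_000,
    overlap_bp: int = 2_000_000,
) -> pd.DataFrame:
    """Tile each chromosome into overlapping windows.

    Step = window - overlap.  A final partial window is retained only if it
    covers at least half a window; a chromosome shorter than one window
    becomes a single whole-chromosome window.  Windows are labelled with the
    chromosome arm containing their midpoint.  The ``gc`` column is NaN
    until GC content is attached (from a reference table or a simulator).
    """
    if not window_bp > overlap_bp >= 0:
        raise ValueError(f"need window_bp > overlap_bp >= 0, got {window_bp}, {overlap_bp}")
    step = window_bp - overlap_bp
    rows = []
    for chrom, length, boundary in genome_model:
        if length < window_bp:
            spans = [(0, length)]
        else:
            spans = []
            start = 0
            while start < length:
                end = min(start + window_bp, length)
                if end - start >= window_bp / 2:
                    spans.append((start, end))
                start += step
        for start, end in spans:
            mid = (start + end) // 2
            rows.append((chrom, start, end, arm_name(chrom, mid < boundary), np.nan))
    df = pd.DataFrame(rows, columns=WINDOW_COLUMNS)
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


@dataclass
class CoverageWindows:
    """Per-cell mean depth over tiled genomic windows.

    ``coverage[i, j]`` is cell i's mean per-base depth in window j
    (total overlapping read-bases / window length).  ``mask`` marks windows
    excluded from all statistics (telomeric/centromeric/low-mapping).
    """

    windows: pd.DataFrame  # WINDOW_COLUMNS
    cells: list[str]
    coverage: np.ndarray  # (n_cells, n_windows), float
    mask: np.ndarray = field(default=None)  # bool per window

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.coverage.shape != (len(self.cells), len(self.windows)):
            raise ValueError("coverage shape does not match cells x windows")
        if (self.coverage < 0).any():
            raise ValueError("negative coverage")
        if self.mask is None:
            self.mask = np.zeros(len(self.windows), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    def to_tsv(self, path) -> None:
        out = self.windows.copy()
        out["masked"] = self.mask
        for i, cell in enumerate(self.cells):
            out[cell] = self.coverage[i]
        out.to_csv(path, sep="\t", index=False)


def window_coverage(store: ChipReadStore, windows: pd.DataFrame) -> CoverageWindows:
    """Mean per-base depth of each well's reads in each window.

    A read contributes only the bases that fall inside the window, so reads
    straddling a boundary are counted fractionally on each side.  Only
    occupied wells become cells.
    """
    reads = store.all_reads()
    reads = reads[reads["chrom"] != "."]
    coords = sorted({(r, c) for r, c in zip(reads["row"], reads["col"])})
    cells = [well_id(r, c) for r, c in coords]
    cell_index = {coord: i for i, coord in enumerate(coords)}
    cov = np.zeros((len(cells), len(windows)))
    if len(reads):
        cell_of_read = np.array([cell_index[(r, c)] for r, c in zip(reads["row"], reads["col"])])
        starts = reads["start"].to_numpy()
        ends = reads["end"].to_numpy()
        chroms = reads["chrom"].to_numpy()
        for j, (w_chrom, w_start, w_end) in enumerate(
            zip(windows["chrom"], windows["start"], windows["end"])
        ):
            on = chroms == w_chrom
            if not on.any():
                continue
            overlap = np.minimum(ends[on], w_end) - np.maximum(starts[on], w_start)
            overlap = np.clip(overlap, 0, None)
            cov[:, j] += np.bincount(
                cell_of_read[on], weights=overlap, minlength=len(cells)
            ) / (w_end - w_start)
    return CoverageWindows(windows=windows, cells=cells, coverage=cov)


def match_gc_background(
    windows: pd.DataFrame,
    target: int,
    n_background: int = 100,
    excluded_arms: set[str] | frozenset[str] = frozenset(),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of the background windows GC-matched to window ``target``.

    Eligible windows are unmasked, off the excluded arms, and distinct from
    the target; the ``n_background`` with smallest |gc - gc(target)| are
    returned, ties broken by genomic order.  If fewer are eligible, all of
    them are returned with a warning.
    """
    gc = windows["gc"].to_numpy(dtype=float)
    if np.isnan(gc[target]):
        raise ValueError("target window has no GC content assigned")
    eligible = ~windows["arm"].isin(excluded_arms).to_numpy()
    eligible &= ~np.isnan(gc)
    if mask is not None:
        eligible &= ~np.asarray(mask, dtype=bool)
    eligible[target] = False
    idx = np.flatnonzero(eligible)
    if len(idx) < n_background:
        warnings.warn(
            f"only {len(idx)} eligible background windows (requested {n_background})",
            stacklevel=2,
        )
    # stable sort keeps genomic order among GC ties
    order = np.argsort(np.abs(gc[idx] - gc[target]), kind="stable")
    return idx[order[:n_background]]


@dataclass
class CovNormTrack:
    """GC-normalized log-coverage per cell and window, with its background map."""

    windows: pd.DataFrame
    cells: list[str]
    normalized: np.ndarray  # (n_cells, n_windows); NaN on masked windows
    background_map: dict[int, np.ndarray]

    def arm_mean(self, arm: str) -> np.ndarray:
        """Per-cell mean CovNorm over the arm's unmasked windows."""
        on_arm = (self.windows["arm"] == arm).to_numpy()
        cols = np.flatnonzero(on_arm & ~np.isnan(self.normalized).all(axis=0))
        if cols.size == 0:
            raise ValueError(f"no unmasked windows on arm {arm!r}")
        return np.nanmean(self.normalized[:, cols], axis=1)

    def to_tsv(self, path) -> None:
        out = self.windows.copy()
        for i, cell in enumerate(self.cells):
            out[cell] = self.normalized[i]
        out.to_csv(path, sep="\t", index=False)


def covnorm(
    cov_windows: CoverageWindows,
    n_background: int = 100,
    excluded_arms: set[str] | frozenset[str] = frozenset(),
    background_map: dict[int, np.ndarray] | None = None,
    log_base: float | None = None,
) -> CovNormTrack:
    """Normalize each window's coverage against its GC-matched background.

    CovNorm(w0) = mean_i log((cov(w0)+1)/(cov(w_i)+1)) per cell, natural log
    unless ``log_base`` is given.  Masked windows emit NaN.
    """
    windows, cov, mask = cov_windows.windows, cov_windows.coverage, cov_windows.mask
    if background_map is None:
        background_map = {
            j: match_gc_background(windows, j, n_background, excluded_arms, mask)
            for j in range(len(windows))
            if not mask[j]
        }
    logc = np.log1p(cov)  # log(cov + 1)
    norm = np.full_like(cov, np.nan)
    for j, bg in background_map.items():
        if len(bg) == 0:
            continue
        norm[:, j] = logc[:, j] - logc[:, bg].mean(axis=1)
    if log_base is not None:
        norm = norm / np.log(log_base)
    return CovNormTrack(
        windows=windows, cells=cov_windows.cells, normalized=norm, background_map=background_map
    )


def call_arm_loss(track: CovNormTrack, arm: str, threshold: float = -0.3) -> np.ndarray:
    """Boolean per cell: arm-mean CovNorm below ``threshold`` (hemizygous loss).

    Raises if the arm has no unmasked windows (no call can be made).
    """
    return track.arm_mean(arm) < threshold
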