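"""Binary matrix construction, the filter cascade, and gene collapsing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from snatac_hetero import (
    AccessibilityMatrix,
    EmptyMatrixError,
    PeakSet,
    collapse_to_genes,
    filter_cascade,
    open_promoter_fraction,
    overlap_with_reference,
)
from snatac_hetero.accessibility import assign_peaks_to_genes


def _matrix(values: np.ndarray, cells=None, peaks=None) -> AccessibilityMatrix:
    cells = cells or [f"c{i}" for i in range(values.shape[0])]
    peaks = peaks or [f"p{i}" for i in range(values.shape[1])]
    ps = PeakSet.from_intervals(
        [("chr1", 1000 * i, 1000 * i + 500) for i in range(values.shape[1])], names=peaks
    )
    return AccessibilityMatrix(values=pd.DataFrame(values, index=cells, columns=peaks), peaks=ps)


# ------------------------------------------------------- overlap

def test_overlap_at_exactly_min_bases_is_positive():
    ref = PeakSet.from_intervals([("c", 150, 300)], names=["p"])
    m = overlap_with_reference({"x": PeakSet.from_intervals([("c", 100, 200)])}, ref, 50)
    assert m.values.loc["x", "p"] == 1


def test_overlap_one_base_short_is_negative():
    ref = PeakSet.from_intervals([("c", 150, 300)], names=["p"])
    m = overlap_with_reference({"x": PeakSet.from_intervals([("c", 100, 199)])}, ref, 50)
    assert m.values.loc["x", "p"] == 0


def test_identical_peak_sets_light_the_diagonal():
    intervals = [("c", 1000 * i, 1000 * i + 200) for i in range(10)]
    ref = PeakSet.from_intervals(intervals)
    m = overlap_with_reference({"x": PeakSet.from_intervals(intervals)}, ref, 50)
    assert m.values.to_numpy().sum() == 10
    assert (m.values.to_numpy() == 1).all()


def test_overlap_matches_brute_force_intersection():
    rng = np.random.default_rng(0)
    ref_iv = sorted(
        ("c", int(s), int(s) + int(w))
        for s, w in zip(rng.integers(0, 5000, 10), rng.integers(60, 400, 10))
    )
    cell_iv = sorted(
        ("c", int(s), int(s) + int(w))
        for s, w in zip(rng.integers(0, 5000, 15), rng.integers(60, 400, 15))
    )
    ref = PeakSet.from_intervals(ref_iv, names=[f"p{i}" for i in range(10)])
    m = overlap_with_reference({"x": PeakSet.from_intervals(cell_iv)}, ref, 50)
    for name, (_, rs, re_) in zip(ref.names, ref.intervals()):
        expected = int(
            any(max(0, min(ce, re_) - max(cs, rs)) >= 50 for _, cs, ce in cell_iv)
        )
        assert m.values.loc["x", name] == expected


def test_unknown_chromosome_warns_and_is_ignored():
    ref = PeakSet.from_intervals([("c", 0, 100)], names=["p"])
    with pytest.warns(UserWarning, match="absent from reference"):
        m = overlap_with_reference({"x": PeakSet.from_intervals([("z", 0, 100)])}, ref, 50)
    assert m.values.loc["x", "p"] == 0


def test_overlap_symmetric_under_role_swap():
    rng = np.random.default_rng(3)
    a = sorted(("c", int(s), int(s) + 150) for s in rng.integers(0, 3000, 8))
    b = sorted(("c", int(s), int(s) + 150) for s in rng.integers(0, 3000, 8))
    m_ab = overlap_with_reference({"x": PeakSet.from_intervals(a)}, PeakSet.from_intervals(b), 50)
    m_ba = overlap_with_reference({"x": PeakSet.from_intervals(b)}, PeakSet.from_intervals(a), 50)
    assert (m_ab.values.to_numpy().sum() > 0) == (m_ba.values.to_numpy().sum() > 0)


# ------------------------------------------------------- filter cascade

def _brute_force_cascade(values: pd.DataFrame, min_cells, min_peaks, max_peaks):
    """Independent oracle: re-derive the three steps by explicit recount."""
    keep_peaks = [p for p in values.columns if values[p].sum() >= min_cells]
    v = values[keep_peaks]
    keep_cells = [c for c in v.index if v.loc[c].sum() >= min_peaks]
    v = v.loc[keep_cells]
    keep_cells = [c for c in v.index if v.loc[c].sum() <= max_peaks]
    return v.loc[keep_cells]


def test_cascade_removes_sparse_peak_and_sparse_cell():
    values = np.zeros((6, 4), dtype=int)
    values[:4, 0] = 1  # peak p0: 4 positives, below min_cells=5
    values[:5, 1] = 1
    values[:, 2] = 1
    values[:5, 3] = 1  # cell c5 keeps only p2 -> 1 positive, below min_peaks=2
    m = _matrix(values)
    out = filter_cascade(m, min_cells_per_peak=5, min_peaks_per_cell=2, max_peaks_per_cell=3)
    assert "p0" not in out.values.columns
    assert "c5" not in out.values.index
    expected = _brute_force_cascade(m.values, 5, 2, 3)
    assert out.values.equals(expected.astype(np.uint8))


@pytest.mark.parametrize(
    "min_cells,min_peaks,max_peaks",
    list(itertools.product([0, 1, 3, 5], [0, 2, 4], [2, 5, 10])),
)
def test_cascade_matches_brute_force_on_random_toys(min_cells, min_peaks, max_peaks):
    rng = np.random.default_rng(min_cells * 100 + min_peaks * 10 + max_peaks)
    values = (rng.random((10, 10)) < 0.4).astype(int)
    m = _matrix(values)
    expected = _brute_force_cascade(m.values, min_cells, min_peaks, max_peaks)
    if expected.shape[0] == 0:
        with pytest.raises(EmptyMatrixError):
            filter_cascade(m, min_cells, min_peaks, max_peaks)
    else:
        out = filter_cascade(m, min_cells, min_peaks, max_peaks)
        assert out.values.equals(expected.astype(np.uint8))


def test_trivial_thresholds_are_identity():
    rng = np.random.default_rng(5)
    values = (rng.random((6, 6)) < 0.5).astype(int)
    m = _matrix(values)
    out = filter_cascade(m, 0, 0, np.inf)
    assert out.values.equals(m.values)


def test_all_cells_removed_raises():
    m = _matrix(np.zeros((3, 3), dtype=int))
    with pytest.raises(EmptyMatrixError):
        filter_cascade(m, 1, 1, 10)


def test_one_pass_keeps_peaks_orphaned_by_cell_removal():
    """Removing cells can push a peak below min_cells; the default single
    pass reports that state rather than iterating, and fixpoint mode
    converges to a matrix where every invariant holds."""
    values = np.array(
        [
            [1, 1, 0],
            [1, 1, 0],
            [1, 1, 1],
        ]
    )
    m = _matrix(values)
    # max_peaks=2 removes c2; peak p2 then has zero positives but survives
    # the single pass (it had 1 >= min_cells=1 before the cell dropped)
    out = filter_cascade(m, min_cells_per_peak=1, min_peaks_per_cell=1, max_peaks_per_cell=2)
    assert "p2" in out.values.columns
    assert out.values["p2"].sum() == 0
    fix = filter_cascade(m, 1, 1, 2, iterate=True)
    assert "p2" not in fix.values.columns
    assert (fix.values.sum(axis=0) >= 1).all()
    assert fix.values.sum(axis=1).between(1, 2).all()


def test_refiltering_filtered_output_is_noop():
    rng = np.random.default_rng(8)
    values = (rng.random((12, 8)) < 0.5).astype(int)
    out = filter_cascade(_matrix(values), 2, 2, 6, iterate=True)
    again = filter_cascade(out, 2, 2, 6)
    assert again.values.equals(out.values)


def test_percentile_reported_for_max_peaks_threshold():
    values = np.tril(np.ones((10, 10), dtype=int))  # cell i has i+1 positives
    out = filter_cascade(_matrix(values), 0, 0, 8)
    assert out.filter_report["max_peaks_percentile"] == pytest.approx(80.0)


# ------------------------------------------------------- gene collapsing

ANNOTATION = pd.DataFrame(
    {
        "gene": ["gA", "gB", "gC"],
        "chrom": ["chr1", "chr1", "chr2"],
        "tss": [250, 2250, 250],
        "strand": ["+", "-", "+"],
    }
)


def _gene_matrix():
    peaks = PeakSet.from_intervals(
        [
            ("chr1", 0, 500),  # promoter of gA
            ("chr1", 2000, 2500),  # promoter of gB
            ("chr1", 3500, 4000),  # within 2 kb of gB's TSS (gap 1251)
            ("chr1", 50_000, 50_500),  # intergenic
            ("chr2", 0, 500),  # promoter of gC
        ],
        names=[f"p{i}" for i in range(5)],
    )
    values = pd.DataFrame(
        [[0, 1, 0, 1, 0], [1, 0, 1, 0, 0], [0, 0, 0, 0, 1]],
        index=["c0", "c1", "c2"],
        columns=peaks.names,
    )
    return AccessibilityMatrix(values=values, peaks=peaks)


def test_gene_open_iff_any_member_peak_open():
    m = collapse_to_genes(_gene_matrix(), ANNOTATION)
    gv = m.gene_view
    # c0: p1 open -> gB open; p3 intergenic ignored
    assert gv.loc["c0", "gB"] == 1 and gv.loc["c0", "gA"] == 0
    # c1: p0 -> gA, p2 -> gB
    assert gv.loc["c1", "gA"] == 1 and gv.loc["c1", "gB"] == 1
    # c2: only gC
    assert list(gv.loc["c2"]) == [0, 0, 1]


def test_gene_view_matches_brute_force_or():
    m = collapse_to_genes(_gene_matrix(), ANNOTATION)
    mapping = m.peak_to_gene
    for gene in m.gene_view.columns:
        member_peaks = [p for p, g in mapping.items() if g == gene]
        expected = m.values[member_peaks].max(axis=1)
        assert (m.gene_view[gene] == expected).all()


def test_intergenic_peaks_excluded_from_gene_view():
    m = collapse_to_genes(_gene_matrix(), ANNOTATION)
    assert "p3" not in m.peak_to_gene
    assert set(m.gene_view.columns) == {"gA", "gB", "gC"}


def test_gene_column_sums_bounded_by_member_peak_sums():
    m = collapse_to_genes(_gene_matrix(), ANNOTATION)
    for gene in m.gene_view.columns:
        members = [p for p, g in m.peak_to_gene.items() if g == gene]
        assert m.gene_view[gene].sum() <= m.values[members].sum().sum()


def test_peak_assignment_prefers_nearest_tss():
    peaks = PeakSet.from_intervals([("chr1", 1000, 1400)], names=["p"])
    ann = pd.DataFrame(
        {
            "gene": ["near", "far"],
            "chrom": ["chr1", "chr1"],
            "tss": [1500, 2500],
            "strand": ["+", "+"],
        }
    )
    assert assign_peaks_to_genes(peaks, ann)["p"] == "near"


def test_annotation_missing_chromosome_warns():
    peaks = PeakSet.from_intervals([("chrZ", 0, 100)], names=["p"])
    with pytest.warns(UserWarning, match="absent from annotation"):
        mapping = assign_peaks_to_genes(peaks, ANNOTATION)
    assert mapping == {}


# ------------------------------------------------------- open promoter fraction

def _fraction_matrix(n_open: int, n_total: int):
    gv = pd.DataFrame(
        {"G": [1] * n_open + [0] * (n_total - n_open)},
        index=[f"c{i}" for i in range(n_total)],
    )
    m = _matrix(np.zeros((n_total, 1), dtype=int), cells=list(gv.index))
    m.gene_view = gv
    return m


def test_open_promoter_fraction_rounds_to_one_decimal():
    m = _fraction_matrix(101, 145)
    assert open_promoter_fraction(m, "G", list(m.gene_view.index)) == (101, 145, 69.7)
    m = _fraction_matrix(20, 191)
    assert open_promoter_fraction(m, "G", list(m.gene_view.index)) == (20, 191, 10.5)


def test_zero_positives_give_zero_percent():
    m = _fraction_matrix(0, 7)
    assert open_promoter_fraction(m, "G", list(m.gene_view.index)) == (0, 7, 0.0)


def test_empty_group_is_an_error():
    m = _fraction_matrix(1, 3)
    with pytest.raises(ValueError, match="empty"):
        open_promoter_fraction(m, "G", [])
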