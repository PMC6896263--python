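"""Window tiling, coverage, GC-matched normalization and arm-loss calls."""

import numpy as np
import pandas as pd
import pytest

from snatac_hetero import (
    CoverageWindows,
    call_arm_loss,
    covnorm,
    match_gc_background,
    simulate_window_coverage,
    tile_windows,
    window_coverage,
)

from conftest import make_store


# ------------------------------------------------------- tiling

def test_hand_tiling_26mb():
    w = tile_windows([("chrA", 26_000_000, 13_000_000)], 10_000_000, 2_000_000)
    assert list(zip(w["start"], w["end"])) == [
        (0, 10_000_000),
        (8_000_000, 18_000_000),
        (16_000_000, 26_000_000),
    ]


def test_zero_overlap_tiles_disjointly():
    w = tile_windows([("chrA", 30_000_000, 15_000_000)], 10_000_000, 0)
    assert list(zip(w["start"], w["end"])) == [
        (0, 10_000_000),
        (10_000_000, 20_000_000),
        (20_000_000, 30_000_000),
    ]


def test_short_chromosome_single_window():
    w = tile_windows([("chrA", 4_000_000, 2_000_000)], 10_000_000, 2_000_000)
    assert list(zip(w["start"], w["end"])) == [(0, 4_000_000)]


def test_small_trailing_fragment_dropped():
    # length 21 Mb: starts 0, 8, 16 -> 16-21 is 5 Mb (= half) retained;
    # length 20 Mb: trailing 16-20 is 4 Mb (< half) dropped
    w = tile_windows([("chrA", 21_000_000, 10_000_000)], 10_000_000, 2_000_000)
    assert list(w["end"])[-1] == 21_000_000
    w = tile_windows([("chrA", 20_000_000, 10_000_000)], 10_000_000, 2_000_000)
    assert list(zip(w["start"], w["end"]))[-1] == (8_000_000, 18_000_000)


def test_invalid_overlap_rejected():
    with pytest.raises(ValueError):
        tile_windows([("chrA", 10_000_000, 5_000_000)], 1_000_000, 1_000_000)


def test_arm_labels_follow_midpoint():
    w = tile_windows([("chrA", 26_000_000, 13_000_000)], 10_000_000, 2_000_000)
    assert list(w["arm"]) == ["chrAp", "chrAq", "chrAq"]


# ------------------------------------------------------- coverage

def test_single_read_mean_depth():
    store = make_store((1, 1), {(0, 0): [("r", "chrA", 5_000_000, 5_000_100, "A" * 100)]})
    w = tile_windows([("chrA", 10_000_000, 5_000_000)], 10_000_000, 0)
    cov = window_coverage(store, w)
    assert cov.coverage[0, 0] == pytest.approx(100 / 10_000_000)


def test_no_reads_zero_coverage():
    store = make_store((1, 1), {(0, 0): [("r", "chrB", 10, 60, "A" * 50)]})
    w = tile_windows([("chrA", 10_000_000, 5_000_000), ("chrB", 10_000_000, 5_000_000)], 10_000_000, 0)
    cov = window_coverage(store, w)
    assert cov.coverage[0, list(w["chrom"]).index("chrA")] == 0.0


def test_straddling_read_split_matches_per_base_count():
    """Brute-force per-base tally on a 20 bp toy genome with 10 bp windows."""
    store = make_store((1, 1), {(0, 0): [("r", "chrA", 6, 14, "A" * 8)]})
    w = pd.DataFrame(
        {"chrom": ["chrA", "chrA"], "start": [0, 10], "end": [10, 20],
         "arm": ["chrAp", "chrAq"], "gc": [0.5, 0.5]}
    )
    cov = window_coverage(store, w)
    per_base = np.zeros(20)
    per_base[6:14] += 1
    assert cov.coverage[0, 0] == pytest.approx(per_base[0:10].sum() / 10)
    assert cov.coverage[0, 1] == pytest.approx(per_base[10:20].sum() / 10)


# ------------------------------------------------------- GC matching

def _windows(gcs, arms=None):
    n = len(gcs)
    return pd.DataFrame(
        {
            "chrom": ["chrA"] * n,
            "start": np.arange(n) * 100,
            "end": (np.arange(n) + 1) * 100,
            "arm": arms or ["chrAp"] * n,
            "gc": gcs,
        }
    )


def test_identical_gc_ties_break_by_genomic_order():
    w = _windows([0.5] * 8)
    bg = match_gc_background(w, target=5, n_background=3)
    assert list(bg) == [0, 1, 2]


def test_exact_gc_match_selected_first():
    w = _windows([0.30, 0.45, 0.52, 0.60, 0.52])
    bg = match_gc_background(w, target=2, n_background=1)
    assert list(bg) == [4]


def test_matches_exhaustive_nearest_gc_search():
    rng = np.random.default_rng(4)
    gcs = rng.uniform(0.3, 0.7, 12).round(3)
    w = _windows(list(gcs))
    target, n = 3, 5
    got = match_gc_background(w, target, n)
    order = sorted(
        (i for i in range(12) if i != target), key=lambda i: (abs(gcs[i] - gcs[target]), i)
    )
    assert sorted(got) == sorted(order[:n])


def test_background_never_includes_target_mask_or_excluded_arms():
    rng = np.random.default_rng(9)
    arms = ["chrAp"] * 6 + ["chrAq"] * 6
    w = _windows(list(rng.uniform(0.3, 0.7, 12)), arms=arms)
    mask = np.zeros(12, dtype=bool)
    mask[2] = True
    for target in range(12):
        if mask[target]:
            continue
        bg = match_gc_background(w, target, 4, excluded_arms={"chrAq"}, mask=mask)
        assert target not in bg
        assert not mask[bg].any()
        assert (w.loc[bg, "arm"] != "chrAq").all()


def test_too_few_eligible_warns_and_returns_all():
    w = _windows([0.4, 0.5, 0.6])
    with pytest.warns(UserWarning, match="eligible background"):
        bg = match_gc_background(w, target=0, n_background=10)
    assert sorted(bg) == [1, 2]


# ------------------------------------------------------- CovNorm

def _covw(cov_rows, gcs=None, arms=None, mask=None):
    cov = np.atleast_2d(np.asarray(cov_rows, dtype=float))
    n = cov.shape[1]
    w = _windows(gcs or [0.5] * n, arms=arms)
    return CoverageWindows(
        windows=w, cells=[f"cell{i}" for i in range(cov.shape[0])], coverage=cov, mask=mask
    )


def test_equal_coverage_normalizes_to_zero():
    covw = _covw([[3.0] * 6])
    track = covnorm(covw, n_background=5)
    assert track.normalized[0] == pytest.approx(np.zeros(6))


def test_closed_form_log_ratio():
    # cov(w0)=4 against uniform background cov=9 -> log(5/10)
    covw = _covw([[4.0] + [9.0] * 5])
    track = covnorm(covw, n_background=5)
    assert track.normalized[0, 0] == pytest.approx(np.log(0.5), abs=1e-9)


def test_masked_windows_emit_nan_and_never_serve_as_background():
    mask = np.array([False, False, True, False, False, False])
    covw = _covw([[4.0, 9.0, 50.0, 9.0, 9.0, 9.0]], mask=mask)
    track = covnorm(covw, n_background=5)
    assert np.isnan(track.normalized[0, 2])
    for j, bg in track.background_map.items():
        assert 2 not in bg
        assert j not in bg


def test_scaling_invariance_in_large_count_limit():
    """The +1 pseudocount breaks exact scale invariance; with counts >> 1
    the ratio normalization becomes scale-free."""
    base = np.linspace(1e5, 2e5, 8)
    t1 = covnorm(_covw([base]), n_background=7).normalized
    t2 = covnorm(_covw([base * 10]), n_background=7).normalized
    assert np.nanmax(np.abs(t1 - t2)) < 1e-4
    # at small counts the pseudocount visibly shifts the values
    s1 = covnorm(_covw([base / 1e5]), n_background=7).normalized
    s2 = covnorm(_covw([base * 10 / 1e5]), n_background=7).normalized
    assert np.nanmax(np.abs(s1 - s2)) > 0.01


def test_log_base_option_rescales():
    covw = _covw([[4.0] + [9.0] * 5])
    nat = covnorm(covw, n_background=5).normalized[0, 0]
    two = covnorm(covw, n_background=5, log_base=2).normalized[0, 0]
    assert two == pytest.approx(nat / np.log(2))


# ------------------------------------------------------- arm calls

def test_all_zero_track_calls_no_losses():
    covw = _covw([[2.0] * 6])
    track = covnorm(covw, n_background=5)
    assert not call_arm_loss(track, "chrAp").any()


def test_infinite_threshold_calls_everything():
    covw = _covw([[2.0] * 6])
    track = covnorm(covw, n_background=5)
    assert call_arm_loss(track, "chrAp", threshold=np.inf).all()


def test_fully_masked_arm_is_a_no_call():
    arms = ["chrAp"] * 3 + ["chrAq"] * 3
    mask = np.array([True, True, True, False, False, False])
    covw = _covw([[2.0] * 6], arms=arms, mask=mask)
    track = covnorm(covw, n_background=2)
    with pytest.raises(ValueError, match="chrAp"):
        call_arm_loss(track, "chrAp")


def test_hemizygous_loss_recovered_from_simulated_coverage():
    """Halved coverage on one arm pulls its CovNorm to ~ -ln 2 and the
    default threshold separates deleted from diploid cells."""
    genome = [(f"chr{i}", 8000, 4000) for i in range(1, 8)]
    windows = tile_windows(genome, 500, 100)
    deleted = [{"chr1p"}] * 30 + [set()] * 30
    covw, _ = simulate_window_coverage(windows, 60, 40_000, deleted, rng_seed=3)
    track = covnorm(covw, n_background=100, excluded_arms={"chr1p"})
    arm_means = track.arm_mean("chr1p")
    assert arm_means[:30].mean() == pytest.approx(np.log(0.5), abs=0.1)
    assert arm_means[30:].mean() == pytest.approx(0.0, abs=0.1)
    loss = call_arm_loss(track, "chr1p", threshold=-0.3)
    assert loss[:30].all() and not loss[30:].any()
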