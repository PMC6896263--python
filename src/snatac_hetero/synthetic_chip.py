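"""Simulated microfluidic snATAC-seq chip with known ground truth.

The generator emulates the failure modes the clean-up pipeline exists for,
on a rows x columns capture chip:

* empty wells and doublet wells (two nuclei whose reads merge, inflating
  the well's peak count);
* subtype-specific peak accessibility (each subtype has its own per-peak
  open probability, so marker scoring has real signal to find);
* PCR duplicates — exact sequence copies within a well, a fraction of
  which carry post-amplification substitutions ("mutant amplicons");
* cross-well leakage — exact sequences copied from donor wells into other
  wells, preferentially along the donor's chip row (weight 3) and, less
  often, its column (weight 1);
* hemizygous arm-level deletions (a 1p/19q analog) expressed as halved
  read sampling on the deleted arm.

Reads are fixed-length random sequences with coordinates drawn inside open
peaks plus a uniform background; at 4^50 possible 50-mers, distinct cells
essentially never collide by chance, so shared sequences mean leakage.
Everything is reproducible from ``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import CoverageWindows, GenomeModel, arm_name
from .peaks import PeakSet
from .readstore import ChipReadStore, well_id

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Raised for an internally inconsistent chip configuration."""


@dataclass
class ChipConfig:
    """Parameters of one simulated chip experiment.

    ``open_prob_by_subtype`` has shape (n_subtypes, n_peaks);
    ``subtype_fractions`` must sum to 1.  ``deleted_arms_by_subtype`` lists
    (subtype, arm) pairs, arms named like ``chr1p`` against ``genome_model``
    entries of (chromosome, length, arm boundary).
    """

    n_rows: int
    n_cols: int
    n_peaks: int
    subtypes: list[str]
    subtype_fractions: np.ndarray
    open_prob_by_subtype: np.ndarray
    genome_model: GenomeModel
    empty_well_rate: float = 0.1
    doublet_rate: float = 0.08
    reads_per_open_peak: int = 5
    background_reads_per_cell: int = 200
    pcr_dup_rate: float = 0.1
    pcr_substitution_rate: float = 0.0
    leak_donor_fraction: float = 0.25
    leak_targets_per_donor: int = 6
    leak_reads_per_target: int = 25
    deleted_arms_by_subtype: list[tuple[str, str]] = field(default_factory=list)
    peak_width: int = 500
    read_len: int = 50
    n_genes: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.subtype_fractions = np.asarray(self.subtype_fractions, dtype=float)
        self.open_prob_by_subtype = np.asarray(self.open_prob_by_subtype, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigError("chip needs at least one well")
        if abs(self.subtype_fractions.sum() - 1.0) > 1e-9:
            raise ConfigError("subtype_fractions must sum to 1")
        if self.open_prob_by_subtype.shape != (len(self.subtypes), self.n_peaks):
            raise ConfigError(
                f"open_prob_by_subtype shape {self.open_prob_by_subtype.shape} "
                f"!= (n_subtypes={len(self.subtypes)}, n_peaks={self.n_peaks})"
            )
        for p in (
            self.empty_well_rate,
            self.doublet_rate,
            self.pcr_dup_rate,
            self.pcr_substitution_rate,
            self.leak_donor_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if ((self.open_prob_by_subtype < 0) | (self.open_prob_by_subtype > 1)).any():
            raise ConfigError("open probabilities outside [0, 1]")
        valid_arms = {arm_name(c, p) for c, _, _ in self.genome_model for p in (True, False)}
        for subtype, arm in self.deleted_arms_by_subtype:
            if subtype not in self.subtypes:
                raise ConfigError(f"unknown subtype in deleted_arms_by_subtype: {subtype}")
            if arm not in valid_arms:
                raise ConfigError(f"arm {arm} not named in genome_model")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated chip, for validating every later stage.

    ``cell_subtype`` maps well id -> "empty", a subtype name, or
    "doublet:<a>+<b>".  ``leaked`` records every injected read (id, sequence,
    source read id, donor and recipient wells); ``leaked_sequences`` is the
    set of sequences involved.  ``deleted_arms`` maps well id -> arms whose
    coverage was halved.  The simulated reference peaks and TSS annotation
    travel with the truth so downstream stages are runnable without any
    external genome.
    """

    cell_subtype: dict[str, str]
    open_peaks_truth: dict[str, list[int]]
    leaked: list[dict]
    deleted_arms: dict[str, list[str]]
    reference_peaks: PeakSet
    tss_annotation: pd.DataFrame

    @property
    def leaked_read_ids(self) -> set[str]:
        return {rec["read_id"] for rec in self.leaked}

    @property
    def leak_source_read_ids(self) -> set[str]:
        return {rec["source_read_id"] for rec in self.leaked}

    @property
    def leaked_sequences(self) -> set[str]:
        return {rec["sequence"] for rec in self.leaked}

    def doublet_wells(self) -> set[str]:
        return {w for w, s in self.cell_subtype.items() if s.startswith("doublet:")}

    def occupied_wells(self) -> list[str]:
        return sorted(w for w, s in self.cell_subtype.items() if s != "empty")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cell_subtype": self.cell_subtype,
            "open_peaks_truth": self.open_peaks_truth,
            "leaked": self.leaked,
            "deleted_arms": self.deleted_arms,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _random_sequences(rng: np.random.Generator, n: int, length: int) -> list[str]:
    if n == 0:
        return []
    codes = rng.integers(0, 4, size=(n, length))
    return [bytes(row).decode("ascii") for row in _BASES[codes]]


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        arr[hit] = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
    return bytes(arr).decode("ascii")


def _make_genome_layout(config: ChipConfig, rng: np.random.Generator):
    """Place reference peaks and gene TSSs on the model genome.

    Peaks are fixed-width, non-overlapping, spread over chromosomes in
    proportion to length.  Half the peaks (by default) host a gene TSS at
    their midpoint, so promoter assignment and gene collapsing have targets.
    """
    lengths = np.array([ln for _, ln, _ in config.genome_model], dtype=float)
    per_chrom = np.floor(lengths / lengths.sum() * config.n_peaks).astype(int)
    while per_chrom.sum() < config.n_peaks:
        per_chrom[int(np.argmax(lengths - per_chrom * config.peak_width))] += 1
    rows = []
    for (chrom, length, _), k in zip(config.genome_model, per_chrom):
        n_slots = length // (2 * config.peak_width)
        if k > n_slots:
            raise ConfigError(f"{chrom} too short for {k} non-overlapping peaks")
        slots = np.sort(rng.choice(n_slots, size=k, replace=False))
        for s in slots:
            start = int(s) * 2 * config.peak_width
            rows.append((chrom, start, start + config.peak_width))
    peaks = PeakSet.from_intervals(rows, names=[f"peak{i:04d}" for i in range(len(rows))])
    n_genes = config.n_genes if config.n_genes is not None else config.n_peaks // 2
    gene_peaks = np.sort(rng.choice(config.n_peaks, size=min(n_genes, config.n_peaks), replace=False))
    ann = pd.DataFrame(
        {
            "gene": [f"G{i:04d}" for i in range(len(gene_peaks))],
            "chrom": [peaks.df.loc[p, "chrom"] for p in gene_peaks],
            "tss": [
                int((peaks.df.loc[p, "start"] + peaks.df.loc[p, "end"]) // 2) for p in gene_peaks
            ],
            "strand": rng.choice(["+", "-"], size=len(gene_peaks)),
        }
    )
    return peaks, ann


def _arm_of(genome_model: GenomeModel, chrom: str, pos: int) -> str:
    for c, _, boundary in genome_model:
        if c == chrom:
            return arm_name(chrom, pos < boundary)
    raise KeyError(chrom)


def simulate_chip(config: ChipConfig):
    """Run one chip experiment; returns (store, per-cell peaks, truth).

    Wells are visited in row-major order with a single seeded generator, so
    repeated calls with the same config produce byte-identical stores.
    Per-cell peak sets are the true open reference peaks of each occupied
    well (the union for doublets), standing in for upstream peak calling.
    """
    rng = np.random.default_rng(config.rng_seed)
    ref_peaks, annotation = _make_genome_layout(config, rng)
    ref_intervals = ref_peaks.intervals()
    peak_arm = [_arm_of(config.genome_model, c, (s + e) // 2) for c, s, e in ref_intervals]
    deleted_by_subtype = {}
    for subtype, arm in config.deleted_arms_by_subtype:
        deleted_by_subtype.setdefault(subtype, set()).add(arm)

    store = ChipReadStore.empty(config.n_rows, config.n_cols)
    cell_peaks: dict[tuple[int, int], PeakSet] = {}
    cell_subtype: dict[str, str] = {}
    open_truth: dict[str, list[int]] = {}
    deleted_arms: dict[str, list[str]] = {}
    arm_spans = []  # (chrom, arm, start, end) for background placement
    for chrom, length, boundary in config.genome_model:
        arm_spans.append((chrom, arm_name(chrom, True), 0, boundary))
        arm_spans.append((chrom, arm_name(chrom, False), boundary, length))

    for r in range(config.n_rows):
        for c in range(config.n_cols):
            wid = well_id(r, c)
            if rng.random() < config.empty_well_rate:
                cell_subtype[wid] = "empty"
                continue
            n_nuclei = 2 if rng.random() < config.doublet_rate else 1
            subs = [
                config.subtypes[i]
                for i in rng.choice(
                    len(config.subtypes), size=n_nuclei, p=config.subtype_fractions
                )
            ]
            cell_subtype[wid] = subs[0] if n_nuclei == 1 else "doublet:" + "+".join(subs)
            well_deleted = sorted(set().union(*(deleted_by_subtype.get(s, set()) for s in subs)))
            deleted_arms[wid] = well_deleted

            open_union: set[int] = set()
            rec_chrom: list[str] = []
            rec_start: list[int] = []
            for subtype in subs:
                probs = config.open_prob_by_subtype[config.subtypes.index(subtype)]
                open_idx = np.flatnonzero(rng.random(config.n_peaks) < probs)
                open_union.update(int(i) for i in open_idx)
                halved = deleted_by_subtype.get(subtype, set())
                counts = rng.poisson(config.reads_per_open_peak, size=len(open_idx))
                for p, k in zip(open_idx, counts):
                    if peak_arm[p] in halved:
                        k = rng.binomial(k, 0.5)
                    if k == 0:
                        continue
                    chrom, ps, pe = ref_intervals[p]
                    hi = max(ps + 1, pe - config.read_len)
                    rec_chrom.extend([chrom] * int(k))
                    rec_start.extend(int(x) for x in rng.integers(ps, hi, size=int(k)))
                # uniform background, halved on deleted arms
                weights = np.array(
                    [(e - s) * (0.5 if arm in halved else 1.0) for _, arm, s, e in arm_spans]
                )
                n_bg = rng.poisson(config.background_reads_per_cell)
                picks = rng.choice(len(arm_spans), size=n_bg, p=weights / weights.sum())
                for a in picks:
                    chrom, _, s, e = arm_spans[a]
                    rec_chrom.append(chrom)
                    rec_start.append(int(rng.integers(s, max(s + 1, e - config.read_len))))

            seqs = _random_sequences(rng, len(rec_chrom), config.read_len)
            ids = [f"{wid}:{i:06d}" for i in range(len(seqs))]
            # PCR duplicates: exact copies, some carrying substitutions
            dup = rng.random(len(seqs)) < config.pcr_dup_rate
            for i in np.flatnonzero(dup):
                ids.append(f"{wid}:{int(i):06d}:dup")
                rec_chrom.append(rec_chrom[i])
                rec_start.append(rec_start[i])
                seqs.append(_mutate(rng, seqs[i], config.pcr_substitution_rate))
            store.wells[(r, c)] = pd.DataFrame(
                {
                    "read_id": ids,
                    "chrom": rec_chrom,
                    "start": rec_start,
                    "end": [s + config.read_len for s in rec_start],
                    "sequence": seqs,
                }
            )
            open_sorted = sorted(open_union)
            open_truth[wid] = open_sorted
            sub_df = ref_peaks.df.iloc[open_sorted]
            cell_peaks[(r, c)] = PeakSet(sub_df.copy()) if len(sub_df) else PeakSet(
                ref_peaks.df.iloc[:0].copy()
            )

    # cross-well leakage: donors spill exact sequences along their row (3:1 vs column)
    leaked: list[dict] = []
    occupied = [coord for coord in store.coords() if len(store.wells[coord]) > 0]
    for r, c in occupied:
        if rng.random() >= config.leak_donor_fraction:
            continue
        donor = store.wells[(r, c)]
        wid = well_id(r, c)
        cands = [((r, cc), 3.0) for cc in range(config.n_cols) if cc != c]
        cands += [((rr, c), 1.0) for rr in range(config.n_rows) if rr != r]
        if not cands or len(donor) == 0:
            continue
        weights = np.array([w for _, w in cands])
        k = min(config.leak_targets_per_donor, len(cands))
        chosen = rng.choice(len(cands), size=k, replace=False, p=weights / weights.sum())
        for t in sorted(int(x) for x in chosen):
            target_coord = cands[t][0]
            twid = well_id(*target_coord)
            m = min(config.leak_reads_per_target, len(donor))
            if m == 0:
                continue
            src = sorted(int(x) for x in rng.choice(len(donor), size=m, replace=False))
            rows = donor.iloc[src]
            new_ids = [f"L:{wid}>{twid}:{i:04d}" for i in range(m)]
            injected = rows.assign(read_id=new_ids)
            store.wells[target_coord] = pd.concat(
                [store.wells[target_coord], injected], ignore_index=True
            )
            for nid, (_, row) in zip(new_ids, rows.iterrows()):
                leaked.append(
                    {
                        "read_id": nid,
                        "source_read_id": row["read_id"],
                        "donor": wid,
                        "recipient": twid,
                        "sequence": row["sequence"],
                    }
                )

    truth = SyntheticTruth(
        cell_subtype=cell_subtype,
        open_peaks_truth=open_truth,
        leaked=leaked,
        deleted_arms=deleted_arms,
        reference_peaks=ref_peaks,
        tss_annotation=annotation,
    )
    return store, cell_peaks, truth


def default_config(
    n_rows: int = 8,
    n_cols: int = 8,
    n_peaks: int = 200,
    rng_seed: int = 0,
    **overrides,
) -> ChipConfig:
    """Study-shaped default chip: two glioma subtypes on a small grid.

    Subtype fractions follow the cohort's cell split (codel 191/336,
    noncodel 145/336).  Each subtype gets 10% of peaks as near-private
    markers (open probability 0.9 vs 0.05); shared peaks open at 0.25.
    The codel subtype carries hemizygous chr1p and chr19q deletions.
    """
    rng = np.random.default_rng(rng_seed + 104729)  # layout-only stream
    subtypes = ["codel", "noncodel"]
    fractions = np.array([191, 145], dtype=float)
    fractions /= fractions.sum()
    probs = np.full((2, n_peaks), 0.25)
    n_marker = max(1, n_peaks // 10)
    marker_sets = rng.choice(n_peaks, size=2 * n_marker, replace=False)
    for s, markers in enumerate((marker_sets[:n_marker], marker_sets[n_marker:])):
        probs[s, markers] = 0.9
        probs[1 - s, markers] = 0.05
    genome_model = [
        ("chr1", 2_000_000, 1_000_000),
        ("chr2", 2_000_000, 1_000_000),
        ("chr19", 2_000_000, 1_000_000),
    ]
    params = dict(
        n_rows=n_rows,
        n_cols=n_cols,
        n_peaks=n_peaks,
        subtypes=subtypes,
        subtype_fractions=fractions,
        open_prob_by_subtype=probs,
        genome_model=genome_model,
        deleted_arms_by_subtype=[("codel", "chr1p"), ("codel", "chr19q")],
        rng_seed=rng_seed,
    )
    params.update(overrides)
    return ChipConfig(**params)


def simulate_window_coverage(
    windows: pd.DataFrame,
    n_cells: int,
    reads_per_cell: int,
    deleted_arms_by_cell: list[set[str]],
    read_len: int = 50,
    gc_range: tuple[float, float] = (0.35, 0.65),
    rng_seed: int = 0,
) -> tuple[CoverageWindows, list[set[str]]]:
    """Window-level coverage counterpart of the read-record simulator.

    Reads land in windows with probability proportional to window length,
    halved on each cell's deleted arms; per-window counts are Poisson and
    converted to mean per-base depth (count * read_len / window length).
    Window GC content is drawn uniformly in ``gc_range`` (coverage is
    GC-neutral here: the GC matching step is exercised, not biased).
    Returns the coverage object plus the per-cell deleted-arm truth.
    """
    rng = np.random.default_rng(rng_seed)
    windows = windows.copy()
    windows["gc"] = rng.uniform(*gc_range, size=len(windows))
    w_len = (windows["end"] - windows["start"]).to_numpy(dtype=float)
    arms = windows["arm"].to_numpy()
    cov = np.zeros((n_cells, len(windows)))
    for i in range(n_cells):
        factor = np.array([0.5 if a in deleted_arms_by_cell[i] else 1.0 for a in arms])
        lam = reads_per_cell * w_len * factor / float((w_len * factor).sum())
        counts = rng.poisson(lam)
        cov[i] = counts * read_len / w_len
    cells = [f"cell{i:04d}" for i in range(n_cells)]
    return CoverageWindows(windows=windows, cells=cells, coverage=cov), deleted_arms_by_cell
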