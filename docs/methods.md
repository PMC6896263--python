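# Methods

## The problem and the data model

Microfluidic single-nucleus ATAC-seq places one nucleus per well on a
rows × columns chip; each well yields a private sequencing library. Two
artifacts dominate quality control on this platform: PCR amplification
produces exact (and occasionally mutated) sequence copies within a well,
and cross-well leakage deposits exact copies of one well's reads into
other wells, preferentially along the donor's row. Because two nuclei
essentially never produce identical fragments by chance, an exact sequence
seen in two wells is treated as contamination, not signal.

Reads are carried as `(id, well, chromosome, start, end, sequence)`
records in per-well tables (`ChipReadStore`). Alignment is upstream of
this package; coordinates are taken as given (or assigned by the
simulator). All genomic coordinates are 0-based half-open; BED I/O is
bit-exact on the chrom/start/end/name columns.

## Clean-up

`dedup_within_well` collapses, independently per well, reads of equal
length whose sequences differ by at most `max_substitutions` (transitive
closure over pairwise Hamming distance, computed via `scipy` pdist). The
representative is the lexicographically smallest sequence, ties broken by
smallest read id. The default radius is 0 (exact copies only); mutated
leaked copies are deliberately *not* chased across wells — the cross-well
rule is exact-sequence only, and a nonzero radius applies within wells
only.

`purge_cross_well` removes every read whose exact sequence occurs in ≥ 2
distinct wells, from **all** wells carrying it. No donor is inferred: the
observable is "this sequence exists in two libraries", and the method
declines to guess which copy was real. The operation is idempotent, and
after it no sequence occupies more than one well (asserted by direct scan
in the tests).

`leakage_diagnostics` defines the shared fraction of a well pair as
|shared sequences| / min(|a|, |b|), so a small, heavily contaminated well
(e.g. an empty chamber that received leakage) registers strongly. Row
(column) enrichment is the mean shared fraction among same-row
(same-column) pairs divided by the mean among pairs sharing neither
coordinate; the empty-chip 0/0 case is reported as 1. Zero-read wells are
excluded from pair statistics.

`tss_profile` measures signal quality: the signed distance (by TSS strand)
from each read midpoint to the nearest TSS, and the fraction of reads
within ±2000 bp. Reads on chromosomes absent from the annotation count in
the denominator with infinite distance — a malformed annotation should
depress the score, not silently shrink the universe.

## Accessibility matrix

`overlap_with_reference` marks cell *c* positive for reference peak *p*
when some called peak of *c* overlaps *p* by at least `min_overlap_bp`
(default 50); overlap length is max(0, min(ends) − max(starts)). The
reference peak set plays the role of a bulk ATAC compendium (TCGA LGG
peaks in the glioma setting): constraining single-cell peaks to
bulk-supported regions guards against per-cell peak-calling noise.

`filter_cascade` runs three steps in a fixed order: drop peaks positive in
fewer than `min_cells_per_peak` cells (default 5), drop cells with fewer
than `min_peaks_per_cell` positives (default 50), drop cells with more
than `max_peaks_per_cell` positives (default 3000). The last step is the
doublet filter: two merged nuclei roughly double the positive-peak count.
The threshold is a fixed number, not a percentile — "top 5%" and ">3000"
coincide only on the original cohort — and the realized percentile of the
cutoff in the pre-filter distribution is reported so either reading can be
checked. The cascade is single-pass by default (matching the stated
narrative order, even though removing cells can strand a peak below the
peak threshold); `iterate=True` repeats the pass to a fixpoint, which
terminates because the matrix shrinks monotonically.

`collapse_to_genes` assigns each peak to at most one gene — the nearest
TSS within `max_distance` (default 2000 bp, a promoter-sized window; gap
distance, 0 if the TSS lies inside the peak; ties to the lexicographically
smallest gene) — and ORs member peaks per gene. Unassigned peaks form an
intergenic bucket excluded from the gene view. This nearest-TSS map is a
deliberate, documented substitute for external annotators (HOMER-style
annotation pipelines are out of scope), so gene-level counts on real data
will differ from annotator-derived ones.

`open_promoter_fraction` returns (positives, group size, percentage
rounded to one decimal). On the glioma cohort's printed counts this gives
101/145 = 69.7% (70% at integer precision) and 20/191 = 10.5%.

## Marker scores

For gene *g* and cell group *G*: x⁺ = peak-positive nuclei in *G*, Y⁺ =
peak-positive nuclei overall, x⁻/Y⁻ the corresponding negatives. Then

    top(g, G)      = x⁺/Y⁺ − (x⁻+1)/Y⁻
    specific(g, G) = (x⁺/Y⁺) / ((x⁻+1)/Y⁻)

ranked descending per group over genes with x⁺ > 10 (strict). The printed
chain form of the specific score is ambiguous under left-associative
division; it is read as the ratio of the two top-score terms, which is the
only reading under which the +1 pseudocount serves its evident purpose
(protecting against x⁻ = 0). Two guards handle edge cases the formulas
leave open: Y⁺ = 0 (gene open nowhere) raises an undefined-score error,
and Y⁻ = 0 (gene open everywhere) is guarded by max(Y⁻, 1). Scores are
descriptive enrichment statistics; no significance is attached. Gated
genes stay in the output table with `passes_gate = False` and no rank;
score ties rank lexicographically by gene id.

## CNV from coverage

Chromosomes are tiled into `window_bp` windows stepping by `window_bp −
overlap_bp` (defaults 10 Mb / 2 Mb, hence an 8 Mb step — the overlap
figure is read literally, and the step is a first-class parameter since
the upstream tradition has also been described with 2 Mb *steps*). A final
partial window survives if it covers at least half a window; a chromosome
shorter than one window becomes a single window. Windows carry the arm
containing their midpoint.

Coverage is mean per-base depth: read-bases overlapping the window divided
by window length (straddling reads contribute only their overlapping
bases). Each window w₀ is normalized against the `n_background` (default
100) eligible windows with GC content closest to its own — never itself,
never masked windows, never windows on the excluded arms (the arms under
test, 1p/19q in the glioma setting, so a real deletion cannot contaminate
its own baseline); GC ties break by genomic order, and if fewer windows
are eligible all of them are used with a warning. Then

    CovNorm(w₀) = mean_i log((cov(w₀)+1)/(cov(wᵢ)+1)),

natural log by default (`log_base` configurable), which puts a hemizygous
deletion at −ln 2 ≈ −0.693. `call_arm_loss` flags cells whose arm-mean
CovNorm falls below a threshold, default −0.3 — roughly midway between the
diploid mode (0) and the hemizygous mode (−0.69), a choice made here since
the source analysis presents coverage plots without a numeric call rule.

The +1 pseudocount matters: CovNorm magnitudes are depth-dependent, and
only approach −ln 2 when per-base depth ≫ 1. At chip-demo depth
(~10⁻³×) the deleted-arm signal is real but tiny (≈ −0.002), which is why
the parameter-recovery analysis runs on the window-level coverage
simulator at depth ≈ 40 (100 cells × 40 000 reads on a 7-chromosome 56 kb
toy genome with 500/100 bp windows — small enough to run in milliseconds,
deep enough that the pseudocount is negligible). The tests assert the
scale-invariance limit explicitly.

## Co-accessibility

Pearson correlation between the query's binary vector and every other
column over all retained cells; for 0/1 data this equals the phi
coefficient of the 2×2 contingency table (asserted against a
contingency-table oracle). Hits are coefficients strictly above the
threshold (default 0.2). Constant columns have no defined coefficient and
are excluded; a constant query raises. The screen is genome-wide;
restrict the matrix first for a neighborhood search.

## The chip simulator

`simulate_chip` emulates, with one seeded generator and a recorded
ground truth: empty wells (rate 0.1), doublet wells that merge two
nuclei's reads (rate 0.08), two subtypes with cohort-shaped fractions
(codel 191/336, noncodel 145/336), per-peak open probabilities (baseline
0.25, with 10% of peaks per subtype near-private at 0.9 vs 0.05), Poisson
reads per open peak (mean 5) plus uniform background (mean 200/nucleus),
PCR duplicates (rate 0.1, optional substitution rate for mutant
amplicons), and hemizygous chr1p/chr19q deletions in the codel subtype
implemented as halved read sampling on the arm. Sequences are random
50-mers, so cross-well collisions are vanishingly unlikely and leakage is
exactly identifiable.

Leakage: each occupied well donates with probability 0.25; a donor picks 6
recipient wells among its row (weight 3 each) and column (weight 1 each)
and deposits exact copies of 25 of its reads into each. The donor rates
are free parameters — the platform literature describes the geometry, not
the rates — and the defaults are set so the designed 3:1 row preference is
actually expressed above the sampling noise of the pair statistics (the
min-denominator shared fraction is heavy-tailed when near-empty wells
receive leakage; with too few leakage events the row/column ordering can
invert by chance).

What the simulator does **not** model: Tn5 insertion-site bias,
fragment-length periodicity, chromatin-state-dependent background,
GC-coverage coupling (simulated GC is independent of coverage, so GC
matching is exercised but unbiased), and sequencing error beyond a flat
substitution rate on PCR copies. Passing tests therefore demonstrate the
correctness of the operations and the recoverability of planted structure,
not robustness to every real-data pathology.

`simulate_window_coverage` is the window-level counterpart used for CNV
calibration: per-window Poisson read counts proportional to window length
(halved on deleted arms), converted to depth.

## Problem sizes and determinism

The shipped analyses use an 8×8 chip with 200 reference peaks and 100
genes (~35 k reads), and 100-cell coverage simulations — sizes chosen so
the whole suite and the acceptance script run in seconds while every
statistic sits far from its decision boundaries. All randomness flows from
a single integer seed per run; reports serialize with sorted keys and are
byte-identical across reruns.

## Known limitations

* Exact-sequence purging removes genuine reads whose sequences collide
  across wells; with real (non-random) fragments sharing hotspot
  boundaries, the purge is conservative by construction (the original
  analysis accepted the same trade).
* Mutated leaked copies survive the cross-well purge (as in the original
  clean-up); the within-well Hamming dedup reduces, but cannot eliminate,
  them.
* The nearest-TSS gene map is a stand-in for annotator pipelines; numbers
  derived from it (gene counts, promoter calls) are not comparable to
  annotator-derived ones without re-mapping.
* CovNorm is uncalibrated at shallow depth (pseudocount regime); arm
  calls should only be made when per-cell depth makes |ln ½| resolvable.
* k-means/t-SNE clustering and significance machinery are intentionally
  absent; groupings are an input.
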