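"""Simulate a microfluidic snATAC chip with known ground truth.

Builds an 8x8 chip of two glioma-like subtypes (codel cells carry
hemizygous chr1p/chr19q deletions), with empty wells, doublets, PCR
duplicates and cross-well leakage injected along rows and columns.
"""

from snatac_hetero import default_config, simulate_chip

config = default_config(n_rows=8, n_cols=8, n_peaks=200, rng_seed=1)
store, cell_peaks, truth = simulate_chip(config)

occupied = truth.occupied_wells()
print(f"wells:            {config.n_rows * config.n_cols}")
print(f"occupied wells:   {len(occupied)}")
print(f"doublet wells:    {len(truth.doublet_wells())}")
print(f"reads simulated:  {store.n_reads()}")
print(f"leaked reads:     {len(truth.leaked)} injected copies "
      f"({len(truth.leaked_sequences)} distinct sequences)")
print(f"subtype of {occupied[0]}: {truth.cell_subtype[occupied[0]]}, "
      f"{len(truth.open_peaks_truth[occupied[0]])} truly open peaks")

# Reads live in per-well tables; every downstream stage consumes this store.
# The truth object records exactly which reads are contamination, which
# wells are doublets and which chromosome arms are deleted, so each
# clean-up step can be scored against it.
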