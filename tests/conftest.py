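import pandas as pd
import pytest

from snatac_hetero import default_config, dedup_within_well, purge_cross_well, simulate_chip
from snatac_hetero.readstore import ChipReadStore, empty_read_frame


def make_store(layout, wells):
    """Build a small store from {(r, c): [(read_id, seq) or (read_id, chrom, start, end, seq)]}."""
    store = ChipReadStore.empty(*layout)
    for coord, reads in wells.items():
        rows = []
        for rec in reads:
            if len(rec) == 2:
                rid, seq = rec
                rows.append((rid, ".", -1, -1, seq))
            else:
                rows.append(rec)
        store.wells[coord] = pd.DataFrame(
            rows, columns=["read_id", "chrom", "start", "end", "sequence"]
        )
    return store


@pytest.fixture(scope="session")
def chip():
    """One seeded 8x8 chip with injected leakage, shared across tests."""
    config = default_config(rng_seed=1)
    store, cell_peaks, truth = simulate_chip(config)
    return config, store, cell_peaks, truth


@pytest.fixture(scope="session")
def cleaned_chip(chip):
    config, store, cell_peaks, truth = chip
    deduped = dedup_within_well(store)
    clean, report = purge_cross_well(deduped)
    return config, clean, report, truth
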