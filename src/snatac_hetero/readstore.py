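"""Per-well read storage for microfluidic single-nucleus ATAC chips.

The Fluidigm C1 HT IFC arranges capture chambers ("wells") on a fixed
rows x columns grid.  Library preparation happens per well, so every read
is addressable by its well coordinate.  The clean-up stages operate on
this per-well structure: duplicates are collapsed within a well, and
sequences shared between wells are treated as cross-well leakage.

Reads are carried as plain records (id, chromosome, start, end, sequence)
rather than alignments: coordinates are assigned upstream (or by the
simulator), and the clean-up itself only ever inspects raw sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

READ_COLUMNS = ["read_id", "chrom", "start", "end", "sequence"]

_WELL_RE = re.compile(r"^R(\d+)C(\d+)$")


def well_id(row: int, col: int) -> str:
    """Human-readable well label for 0-based grid coordinates, e.g. ``R01C03``."""
    return f"R{row + 1:02d}C{col + 1:02d}"


def parse_well_id(label: str) -> tuple[int, int]:
    m = _WELL_RE.match(label)
    if m is None:
        raise ValueError(f"not a well id: {label!r}")
    return int(m.group(1)) - 1, int(m.group(2)) - 1


def empty_read_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype="int64"),
            "end": pd.Series(dtype="int64"),
            "sequence": pd.Series(dtype=str),
        }
    )


@dataclass
class ChipReadStore:
    """Reads grouped by chip well on an ``n_rows`` x ``n_cols`` grid.

    ``wells`` maps 0-based ``(row, col)`` coordinates to a DataFrame with
    columns ``read_id, chrom, start, end, sequence``.  Genomic intervals are
    0-based half-open; reads without a placement carry chrom ``"."`` and
    start = end = -1.  Every grid coordinate is present (empty wells hold an
    empty frame), and read ids are unique within a well.
    """

    n_rows: int
    n_cols: int
    wells: dict[tuple[int, int], pd.DataFrame] = field(default_factory=dict)

    @classmethod
    def empty(cls, n_rows: int, n_cols: int) -> "ChipReadStore":
        wells = {
            (r, c): empty_read_frame() for r in range(n_rows) for c in range(n_cols)
        }
        return cls(n_rows=n_rows, n_cols=n_cols, wells=wells)

    # -- basic queries -------------------------------------------------

    @property
    def layout(self) -> tuple[int, int]:
        return self.n_rows, self.n_cols

    def coords(self) -> list[tuple[int, int]]:
        return [(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]

    def n_reads(self) -> int:
        return sum(len(df) for df in self.wells.values())

    def reads_per_well(self) -> dict[tuple[int, int], int]:
        return {coord: len(df) for coord, df in self.wells.items()}

    def sequences(self, coord: tuple[int, int]) -> set[str]:
        return set(self.wells[coord]["sequence"])

    def all_reads(self) -> pd.DataFrame:
        """Single frame over all wells with added ``row``/``col`` columns."""
        frames = []
        for (r, c), df in sorted(self.wells.items()):
            if len(df) == 0:
                continue
            frames.append(df.assign(row=r, col=c))
        if not frames:
            return empty_read_frame().assign(row=pd.Series(dtype=int), col=pd.Series(dtype=int))
        return pd.concat(frames, ignore_index=True)

    def copy(self) -> "ChipReadStore":
        return ChipReadStore(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            wells={coord: df.copy() for coord, df in self.wells.items()},
        )

    def validate(self) -> None:
        for coord, df in self.wells.items():
            r, c = coord
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"well {coord} outside {self.n_rows}x{self.n_cols} grid")
            if df["read_id"].duplicated().any():
                raise ValueError(f"duplicate read ids in well {well_id(r, c)}")

    # -- I/O -----------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write all reads as one TSV; the grid shape goes in a header comment."""
        path = Path(path)
        table = self.all_reads()
        table.insert(0, "well", [well_id(r, c) for r, c in zip(table["row"], table["col"])])
        table = table.drop(columns=["row", "col"])
        with open(path, "w") as fh:
            fh.write(f"#layout\t{self.n_rows}\t{self.n_cols}\n")
            table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChipReadStore":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[0] != "#layout":
                raise ValueError(f"{path}: missing #layout header")
            n_rows, n_cols = int(header[1]), int(header[2])
            table = pd.read_csv(
                fh, sep="\t", dtype={"well": str, "read_id": str, "chrom": str, "sequence": str}
            )
        store = cls.empty(n_rows, n_cols)
        if len(table):
            for label, group in table.groupby("well", sort=True):
                coord = parse_well_id(label)
                store.wells[coord] = group[READ_COLUMNS].reset_index(drop=True)
        return store

    def write_fastq(self, outdir: str | Path) -> list[Path]:
        """One 4-line-record FASTQ per occupied well (constant quality)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for (r, c), df in sorted(self.wells.items()):
            if len(df) == 0:
                continue
            path = outdir / f"{well_id(r, c)}.fastq"
            with open(path, "w") as fh:
                for rid, seq in zip(df["read_id"], df["sequence"]):
                    fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            written.append(path)
        return written
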