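"""Peak sets and TSS annotation tables.

Peaks are unstranded genomic intervals in 0-based half-open coordinates,
kept sorted by (chromosome, start).  BED I/O is bit-exact: columns beyond
chrom/start/end/name are neither read nor invented.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

PEAK_COLUMNS = ["chrom", "start", "end", "name"]


@dataclass
class PeakSet:
    """Sorted, named genomic intervals (chrom, start, end) with start < end."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        if "name" not in df.columns:
            df = df.assign(
                name=[f"{c}:{s}-{e}" for c, s, e in zip(df["chrom"], df["start"], df["end"])]
            )
        df = df[[c for c in df.columns if c in PEAK_COLUMNS or c == "gene"]]
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(f"empty or inverted interval: {bad['chrom']}:{bad['start']}-{bad['end']}")
        self.df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)

    @classmethod
    def from_intervals(cls, intervals, names=None) -> "PeakSet":
        df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
        if names is not None:
            df["name"] = list(names)
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def names(self) -> list[str]:
        return list(self.df["name"])

    def intervals(self) -> list[tuple[str, int, int]]:
        return list(zip(self.df["chrom"], self.df["start"], self.df["end"]))

    # -- BED I/O -------------------------------------------------------

    def to_bed(self, path: str | Path) -> None:
        self.df[PEAK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path) -> "PeakSet":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2, 3],
            names=PEAK_COLUMNS,
            dtype={"chrom": str, "start": "int64", "end": "int64", "name": str},
            comment="#",
        )
        return cls(df)


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read a BED-like TSS annotation: chrom, start(=TSS), end, gene, score, strand."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene", "score", "strand"],
        dtype={"chrom": str, "gene": str, "strand": str},
        comment="#",
    )
    return pd.DataFrame(
        {"gene": df["gene"], "chrom": df["chrom"], "tss": df["start"], "strand": df["strand"]}
    )


def write_tss_table(annotation: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": annotation["tss"],
            "end": annotation["tss"] + 1,
            "gene": annotation["gene"],
            "score": 0,
            "strand": annotation["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
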