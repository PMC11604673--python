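"""Genomic region specifications for cis-windows around candidate genes.

A cis-region is the gene body plus a symmetric flank (default 1 Mb each
side), on hg38 with 1-based closed coordinates.  A built-in table of the
seven type 1 diabetes drug-target candidate genes (plus IL23A, which has
no circulating-level data) is provided for convenience; arbitrary region
tables can be read from BED-like TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["RegionSpec", "BUILTIN_REGIONS", "builtin_region", "read_region_table"]

DEFAULT_FLANK_BP = 1_000_000


@dataclass(frozen=True)
class RegionSpec:
    """A gene region on hg38: 1-based, closed interval, plus a cis-flank."""

    gene: str
    chrom: str
    start: int
    end: int
    flank_bp: int = DEFAULT_FLANK_BP
    build: str = "hg38"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end for {self.gene}: {self.start} > {self.end}")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")

    @property
    def window(self) -> tuple[int, int]:
        """The (lo, hi) closed interval including the flank."""
        return max(1, self.start - self.flank_bp), self.end + self.flank_bp


# Candidate drug-target gene coordinates (hg38).  IL23A is retained for
# completeness although no protein-level GWAS covers it.
BUILTIN_REGIONS: dict[str, RegionSpec] = {
    r.gene: r
    for r in [
        RegionSpec("IL2RA", "10", 6_010_689, 6_062_367),
        RegionSpec("IL2RB", "22", 37_118_666, 37_175_118),
        RegionSpec("IL23A", "12", 56_338_884, 56_340_410),
        RegionSpec("IL6R", "1", 154_405_193, 154_469_450),
        RegionSpec("IL6ST", "5", 55_935_095, 55_995_022),
        RegionSpec("JAK2", "9", 4_984_390, 5_129_948),
        RegionSpec("JAK3", "19", 17_824_780, 17_848_071),
        RegionSpec("TYK2", "19", 10_350_533, 10_380_608),
    ]
}


def builtin_region(gene: str, flank_bp: int = DEFAULT_FLANK_BP) -> RegionSpec:
    """Look up a built-in gene region, with a custom flank if requested."""
    try:
        base = BUILTIN_REGIONS[gene.upper()]
    except KeyError:
        raise KeyError(
            f"unknown gene {gene!r}; built-ins: {sorted(BUILTIN_REGIONS)}"
        ) from None
    return RegionSpec(base.gene, base.chrom, base.start, base.end, flank_bp)


def read_region_table(path: str | Path, flank_bp: int = DEFAULT_FLANK_BP) -> list[RegionSpec]:
    """Read a BED-like TSV with columns gene, chrom, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    return [
        RegionSpec(str(r.gene), str(r.chrom), int(r.start), int(r.end), flank_bp)
        for r in df.itertuples()
    ]
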