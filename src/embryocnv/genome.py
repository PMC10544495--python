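"""Chromosome / bin coordinate system shared by the simulator and the caller.

The genome is a fixed karyotype table (approximate GRCh38 chromosome lengths
and centromere positions, shipped as package data) tiled into fixed-width
bins.  Coordinates are 0-based half-open.  Bins never span the centromere:
the bin reaching it is truncated and a fresh bin starts at the centromere, so
every bin lies entirely on one chromosome arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

MIN_BIN_SIZE = 100_000

#: integer codes for arms
P_ARM, Q_ARM = 0, 1


class GenomeConfigError(ValueError):
    """Raised for invalid genome/bin configuration (e.g. bin size too small)."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: int
    is_autosome: bool

    def __post_init__(self) -> None:
        if not (0 < self.centromere < self.length):
            raise GenomeConfigError(
                f"{self.name}: centromere must lie strictly inside the chromosome"
            )


@dataclass
class GenomeModel:
    """Karyotype table plus a bin grid.

    Attributes
    ----------
    chromosomes : list[Chromosome]
        22 autosomes followed by X and Y.
    bin_size : int
        Target bin width in bp (last bin of each arm may be short).
    bin_chrom, bin_start, bin_end, bin_arm : ndarray
        Parallel per-bin arrays; ``bin_chrom`` holds the chromosome index,
        ``bin_arm`` is 0 for the p arm and 1 for the q arm.
    """

    chromosomes: list[Chromosome]
    bin_size: int
    bin_chrom: np.ndarray = field(repr=False, default=None)
    bin_start: np.ndarray = field(repr=False, default=None)
    bin_end: np.ndarray = field(repr=False, default=None)
    bin_arm: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.bin_size < MIN_BIN_SIZE:
            raise GenomeConfigError(
                f"bin_size must be >= {MIN_BIN_SIZE} bp, got {self.bin_size}"
            )
        if len(self.chromosomes) != 24 or sum(c.is_autosome for c in self.chromosomes) != 22:
            raise GenomeConfigError("expected exactly 22 autosomes plus X and Y")
        if self.bin_chrom is None:
            self._tile()

    def _tile(self) -> None:
        chrom_idx, starts, ends, arms = [], [], [], []
        for i, c in enumerate(self.chromosomes):
            for arm, (lo, hi) in enumerate(((0, c.centromere), (c.centromere, c.length))):
                edges = list(range(lo, hi, self.bin_size)) + [hi]
                for s, e in zip(edges[:-1], edges[1:]):
                    chrom_idx.append(i)
                    starts.append(s)
                    ends.append(e)
                    arms.append(arm)
        self.bin_chrom = np.asarray(chrom_idx, dtype=np.int32)
        self.bin_start = np.asarray(starts, dtype=np.int64)
        self.bin_end = np.asarray(ends, dtype=np.int64)
        self.bin_arm = np.asarray(arms, dtype=np.int8)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_bins(self) -> int:
        return len(self.bin_chrom)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def autosome_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.chromosomes) if c.is_autosome])

    @property
    def x_index(self) -> int:
        return next(i for i, c in enumerate(self.chromosomes) if c.name == "chrX")

    @property
    def y_index(self) -> int:
        return next(i for i, c in enumerate(self.chromosomes) if c.name == "chrY")

    @property
    def autosome_bin_mask(self) -> np.ndarray:
        auto = np.array([c.is_autosome for c in self.chromosomes])
        return auto[self.bin_chrom]

    def chrom_index(self, name: str) -> int:
        for i, c in enumerate(self.chromosomes):
            if c.name == name:
                return i
        raise KeyError(name)

    def bins_of(self, chrom: int, arm: int | None = None) -> np.ndarray:
        """Boolean mask of the bins of one chromosome (optionally one arm)."""
        mask = self.bin_chrom == chrom
        if arm is not None:
            mask &= self.bin_arm == arm
        return mask

    def bin_table(self) -> pd.DataFrame:
        names = [self.chromosomes[i].name for i in self.bin_chrom]
        return pd.DataFrame(
            {
                "chrom": names,
                "start": self.bin_start,
                "end": self.bin_end,
                "arm": np.where(self.bin_arm == P_ARM, "p", "q"),
            }
        )


def load_genome_table() -> pd.DataFrame:
    """Packaged 4-column karyotype table (name, length, centromere, is_autosome)."""
    with resources.files("embryocnv.data").joinpath("genome_grch38.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def build_default_genome(bin_size: int = 1_000_000) -> GenomeModel:
    """Build the packaged GRCh38-like genome tiled at ``bin_size``.

    Centromere coordinates in the packaged table are rounded to whole Mb, so
    at the default 1 Mb grid the per-chromosome bin count equals
    ``ceil(length / bin_size)`` even though bins are tiled per arm.
    """
    tab = load_genome_table()
    chroms = [
        Chromosome(str(r.name), int(r.length), int(r.centromere), bool(r.is_autosome))
        for r in tab.itertuples(index=False)
    ]
    return GenomeModel(chromosomes=chroms, bin_size=int(bin_size))
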