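"""Five-category embryo classification and aneuploidy complexity counts.

Each tested embryo falls into exactly one of five mutually exclusive
categories based on its autosomal calls: Euploid; meiotic whole-chromosome
aneuploidy only; meiotic plus mitotic-whole or segmental; mitotic
whole-chromosome only; or segmental with or without mitotic whole-chromosome
aneuploidy.  Sex-chromosome calls (origin not_classified by construction)
never enter the category logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class EmbryoCategory(str, Enum):
    EUPLOID = "Euploid"
    MEIOTIC_ONLY = "MeioticOnly"
    MEIOTIC_PLUS = "MeioticPlusMitoticOrSeg"
    MITOTIC_ONLY = "MitoticOnly"
    MITOTIC_SEG = "MitoticAndOrSeg"


CATEGORY_ORDER = [
    EmbryoCategory.EUPLOID,
    EmbryoCategory.MEIOTIC_ONLY,
    EmbryoCategory.MEIOTIC_PLUS,
    EmbryoCategory.MITOTIC_ONLY,
    EmbryoCategory.MITOTIC_SEG,
]

COMPLEXITY_BINS = ["0", "1", "2", "3", "4", ">=5"]


def _split(calls):
    """Partition autosomal calls into meiotic-whole / mitotic-whole /
    segmental; sex-chromosome calls are dropped."""
    meiotic, mitotic, segmental = [], [], []
    for c in calls:
        if c.chrom in ("chrX", "chrY"):
            continue
        if c.scope != "whole":
            segmental.append(c)
        elif c.origin == "meiotic":
            meiotic.append(c)
        elif c.origin == "mitotic":
            mitotic.append(c)
    return meiotic, mitotic, segmental


def categorize(calls) -> EmbryoCategory:
    """Assign the five-category label from one sample's call list."""
    meiotic, mitotic, segmental = _split(calls)
    if not meiotic and not mitotic and not segmental:
        return EmbryoCategory.EUPLOID
    if meiotic:
        return EmbryoCategory.MEIOTIC_PLUS if (mitotic or segmental) else EmbryoCategory.MEIOTIC_ONLY
    if segmental:
        return EmbryoCategory.MITOTIC_SEG
    return EmbryoCategory.MITOTIC_ONLY


@dataclass
class ComplexityCount:
    n_meiotic_whole_autosome: int
    n_mitotic_whole_autosome: int
    n_segmental: int
    n_total_aneuploid_chromosomes: int
    binned_total: str

    def __post_init__(self) -> None:
        parts = (
            self.n_meiotic_whole_autosome,
            self.n_mitotic_whole_autosome,
            self.n_segmental,
        )
        if self.n_total_aneuploid_chromosomes < max(parts):
            raise ValueError("total aneuploid chromosomes below a component count")


def count_complexity(calls) -> ComplexityCount:
    """Distinct-chromosome counts per origin class.

    A chromosome carrying both whole-chromosome and segmental events counts
    once toward the total."""
    meiotic, mitotic, segmental = _split(calls)
    m_chroms = {c.chrom for c in meiotic}
    t_chroms = {c.chrom for c in mitotic}
    s_chroms = {c.chrom for c in segmental}
    total = len(m_chroms | t_chroms | s_chroms)
    binned = COMPLEXITY_BINS[min(total, 5)]
    return ComplexityCount(len(m_chroms), len(t_chroms), len(s_chroms), total, binned)
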