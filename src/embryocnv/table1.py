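"""Published five-category counts for arrested embryos vs trophectoderm
biopsies, packaged as a fixture, plus the statistics recomputed from it.

The fixture is the 5 x 2 table of tested embryos (297 whole arrested
embryos, 612 blastocyst biopsies) by copy-number category, together with the
study-flow denominators (610 arrested and 622 blastocysts among 1232
normally fertilized zygotes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .stats import pearson_chi_squared

# study-flow denominators
TOTAL_2PN = 1232
TOTAL_ARRESTED = 610
TOTAL_BLASTOCYSTS = 622
EXPECTED_TESTED = (297, 612)


class FixtureIntegrityError(ValueError):
    """The packaged count table does not reproduce the expected totals."""


def load_table1() -> pd.DataFrame:
    with resources.files("embryocnv.data").joinpath("table1_counts.tsv").open() as fh:
        tab = pd.read_csv(fh, sep="\t")
    totals = (int(tab["arrested"].sum()), int(tab["blastocyst"].sum()))
    if totals != EXPECTED_TESTED:
        raise FixtureIntegrityError(
            f"fixture totals {totals} != expected {EXPECTED_TESTED}"
        )
    return tab


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    factor = 10**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class Table1Statistics:
    chi2: float
    df: int
    p: float
    arrested_aneuploidy_pct: float  # percent, rounded half-up to integer
    blastocyst_aneuploidy_pct: float
    overall_euploid_pct: float  # one decimal
    overall_aneuploid_pct: float
    arrested_tested_pct: float  # 297 / 610
    blastulation_pct: float  # 622 / 1232
    n_tested: int


def reproduce_paper_tables(counts: pd.DataFrame | None = None) -> Table1Statistics:
    """Recompute the category-table statistics from the fixture counts alone."""
    tab = counts if counts is not None else load_table1()
    totals = (int(tab["arrested"].sum()), int(tab["blastocyst"].sum()))
    if totals != EXPECTED_TESTED:
        raise FixtureIntegrityError(
            f"fixture totals {totals} != expected {EXPECTED_TESTED}"
        )
    table = tab[["arrested", "blastocyst"]].to_numpy()
    chi = pearson_chi_squared(table)
    n_arr, n_bla = totals
    eu_arr = int(tab.loc[tab["category"] == "Euploid", "arrested"].iloc[0])
    eu_bla = int(tab.loc[tab["category"] == "Euploid", "blastocyst"].iloc[0])
    n = n_arr + n_bla
    eu = eu_arr + eu_bla
    return Table1Statistics(
        chi2=float(np.round(chi.statistic, 1)),
        df=int(chi.df),
        p=chi.p,
        arrested_aneuploidy_pct=round_half_up(100.0 * (n_arr - eu_arr) / n_arr),
        blastocyst_aneuploidy_pct=round_half_up(100.0 * (n_bla - eu_bla) / n_bla),
        overall_euploid_pct=round_half_up(100.0 * eu / n, 1),
        overall_aneuploid_pct=round_half_up(100.0 * (n - eu) / n, 1),
        arrested_tested_pct=round_half_up(100.0 * n_arr / TOTAL_ARRESTED, 1),
        blastulation_pct=round_half_up(100.0 * TOTAL_BLASTOCYSTS / TOTAL_2PN, 1),
        n_tested=n,
    )
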