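"""Five-category classification summary: category-by-outcome counts with
within-column percentages (the arrested-vs-blastocyst contrast).

Reads results/embryo_table.tsv (from 02) and writes
results/category_table.tsv.
"""
from pathlib import Path

import pandas as pd

from embryocnv.stats import pearson_chi_squared

OUT = Path("results")

def main():
    df = pd.read_csv(OUT / "embryo_table.tsv", sep="\t")
    d = df[~df.qc_excluded].copy()
    tab = pd.crosstab(d["category"], d["arrested"].map({True: "arrested", False: "blastocyst"}))
    tab = tab.reindex(["Euploid", "MeioticOnly", "MeioticPlusMitoticOrSeg", "MitoticOnly", "MitoticAndOrSeg"]).fillna(0).astype(int)
    chi = pearson_chi_squared(tab.to_numpy())
    tab.to_csv(OUT / "category_table.tsv", sep="\t")
    print(tab)
    print(f"chi-squared [{chi.df}, N = {int(tab.to_numpy().sum())}] = {chi.statistic:.1f}, p = {chi.p:.3g}")

if __name__ == "__main__":
    main()
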