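"""Association battery on the called cohort: age trends (quasi-binomial),
meiotic/mitotic co-occurrence, arrest enrichment, division-pattern
associations and the aneuploidy-complexity contrast (quasi-Poisson).

Reads results/embryo_table.tsv and writes results/association_tests.tsv.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from embryocnv import stats

OUT = Path("results")

def two_by_two(df, a, b):
    return np.array([
        [int((df[a] & df[b]).sum()), int((df[a] & ~df[b]).sum())],
        [int((~df[a] & df[b]).sum()), int((~df[a] & ~df[b]).sum())],
    ])

def main():
    df = pd.read_csv(OUT / "embryo_table.tsv", sep="\t")
    d = df[~df.qc_excluded].copy()
    for c in ("has_meiotic_call", "has_mitotic_call", "arrested", "abnormal_division"):
        d[c] = d[c].astype(bool)
    results = {}
    for flag, name in (("has_meiotic_call", "meiotic_age_trend"), ("has_mitotic_call", "mitotic_age_trend")):
        grp = d.groupby("cycle_id").agg(age=("maternal_age", "first"), k=(flag, "sum"), n=(flag, "size"))
        resp = np.column_stack([grp.k, grp.n - grp.k]).astype(float)
        results[name] = stats.fit_quasi_glm(resp, grp.age.to_numpy(), "quasi_binomial")
    results["cooccurrence"] = stats.fisher_exact(two_by_two(d, "has_meiotic_call", "has_mitotic_call"))
    results["arrest_x_meiotic"] = stats.fisher_exact(two_by_two(d, "has_meiotic_call", "arrested"))
    results["arrest_x_mitotic"] = stats.fisher_exact(two_by_two(d, "has_mitotic_call", "arrested"))
    results["division_x_mitotic"] = stats.fisher_exact(two_by_two(d, "abnormal_division", "has_mitotic_call"))
    results["division_x_arrest"] = stats.fisher_exact(two_by_two(d, "abnormal_division", "arrested"))
    counts, origin = [], []
    for _, r in d.iterrows():
        if r.has_meiotic_call:
            counts.append(r.n_meiotic); origin.append("meiotic")
        if r.has_mitotic_call:
            counts.append(r.n_mitotic); origin.append("mitotic")
    results["complexity_by_origin"] = stats.fit_quasi_glm(np.asarray(counts, float), np.asarray(origin), "quasi_poisson")
    tidy = stats.results_to_frame(results)
    tidy.to_csv(OUT / "association_tests.tsv", sep="\t", index=False)
    print(tidy.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

if __name__ == "__main__":
    main()
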