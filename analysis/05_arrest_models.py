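"""Mixed-effects models of embryo arrest: binomial GLMMs (patient random
intercept) with category / complexity / division-pattern predictors, AMEs on
the probability scale, and the biopsy-day linear mixed model.

Reads results/embryo_table.tsv; writes results/glmm_*.tsv.
"""
from pathlib import Path

import pandas as pd

from embryocnv.glmm import average_marginal_effect, fit_binomial_glmm, fit_lmm

OUT = Path("results")

def main():
    df = pd.read_csv(OUT / "embryo_table.tsv", sep="\t")
    d = df[~df.qc_excluded].copy()
    d["arrested"] = d["arrested"].astype(bool)

    fit = fit_binomial_glmm(d.arrested.to_numpy().astype(float), d.category.to_numpy(), d.patient_id.to_numpy(), reference="Euploid")
    probs = fit.level_probabilities()
    probs.to_csv(OUT / "glmm_category_probs.tsv", sep="\t", index=False)
    print("marginal arrest probability by category:")
    print(probs.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    fit_cx = fit_binomial_glmm(d.arrested.to_numpy().astype(float), d.n_total.to_numpy().astype(float), d.patient_id.to_numpy())
    ame = average_marginal_effect(fit_cx)
    print(f"\narrest AME per aneuploid chromosome: {ame.ame:.3f} (SE {ame.se:.3f})")

    blasto = d[~d.arrested].dropna(subset=["biopsy_day"])
    lmm = fit_lmm(blasto.biopsy_day.to_numpy(), blasto.any_aneuploidy_call.astype(bool).to_numpy(), blasto.patient_id.to_numpy())
    print(f"biopsy-day AME (aneuploid - euploid): {lmm.ame:.3f} days (SE {lmm.se:.3f}, p {lmm.p:.3g})")
    pd.DataFrame([{"ame_per_chromosome": ame.ame, "ame_se": ame.se,
                   "biopsy_day_ame": lmm.ame, "biopsy_day_se": lmm.se}]).to_csv(
        OUT / "glmm_ames.tsv", sep="\t", index=False)

if __name__ == "__main__":
    main()
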