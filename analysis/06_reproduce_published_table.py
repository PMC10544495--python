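"""Recompute the published five-category statistics from the packaged count
fixture alone (no simulation): chi-squared, aneuploidy incidences, overall
euploid/aneuploid fractions and the study-flow percentages.
"""
from embryocnv.table1 import reproduce_paper_tables

def main():
    st = reproduce_paper_tables()
    print(f"chi-squared [{st.df}, N = {st.n_tested}] = {st.chi2}  (p = {st.p:.3g})")
    print(f"aneuploidy incidence: arrested {st.arrested_aneuploidy_pct:.0f}%, blastocysts {st.blastocyst_aneuploidy_pct:.0f}%")
    print(f"overall: euploid {st.overall_euploid_pct}%, aneuploid {st.overall_aneuploid_pct}%")
    print(f"arrested embryos tested: {st.arrested_tested_pct}%; blastulation: {st.blastulation_pct}%")

if __name__ == "__main__":
    main()
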