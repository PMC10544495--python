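"""Simulate reads for every embryo sample, run copy-number calling, and join
calls with simulator truth.

Writes results/calls.tsv (per-call rows) and results/embryo_table.tsv (one
row per embryo: truth, category, complexity), the input for the later
association and modeling steps.
"""
from pathlib import Path

from embryocnv import calling, pipeline
from embryocnv.genome import build_default_genome
from embryocnv.sim import SimulationConfig, simulate_cohort

OUT = Path("results")

def main():
    genome = build_default_genome()
    cfg = SimulationConfig(seed=0)
    embryos, samples, counts = simulate_cohort(cfg, genome)
    results = [calling.call_sample(c, genome) for c in counts]
    df = pipeline.build_embryo_table(embryos, samples, results)
    OUT.mkdir(exist_ok=True)
    calling.calls_to_frame(results).to_csv(OUT / "calls.tsv", sep="\t", index=False)
    df.to_csv(OUT / "embryo_table.tsv", sep="\t", index=False)
    n_qc = int(df.qc_excluded.sum())
    d = df[~df.qc_excluded]
    print(f"{len(results)} samples called, {n_qc} QC-excluded ({n_qc/len(results):.1%})")
    print(f"meiotic call rate {d.has_meiotic_call.mean():.3f}, mitotic {d.has_mitotic_call.mean():.3f}")
    print(f"aneuploidy among arrested: {d.loc[d.arrested.astype(bool),'any_aneuploidy_call'].astype(bool).mean():.3f}")

if __name__ == "__main__":
    main()
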