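"""Simulate the default IVF cohort and summarize its truth structure.

Writes the per-embryo truth table to results/cohort/embryos.tsv and prints
the cohort-level rates (cycles, zygotes per cycle, abnormal divisions,
meiotic/mitotic error prevalence, blastulation).
"""
from pathlib import Path

from embryocnv.sim import SimulationConfig, simulate_cohort, embryos_to_frame

OUT = Path("results/cohort")

def main():
    cfg = SimulationConfig(seed=0)
    embryos, _, _ = simulate_cohort(cfg, with_reads=False)
    df = embryos_to_frame(embryos)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "embryos.tsv", sep="\t", index=False)
    cfg.to_yaml(OUT / "config.yaml")
    print(f"{len(df)} embryos, {df.patient_id.nunique()} patients, {df.cycle_id.nunique()} cycles")
    print(f"zygotes per cycle: {df.groupby('cycle_id').size().mean():.2f}")
    print(f"abnormal first division: {(df.first_division_pattern != 'normal').mean():.3f}")
    print(f"meiotic-error embryos: {df.meiotic_truth.mean():.3f}")
    print(f"mitotic-error embryos: {df.mitotic_truth.mean():.3f}")
    print(f"blastulation: {(~df.arrested).mean():.3f}")

if __name__ == "__main__":
    main()
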