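"""End-to-end orchestration: simulate -> call -> classify -> analyze.

``run_pipeline`` produces an AnalysisReport whose tables mirror the study's
summary outputs: the five-category arrested-vs-blastocyst table with
within-column percentages, chromosome-specific meiotic/mitotic gain and
loss counts, quasi-binomial age trends, Fisher enrichment tests, the
binomial GLMMs for arrest probability (category, complexity and
division-pattern predictors), the morphology chi-squared and the biopsy-day
linear mixed model.  Every statistic is computed from the serialized
intermediate tables, so a report can be regenerated from the TSVs alone.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, categories, glmm, sim, stats
from .genome import GenomeModel, build_default_genome
from .table1 import round_half_up


@dataclass
class AnalysisReport:
    config_hash: str
    seed: int
    cohort_summary: dict
    table1_analogue: pd.DataFrame
    chromosome_counts: pd.DataFrame
    tests: dict = field(default_factory=dict)  # name -> ContingencyResult/TrendFit
    glmm_category: "glmm.GlmmFit | None" = None
    glmm_category_probs: pd.DataFrame | None = None
    glmm_category_ames: pd.DataFrame | None = None
    glmm_complexity_ame: "glmm.AmeResult | None" = None
    glmm_division: "glmm.GlmmFit | None" = None
    lmm_biopsy_day: "glmm.LmmFit | None" = None
    embryo_table: pd.DataFrame | None = None
    calls_table: pd.DataFrame | None = None


def _config_hash(config: sim.SimulationConfig) -> str:
    payload = yaml.safe_dump(
        {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in vars(config).items()},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_embryo_table(embryos, samples, results) -> pd.DataFrame:
    """Join simulator truth with per-sample calls and category labels.

    QC-excluded samples are retained with ``qc_excluded=True`` and dropped
    from downstream statistics, mirroring the study's exclusions."""
    truth = sim.embryos_to_frame(embryos)
    by_embryo = {s.embryo_id: r for s, r in zip(samples, results)}
    rows = []
    for eid, r in by_embryo.items():
        if r.qc_excluded:
            rows.append({"embryo_id": eid, "qc_excluded": True})
            continue
        cat = categories.categorize(r.calls)
        cx = categories.count_complexity(r.calls)
        rows.append(
            {
                "embryo_id": eid,
                "qc_excluded": False,
                "category": cat.value,
                "n_meiotic": cx.n_meiotic_whole_autosome,
                "n_mitotic": cx.n_mitotic_whole_autosome,
                "n_segmental": cx.n_segmental,
                "n_total": cx.n_total_aneuploid_chromosomes,
                "binned_total": cx.binned_total,
                "has_meiotic_call": cx.n_meiotic_whole_autosome > 0,
                "has_mitotic_call": cx.n_mitotic_whole_autosome > 0,
                "any_aneuploidy_call": cat != categories.EmbryoCategory.EUPLOID,
            }
        )
    return truth.merge(pd.DataFrame(rows), on="embryo_id", how="inner")


def _table1_analogue(df: pd.DataFrame) -> pd.DataFrame:
    order = [c.value for c in categories.CATEGORY_ORDER]
    tab = (
        df.assign(column=np.where(df["arrested"], "arrested", "blastocyst"))
        .pivot_table(index="category", columns="column", values="embryo_id", aggfunc="count", fill_value=0)
        .reindex(order, fill_value=0)
    )
    for col in ("arrested", "blastocyst"):
        if col not in tab:
            tab[col] = 0
        tab[f"{col}_pct"] = [round_half_up(100.0 * v / max(tab[col].sum(), 1)) for v in tab[col]]
    return tab[["arrested", "arrested_pct", "blastocyst", "blastocyst_pct"]].reset_index()


def _chromosome_counts(results, df: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome counts of whole-autosome gains and losses by origin
    (the chromosome-specific rates panel)."""
    rows = []
    for r in results:
        if r.qc_excluded:
            continue
        for c in r.calls:
            if c.scope != "whole" or c.origin not in ("meiotic", "mitotic"):
                continue
            rows.append({"sample_id": r.sample_id, "chrom": c.chrom, "origin": c.origin, "direction": c.direction})
    if not rows:
        return pd.DataFrame(columns=["chrom", "origin", "direction", "count"])
    return (
        pd.DataFrame(rows)
        .groupby(["chrom", "origin", "direction"])
        .size()
        .rename("count")
        .reset_index()
    )


def _two_by_two(df, row_flag, col_flag):
    a = int((df[row_flag] & df[col_flag]).sum())
    b = int((df[row_flag] & ~df[col_flag]).sum())
    c = int((~df[row_flag] & df[col_flag]).sum())
    d = int((~df[row_flag] & ~df[col_flag]).sum())
    return np.array([[a, b], [c, d]])


def _per_cycle_rates(df: pd.DataFrame, flag: str) -> tuple[np.ndarray, np.ndarray]:
    grp = df.groupby("cycle_id").agg(age=("maternal_age", "first"), k=(flag, "sum"), n=(flag, "size"))
    response = np.column_stack([grp["k"].to_numpy(), (grp["n"] - grp["k"]).to_numpy()])
    return response, grp["age"].to_numpy()


def analyze(df: pd.DataFrame, results, fit_mixed: bool = True) -> dict:
    """All association statistics and mixed models on the analysis table."""
    out: dict = {"tests": {}}
    t = out["tests"]

    resp, age = _per_cycle_rates(df, "has_meiotic_call")
    t["meiotic_age_trend"] = stats.fit_quasi_glm(resp, age, "quasi_binomial")
    resp, age = _per_cycle_rates(df, "has_mitotic_call")
    t["mitotic_age_trend"] = stats.fit_quasi_glm(resp, age, "quasi_binomial")

    t["cooccurrence_meiotic_mitotic"] = stats.fisher_exact(_two_by_two(df, "has_meiotic_call", "has_mitotic_call"))
    t["arrest_enrichment_meiotic"] = stats.fisher_exact(_two_by_two(df, "has_meiotic_call", "arrested"))
    t["arrest_enrichment_mitotic"] = stats.fisher_exact(_two_by_two(df, "has_mitotic_call", "arrested"))
    t["division_mitotic"] = stats.fisher_exact(_two_by_two(df, "abnormal_division", "has_mitotic_call"))
    t["division_meiotic"] = stats.fisher_exact(_two_by_two(df, "abnormal_division", "has_meiotic_call"))
    t["division_arrest"] = stats.fisher_exact(_two_by_two(df, "abnormal_division", "arrested"))

    # complexity: do mitotic aneuploidies affect more chromosomes per embryo?
    stacked_counts, stacked_origin = [], []
    for _, row in df.iterrows():
        if row["has_meiotic_call"]:
            stacked_counts.append(row["n_meiotic"])
            stacked_origin.append("meiotic")
        if row["has_mitotic_call"]:
            stacked_counts.append(row["n_mitotic"])
            stacked_origin.append("mitotic")
    if len(set(stacked_origin)) == 2:
        t["complexity_by_origin"] = stats.fit_quasi_glm(
            np.asarray(stacked_counts), np.asarray(stacked_origin), "quasi_poisson"
        )

    blasto = df[~df["arrested"]]
    if len(blasto) and blasto["icm_grade"].nunique() > 1:
        aneuclass = np.select(
            [
                blasto["has_meiotic_call"] & blasto["has_mitotic_call"],
                blasto["has_meiotic_call"],
                blasto["has_mitotic_call"],
            ],
            ["both", "meiotic", "mitotic"],
            default="euploid_or_seg",
        )
        tab = pd.crosstab(blasto["icm_grade"], aneuclass)
        tab = tab.loc[tab.sum(axis=1) > 0, tab.sum(axis=0) > 0]
        if tab.shape[0] > 1 and tab.shape[1] > 1:
            t["morphology_chi2"] = stats.pearson_chi_squared(tab.to_numpy())

    if not fit_mixed:
        return out

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_cat = glmm.fit_binomial_glmm(
            df["arrested"].to_numpy(), df["category"].to_numpy(), df["patient_id"].to_numpy(),
            reference=categories.EmbryoCategory.EUPLOID.value,
        )
        out["glmm_category"] = fit_cat
        if fit_cat.converged:
            out["glmm_category_probs"] = fit_cat.level_probabilities()
            ames = []
            for level in fit_cat.levels[1:]:
                a = glmm.average_marginal_effect(fit_cat, level)
                ames.append({"level": level, "ame": a.ame, "se": a.se, "ci_low": a.ci_low, "ci_high": a.ci_high})
            out["glmm_category_ames"] = pd.DataFrame(ames)

        fit_cx = glmm.fit_binomial_glmm(
            df["arrested"].to_numpy(), df["n_total"].to_numpy().astype(float), df["patient_id"].to_numpy()
        )
        out["glmm_complexity"] = fit_cx
        if fit_cx.converged:
            out["glmm_complexity_ame"] = glmm.average_marginal_effect(fit_cx)

        div = df[df["cells_after_first_division"] != ""]
        if div["cells_after_first_division"].nunique() > 1:
            out["glmm_division"] = glmm.fit_binomial_glmm(
                div["arrested"].to_numpy(),
                div["cells_after_first_division"].to_numpy(),
                div["patient_id"].to_numpy(),
                reference="2",
            )

        day = blasto.dropna(subset=["biopsy_day"])
        if len(day) and day["patient_id"].nunique() > 1 and day["any_aneuploidy_call"].nunique() > 1:
            out["lmm_biopsy_day"] = glmm.fit_lmm(
                day["biopsy_day"].to_numpy(),
                day["any_aneuploidy_call"].to_numpy(),
                day["patient_id"].to_numpy(),
            )
    return out


def run_pipeline(
    config: sim.SimulationConfig,
    genome: GenomeModel | None = None,
    outdir: str | Path | None = None,
    fit_mixed: bool = True,
) -> AnalysisReport:
    """Simulate a cohort, call every sample, classify, and analyze.

    Deterministic given ``config.seed``; when ``outdir`` is given, every
    intermediate (embryos, divisions, calls, categories, statistics) is
    written as TSV next to a Markdown report and a log of the seed, config
    hash and QC exclusions."""
    genome = genome or build_default_genome()
    embryos, samples, counts = sim.simulate_cohort(config, genome, with_reads=True)
    results = [calling.call_sample(c, genome) for c in counts]
    df_all = build_embryo_table(embryos, samples, results)
    df = df_all[~df_all["qc_excluded"]].reset_index(drop=True)
    # call-derived columns are object-dtype after the merge (QC rows hold NaN)
    for col in ("has_meiotic_call", "has_mitotic_call", "any_aneuploidy_call"):
        df[col] = df[col].astype(bool)
    df["n_total"] = df["n_total"].astype(int)

    analysis = analyze(df, results, fit_mixed=fit_mixed)
    report = AnalysisReport(
        config_hash=_config_hash(config),
        seed=config.seed,
        cohort_summary={
            "n_patients": int(df_all["patient_id"].nunique()),
            "n_cycles": int(df_all["cycle_id"].nunique()),
            "n_embryos": int(len(df_all)),
            "n_tested": int(len(df)),
            "n_qc_excluded": int(df_all["qc_excluded"].sum()),
            "blastulation_fraction": float((~df_all["arrested"].fillna(False)).mean())
            if "arrested" in df_all
            else float("nan"),
            "arrested_aneuploidy_fraction": float(df.loc[df["arrested"], "any_aneuploidy_call"].mean()),
            "blastocyst_aneuploidy_fraction": float(df.loc[~df["arrested"], "any_aneuploidy_call"].mean()),
            "truth_euploid_arrest_fraction": float(df.loc[df["truth_euploid"], "arrested"].mean()),
        },
        table1_analogue=_table1_analogue(df),
        chromosome_counts=_chromosome_counts(results, df),
        tests=analysis["tests"],
        glmm_category=analysis.get("glmm_category"),
        glmm_category_probs=analysis.get("glmm_category_probs"),
        glmm_category_ames=analysis.get("glmm_category_ames"),
        glmm_complexity_ame=analysis.get("glmm_complexity_ame"),
        glmm_division=analysis.get("glmm_division"),
        lmm_biopsy_day=analysis.get("lmm_biopsy_day"),
        embryo_table=df_all,
        calls_table=calling.calls_to_frame(results),
    )
    if outdir is not None:
        write_report(report, embryos, Path(outdir))
    return report


def report_markdown(report: AnalysisReport) -> str:
    s = report.cohort_summary
    lines = [
        "# Simulated cohort analysis report",
        "",
        f"- seed: {report.seed}; config hash: {report.config_hash}",
        f"- patients: {s['n_patients']}; cycles: {s['n_cycles']}; embryos: {s['n_embryos']}"
        f" (tested {s['n_tested']}, QC-excluded {s['n_qc_excluded']})",
        f"- blastulation fraction: {s['blastulation_fraction']:.3f}",
        f"- aneuploidy among arrested: {s['arrested_aneuploidy_fraction']:.3f};"
        f" among blastocysts: {s['blastocyst_aneuploidy_fraction']:.3f}",
        f"- arrest among truth-euploid embryos: {s['truth_euploid_arrest_fraction']:.3f}",
        "",
        "## Five-category table (arrested vs blastocyst)",
        "",
        report.table1_analogue.to_string(index=False),
        "",
        "## Association tests (unadjusted p-values; no multiple-testing correction)",
        "",
        stats.results_to_frame(report.tests).to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        "",
    ]
    if report.glmm_category_probs is not None:
        lines += [
            "## GLMM marginal arrest probability by category",
            "",
            report.glmm_category_probs.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
        ]
    if report.glmm_category_ames is not None:
        lines += [
            "## GLMM AMEs vs Euploid (probability scale)",
            "",
            report.glmm_category_ames.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
        ]
    if report.glmm_complexity_ame is not None:
        a = report.glmm_complexity_ame
        lines += [f"- complexity AME (per aneuploid chromosome): {a.ame:.4f} (SE {a.se:.4f})", ""]
    if report.lmm_biopsy_day is not None:
        m = report.lmm_biopsy_day
        lines += [f"- biopsy-day LMM AME (aneuploid vs euploid): {m.ame:.4f} days (SE {m.se:.4f})", ""]
    return "\n".join(lines)


def write_report(report: AnalysisReport, embryos, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.embryo_table.to_csv(outdir / "embryos.tsv", sep="\t", index=False)
    report.calls_table.to_csv(outdir / "calls.tsv", sep="\t", index=False)
    report.table1_analogue.to_csv(outdir / "table1_analogue.tsv", sep="\t", index=False)
    report.chromosome_counts.to_csv(outdir / "chromosome_counts.tsv", sep="\t", index=False)
    stats.results_to_frame(report.tests).to_csv(outdir / "association_tests.tsv", sep="\t", index=False)
    if report.glmm_category_probs is not None:
        report.glmm_category_probs.to_csv(outdir / "glmm_category_probs.tsv", sep="\t", index=False)
    if report.glmm_category_ames is not None:
        report.glmm_category_ames.to_csv(outdir / "glmm_category_ames.tsv", sep="\t", index=False)
    divs = [
        {"embryo_id": e.embryo_id, "division_index": d.division_index, "pattern": d.pattern,
         "cells_after_first_division": d.cells_after_first_division}
        for e in embryos
        for d in e.divisions
    ]
    pd.DataFrame(divs).to_csv(outdir / "divisions.tsv", sep="\t", index=False)
    (outdir / "report.md").write_text(report_markdown(report))
    (outdir / "run.log").write_text(
        f"seed={report.seed}\nconfig_hash={report.config_hash}\n"
        f"qc_excluded={report.cohort_summary['n_qc_excluded']}\n"
    )


def write_binned_counts(counts_list, genome: GenomeModel, outdir: Path) -> None:
    """One BED-like (chrom, start, end, count) file per sample."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = np.array([c.name for c in genome.chromosomes])[genome.bin_chrom]
    for bc in counts_list:
        df = pd.DataFrame(
            {"chrom": names, "start": genome.bin_start, "end": genome.bin_end, "count": bc.counts}
        )
        df.to_csv(outdir / f"{bc.sample_id}.bed", sep="\t", index=False, header=False)


def read_binned_counts(path: Path, genome: GenomeModel, sample_id: str | None = None, qc_pass: bool = True):
    """Read one BED-like binned-counts file back into BinnedCounts."""
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "count"])
    if len(df) != genome.n_bins:
        raise ValueError(f"{path}: {len(df)} rows != {genome.n_bins} genome bins")
    return sim.BinnedCounts(sample_id or Path(path).stem, df["count"].to_numpy(), qc_pass=qc_pass)
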