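import dataclasses

import numpy as np
import pytest
from scipy.special import expit

from embryocnv import sim
from embryocnv.sim import (
    CellKaryotype,
    ConfigError,
    SimulationConfig,
    _Cell,
    _divide_normal,
    _divide_tripolar,
    sample_meiotic_errors,
    simulate_cleavage,
    simulate_cohort,
    simulate_reads,
)


def _quiet_config(**kw):
    """Config with every error channel off unless overridden."""
    base = dict(
        n_patients=5,
        meiotic_intercept=-np.inf,
        per_division_missegregation_rate=0.0,
        segmental_missegregation_rate=0.0,
        p_abnormal_first_division=0.0,
        p_abnormal_second_division=0.0,
        sex_error_rate=0.0,
        zygotic_segmental_rate=0.0,
        qc_fail_rate=0.0,
        low_dna_fail_rate=0.0,
        seed=11,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestMeioticErrors:
    def test_age_effect_is_logit_linear(self, rng):
        # one year of maternal age multiplies the odds of >= 1 meiotic error
        # by e^0.261 ~ 1.298
        cfg = SimulationConfig(seed=0)
        n = 40_000
        rates = []
        for age in (38.9, 39.9):
            hits = sum(bool(sample_meiotic_errors(age, cfg, rng)) for _ in range(n))
            rates.append(hits / n)
        odds = [r / (1 - r) for r in rates]
        assert odds[1] / odds[0] == pytest.approx(np.exp(0.261), rel=0.06)

    def test_minus_infinity_intercept_disables_errors(self, rng):
        cfg = _quiet_config()
        assert all(sample_meiotic_errors(40.0, cfg, rng) == [] for _ in range(200))

    def test_concentrated_weights_hit_that_chromosome(self, rng):
        w = np.full(22, 1e-4)
        w[15] = 1.0  # chr16
        cfg = SimulationConfig(meiotic_intercept=5.0, meiotic_extra_mean=0.0, chromosome_weights=w / w.sum(), seed=0)
        events = []
        for _ in range(10_000):
            events.extend(sample_meiotic_errors(38.9, cfg, rng))
        frac16 = np.mean([c == 15 for c, _ in events])
        assert frac16 >= 0.99

    def test_errors_apply_to_both_arms(self, rng):
        z = sim.make_zygote([(4, "gain"), (9, "loss")], "XX", _quiet_config(), rng)
        assert tuple(z.copies[4]) == (3, 3)
        assert tuple(z.copies[9]) == (1, 1)


class TestCleavage:
    def test_tripolar_conserves_replicated_chromatids(self, rng):
        # 2 homologs x 2 chromatids = 4 copies of every chromosome are
        # distributed over the 3 daughters, leaving hypodiploid cells
        zygote = CellKaryotype.disomic("XX")
        events = set()
        for _ in range(50):
            daughters = _divide_tripolar(_Cell(zygote.copies.copy()), 0.5, rng, events)
            stack = np.stack([d.copies for d in daughters])
            assert (stack[:, :22].sum(axis=0) == 4).all()
            # pigeonhole: 4 copies over 3 cells leave some cell with <= 1
            assert (stack[:, :22].min(axis=0) <= 1).all()

    def test_reciprocal_missegregation_conserves_copy_number(self, rng):
        mother = _Cell(CellKaryotype.disomic("XY").copies.copy())
        d1, d2 = _divide_normal(mother, 1.0, 0.0, rng, set(), set())
        total = d1.copies.astype(int) + d2.copies.astype(int)
        assert (total == 2 * mother.copies).all()
        assert (d1.copies != d2.copies).any()  # rate 1 forces events

    def test_faithful_mitosis_preserves_karyotype(self, rng):
        cfg = _quiet_config()
        zygote = CellKaryotype.disomic("XY")
        records, ancestors, major, minor, seg = simulate_cleavage(zygote, cfg, rng)
        assert len(ancestors) == 8
        assert not major and not minor and not seg
        for cell in ancestors:
            assert (cell.copies == zygote.copies).all()

    def test_first_division_normal_gives_two_cells_label(self, rng):
        cfg = _quiet_config()
        records, *_ = simulate_cleavage(CellKaryotype.disomic(), cfg, rng)
        assert records[0].pattern == "normal"
        assert records[0].cells_after_first_division == "2"


class TestCohort:
    def test_all_channels_off_yields_fully_euploid_embryos(self):
        cfg = _quiet_config(n_patients=6)
        embryos, _, _ = simulate_cohort(cfg, with_reads=False)
        assert len(embryos) > 0
        for e in embryos:
            assert e.is_truth_euploid
            for cell in e.final_cells:
                assert (cell.copies[:22] == 2).all()

    def test_same_seed_reproduces_identical_cohort(self, coarse_genome):
        cfg = SimulationConfig(n_patients=4, seed=123)
        a = simulate_cohort(cfg, coarse_genome)
        b = simulate_cohort(SimulationConfig(n_patients=4, seed=123), coarse_genome)
        assert len(a[0]) == len(b[0])
        for ea, eb in zip(a[0], b[0]):
            assert ea.embryo_id == eb.embryo_id and ea.outcome == eb.outcome
            assert (ea.zygote_karyotype.copies == eb.zygote_karyotype.copies).all()
        for ca, cb in zip(a[2], b[2]):
            assert (ca.counts == cb.counts).all() and ca.qc_pass == cb.qc_pass

    def test_division_rates_match_configuration(self):
        cfg = SimulationConfig(n_patients=60, seed=5)
        embryos, _, _ = simulate_cohort(cfg, with_reads=False)
        first_abn = np.mean([e.divisions[0].pattern != "normal" for e in embryos])
        n = len(embryos)
        se = np.sqrt(0.26 * 0.74 / n)
        assert abs(first_abn - 0.26) < 3 * se
        second_abn = np.mean(
            [e.divisions[0].pattern == "normal" and e.divisions[1].pattern != "normal" for e in embryos]
        )
        assert abs(second_abn - 0.097 * 0.74) < 4 * np.sqrt(0.072 * 0.928 / n)

    def test_null_arrest_model_matches_baseline(self):
        cfg = _quiet_config(
            n_patients=40,
            arrest_per_chromosome=0.0,
            arrest_abnormal_division=0.0,
            patient_sd=0.0,
        )
        embryos, _, _ = simulate_cohort(cfg, with_reads=False)
        arrested = np.mean([e.outcome != "blastocyst" for e in embryos])
        p0 = expit(cfg.arrest_intercept)
        assert abs(arrested - p0) < 3 * np.sqrt(p0 * (1 - p0) / len(embryos))

    def test_arrest_stage_respects_early_cell_bound(self):
        cfg = SimulationConfig(n_patients=25, seed=9)
        embryos, _, _ = simulate_cohort(cfg, with_reads=False)
        stages = set()
        for e in embryos:
            stages.add(e.outcome)
            if e.outcome == "early_arrest":
                assert e.n_final_cells <= 10
            if e.outcome == "blastocyst":
                assert e.icm_grade in "ABCD" and e.te_grade in "ABCD"
                assert 5 <= e.biopsy_day <= 7
        assert "blastocyst" in stages and "early_arrest" in stages

    def test_biopsy_day_shift_near_configured_value(self):
        cfg = SimulationConfig(n_patients=150, seed=17)
        embryos, _, _ = simulate_cohort(cfg, with_reads=False)
        days_eu, days_an = [], []
        for e in embryos:
            if e.outcome != "blastocyst":
                continue
            (days_an if not e.is_truth_euploid else days_eu).append(e.biopsy_day)
        shift = np.mean(days_an) - np.mean(days_eu)
        # configured per-trial shift 0.11 over 2 trials -> mean day shift 0.22
        assert shift == pytest.approx(0.22, abs=0.09)

    def test_biopsy_samples_have_expected_cell_counts(self, coarse_genome):
        cfg = SimulationConfig(n_patients=10, seed=3)
        embryos, samples, counts = simulate_cohort(cfg, coarse_genome)
        outcomes = {e.embryo_id: e for e in embryos}
        for s, c in zip(samples, counts):
            emb = outcomes[s.embryo_id]
            if s.sample_type == "TE_biopsy":
                assert cfg.biopsy_cells_min <= len(s.cells) <= cfg.biopsy_cells_max
            else:
                assert len(s.cells) == emb.n_final_cells
            assert len(c.counts) == coarse_genome.n_bins


class TestReads:
    def test_expected_depth_linear_in_copy_number(self, coarse_genome):
        # 10 cells, 4 with trisomy 16: mean chr16 copy 2.4 -> 1.2x baseline
        cells = [CellKaryotype.disomic("XX") for _ in range(10)]
        for cell in cells[:4]:
            cell.copies[15] += 1
        cfg = SimulationConfig(read_dispersion=0.0, sequencing_depth=50_000, background_rate=0.0, qc_fail_rate=0.0)
        sample = sim.BiopsySample("s", "e", "TE_biopsy", cells)
        bc = simulate_reads(sample, coarse_genome, cfg, np.random.default_rng(1))
        ratios = bc.counts / np.median(bc.counts[coarse_genome.autosome_bin_mask])
        chr16 = ratios[coarse_genome.bins_of(15)].mean()
        baseline = ratios[coarse_genome.bins_of(0)].mean()
        assert chr16 / baseline == pytest.approx(1.2, abs=0.01)

    def test_triploid_profile_indistinguishable_from_disomy(self, coarse_genome):
        # uniform copy 3 is scale-invariant under median normalization —
        # the documented reason genome-wide ploidy is out of scope
        cells = [CellKaryotype(np.full((24, 2), 3, dtype=np.int16)) for _ in range(5)]
        cfg = SimulationConfig(read_dispersion=0.0, sequencing_depth=60_000, background_rate=0.0, qc_fail_rate=0.0)
        sample = sim.BiopsySample("s", "e", "TE_biopsy", cells)
        bc = simulate_reads(sample, coarse_genome, cfg, np.random.default_rng(2))
        auto = bc.counts[coarse_genome.autosome_bin_mask]
        ratios = auto / np.median(auto)
        assert np.abs(ratios - 1.0).max() < 0.02

    def test_empty_sample_rejected(self, coarse_genome):
        sample = sim.BiopsySample("s", "e", "whole_arrested", [])
        with pytest.raises(ValueError):
            simulate_reads(sample, coarse_genome, SimulationConfig(), np.random.default_rng(0))


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=99, sequencing_depth=123.0)
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        loaded = SimulationConfig.from_yaml(path)
        for f in dataclasses.fields(SimulationConfig):
            a, b = getattr(cfg, f.name), getattr(loaded, f.name)
            if isinstance(a, np.ndarray):
                assert np.allclose(a, b)
            else:
                assert a == b

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("n_patients: 10\nnot_a_key: 1\n")
        with pytest.raises(ConfigError, match="not_a_key"):
            SimulationConfig.from_yaml(path)

    @pytest.mark.parametrize(
        "kw",
        [
            {"qc_fail_rate": 1.5},
            {"sequencing_depth": 0.0},
            {"biopsy_cells_min": 12, "biopsy_cells_max": 10},
            {"chromosome_weights": np.zeros(22)},
        ],
    )
    def test_invalid_configuration_rejected(self, kw):
        with pytest.raises(ConfigError):
            SimulationConfig(**kw)
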