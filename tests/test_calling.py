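import numpy as np
import pytest

from embryocnv import calling
from embryocnv.calling import (
    DegenerateInputError,
    QCError,
    call_sample,
    classify_origin,
    detect_segmental,
    infer_sex,
    normalize_counts,
)
from embryocnv.sim import BinnedCounts, BiopsySample, CellKaryotype, SimulationConfig, simulate_reads

from conftest import disomic_arm_copies, make_counts


def _classify_fraction(f: float) -> str:
    """Analytic oracle: threshold classification of a trisomy present in a
    fraction f of sampled cells (displacement d = 100 f)."""
    d = 100.0 * f
    if d < 30.0:
        return "disomy"
    if d <= 70.0:
        return "mitotic"
    return "meiotic"


class TestNormalization:
    def test_disomic_sample_has_zero_displacement(self, genome):
        profile = normalize_counts(make_counts(genome, disomic_arm_copies("XX")), genome)
        assert profile.chrom_disp[:22].max() == 0.0
        assert np.allclose(profile.chrom_copy[:22], 2.0)

    def test_full_trisomy_21_gives_displacement_100(self, genome):
        arm = disomic_arm_copies("XY")
        arm[20] = 3.0  # chr21 bins at 1.5x baseline
        profile = normalize_counts(make_counts(genome, arm), genome)
        i = 20
        assert profile.chrom_copy[i] == pytest.approx(3.0, abs=1e-9)
        assert profile.chrom_disp[i] == pytest.approx(100.0, abs=1e-6)

    def test_forty_percent_mosaic_trisomy_16(self, genome):
        # 4 of 10 cells trisomic -> mean copy 2.4 -> d = 40
        arm = disomic_arm_copies("XX")
        arm[15] = 2.4
        profile = normalize_counts(make_counts(genome, arm, depth=5040.0), genome)
        assert profile.chrom_disp[15] == pytest.approx(40.0, abs=1.0)

    def test_qc_failed_sample_refused(self, genome):
        bc = make_counts(genome, disomic_arm_copies())
        bc.qc_pass = False
        with pytest.raises(QCError):
            normalize_counts(bc, genome)

    def test_zero_counts_degenerate(self, genome):
        bc = BinnedCounts("z", np.zeros(genome.n_bins, dtype=np.int64), qc_pass=True)
        with pytest.raises(DegenerateInputError):
            normalize_counts(bc, genome)

    def test_many_displaced_autosomes_flagged_unreliable(self, genome):
        arm = disomic_arm_copies("XX")
        arm[10:22] = 3.0  # 12 of 22 autosomes displaced (a minority of bins)
        profile = normalize_counts(make_counts(genome, arm), genome)
        assert profile.baseline_unreliable


class TestClassifyOrigin:
    @pytest.mark.parametrize(
        "d, chrom, scope, expected",
        [
            (85.0, "chr16", "whole", "meiotic"),
            (50.0, "chr3", "whole", "mitotic"),
            (0.0, "chr3", "whole", None),
            (29.999, "chr5", "whole", None),
            (30.0, "chr5", "whole", "mitotic"),
            (70.0, "chr5", "whole", "mitotic"),
            (70.001, "chr5", "whole", "meiotic"),
            (45.0, "chrX", "whole", "not_classified"),
            (45.0, "chr7", "segmental_q", "not_classified"),
            (10.0, "chrX", "whole", None),
        ],
    )
    def test_threshold_rules(self, d, chrom, scope, expected):
        assert classify_origin(d, chrom, scope) == expected

    def test_negative_displacement_rejected(self):
        with pytest.raises(ValueError):
            classify_origin(-1.0, "chr1", "whole")


class TestLinearityAndOracle:
    def test_displacement_linear_in_mosaic_fraction(self, genome):
        # d = 100 f exactly over a noise-free fraction grid
        for k in range(11):
            arm = disomic_arm_copies("XX")
            arm[7] = 2.0 + k / 10.0
            profile = normalize_counts(make_counts(genome, arm, depth=5040.0), genome)
            assert profile.chrom_disp[7] == pytest.approx(100.0 * k / 10.0, abs=1e-6)

    def test_classification_matches_enumeration_oracle(self, genome):
        # every biopsy composition of <= 10 cells with 0..n trisomic cells
        for n in range(1, 11):
            for k in range(n + 1):
                arm = disomic_arm_copies("XX")
                arm[15] = 2.0 + k / n
                profile = normalize_counts(make_counts(genome, arm, depth=5040.0), genome)
                d = float(profile.chrom_disp[15])
                assert d == pytest.approx(100.0 * k / n, abs=1e-6)
                got = classify_origin(d, "chr16", "whole") or "disomy"
                assert got == _classify_fraction(k / n), (n, k, d)

    def test_classification_monotone_in_fraction(self, genome):
        order = {"disomy": 0, "mitotic": 1, "meiotic": 2}
        prev = -1
        for k in range(21):
            arm = disomic_arm_copies("XX")
            arm[3] = 2.0 + k / 20.0
            profile = normalize_counts(make_counts(genome, arm, depth=5040.0), genome)
            got = classify_origin(float(profile.chrom_disp[3]), "chr4", "whole") or "disomy"
            assert order[got] >= prev
            prev = order[got]


class TestSegmental:
    def test_single_arm_loss_called(self, genome):
        arm = disomic_arm_copies("XX")
        arm[4, 1] = 1.5  # 5q bins at 0.75x baseline
        profile = normalize_counts(make_counts(genome, arm), genome)
        calls = detect_segmental(profile, genome)
        assert len(calls) == 1
        c = calls[0]
        assert (c.chrom, c.scope, c.direction) == ("chr5", "segmental_q", "loss")
        assert c.displacement == pytest.approx(50.0, abs=1.0)
        assert c.origin == "not_classified"

    def test_flat_profile_gives_no_segmental_calls(self, genome):
        profile = normalize_counts(make_counts(genome, disomic_arm_copies("XY")), genome)
        assert detect_segmental(profile, genome) == []

    def test_whole_chromosome_takes_precedence(self, genome):
        arm = disomic_arm_copies("XX")
        arm[6] = 3.0  # both chr7 arms gained
        profile = normalize_counts(make_counts(genome, arm), genome)
        seg = detect_segmental(profile, genome)
        assert all(c.chrom != "chr7" for c in seg)
        result = call_sample(make_counts(genome, arm), genome)
        chr7 = [c for c in result.calls if c.chrom == "chr7"]
        assert len(chr7) == 1 and chr7[0].scope == "whole"


class TestSexInference:
    def test_normal_male(self, genome):
        profile = normalize_counts(make_counts(genome, disomic_arm_copies("XY")), genome)
        sex, calls = infer_sex(profile, genome)
        assert sex == "XY" and calls == []

    def test_normal_female(self, genome):
        profile = normalize_counts(make_counts(genome, disomic_arm_copies("XX")), genome)
        sex, calls = infer_sex(profile, genome)
        assert sex == "XX" and calls == []

    def test_male_x_gain_not_classified(self, genome):
        arm = disomic_arm_copies("XY")
        arm[22] = 1.5  # X at 0.75x autosomal baseline vs 1-copy expectation
        profile = normalize_counts(make_counts(genome, arm), genome)
        sex, calls = infer_sex(profile, genome)
        assert sex == "XY"
        assert len(calls) == 1
        assert calls[0].chrom == "chrX" and calls[0].direction == "gain"
        assert calls[0].displacement == pytest.approx(50.0, abs=1.0)
        assert calls[0].origin == "not_classified"

    def test_ambiguous_y_suppresses_sex_calls(self, genome):
        arm = disomic_arm_copies("XX")
        arm[23] = 0.5  # Y at 0.25x: inside the ambiguous window
        profile = normalize_counts(make_counts(genome, arm), genome)
        sex, calls = infer_sex(profile, genome)
        assert sex == "uncertain" and calls == []


class TestCallSample:
    def test_flagged_sample_returns_qc_marker(self, genome):
        bc = make_counts(genome, disomic_arm_copies())
        bc.qc_pass = False
        result = call_sample(bc, genome)
        assert result.qc_excluded and result.qc_reason == "flagged_qc_fail"

    def test_noisy_sample_excluded(self, genome, rng):
        base = make_counts(genome, disomic_arm_copies()).counts.astype(float)
        noisy = np.round(base * np.exp(rng.normal(0, 0.8, base.shape))).astype(np.int64)
        result = call_sample(BinnedCounts("noisy", noisy, qc_pass=True), genome)
        assert result.qc_excluded and result.qc_reason == "excessive_noise"

    def test_meiotic_trisomy_21_end_to_end(self, genome):
        cells = [CellKaryotype.disomic("XX") for _ in range(8)]
        for cell in cells:
            cell.copies[20] += 1
        cfg = SimulationConfig(qc_fail_rate=0.0)
        sample = BiopsySample("s1", "e1", "TE_biopsy", cells)
        bc = simulate_reads(sample, genome, cfg, np.random.default_rng(42))
        result = call_sample(bc, genome)
        assert not result.qc_excluded
        assert len(result.autosomal_calls) == 1
        c = result.autosomal_calls[0]
        assert (c.chrom, c.direction, c.origin, c.scope) == ("chr21", "gain", "meiotic", "whole")

    def test_euploid_specificity_at_default_depth(self, genome):
        cfg = SimulationConfig(qc_fail_rate=0.0)
        cells = [CellKaryotype.disomic("XY") for _ in range(6)]
        sample = BiopsySample("s", "e", "TE_biopsy", cells)
        clean = 0
        n_rep = 40
        for rep in range(n_rep):
            bc = simulate_reads(sample, genome, cfg, np.random.default_rng(1000 + rep))
            result = call_sample(bc, genome)
            if not result.qc_excluded and not result.calls:
                clean += 1
        assert clean / n_rep >= 0.95
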