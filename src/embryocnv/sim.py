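"""Synthetic IVF embryo cohorts with meiotic and mitotic (mosaic) aneuploidy.

The generator reproduces the statistical structure the downstream analysis
assumes: patients contribute one or more IVF cycles; each normally fertilized
zygote may carry whole-chromosome meiotic errors whose probability rises with
maternal age on the logit scale; the first two cleavage divisions may be
abnormal (multipolar, precocious, reverse, failed), seeding mosaic mitotic
aneuploidy mechanically through chromatid mis-distribution; embryos arrest or
blastulate under a logistic model with a per-patient random intercept; and
each sampled embryo (5-10-cell trophectoderm biopsy, or the whole cell mass
of an arrested embryo) yields negative-binomial binned read counts whose
expectation is linear in the mean cell copy number.

Mosaic fractions in a biopsy are never drawn directly: they emerge from
lineage sampling, so the intermediate (30-70%) copy-number displacements the
caller looks for are a consequence of the division model, not an input.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .genome import GenomeModel

N_CHROMS = 24  # 22 autosomes + X + Y (indices 22, 23)
X, Y = 22, 23

PATTERNS = ("normal", "multipolar", "precocious", "reverse", "failed")

#: chromosomes with elevated meiotic-error rates (1-based names 15,16,19,21,22)
HIGH_RISK_AUTOSOMES = (14, 15, 18, 20, 21)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_chromosome_weights() -> np.ndarray:
    w = np.ones(22)
    w[list(HIGH_RISK_AUTOSOMES)] = 3.0
    return w / w.sum()


@dataclass
class SimulationConfig:
    """All tunable parameters of the cohort generator.

    Defaults encode the study conditions: 125 patients / ~165 cycles, mean
    maternal age 38.9 (range 30-45), ~7.2 zygotes per cycle, a meiotic-error
    age trend of 0.261 logits per year, a flat mitotic age trend (0.009),
    26.0% / 9.7% abnormal first / second divisions, a 16% euploid arrest
    baseline, 5-10-cell biopsies and a 3.2% QC failure rate.
    """

    n_patients: int = 125
    extra_cycles_rate: float = 0.32  # extra cycles per patient, Poisson mean
    zygotes_per_cycle_mean: float = 7.2
    maternal_age_mean: float = 38.9
    maternal_age_sd: float = 3.5
    maternal_age_min: float = 30.0
    maternal_age_max: float = 45.0

    meiotic_intercept: float = 0.80  # logit P(>=1 meiotic error) at mean age
    meiotic_age_slope: float = 0.261  # logits per year of maternal age
    meiotic_extra_mean: float = 1.0  # Poisson mean of additional meiotic errors
    mitotic_age_slope: float = 0.009  # logits per year, on abnormal-division risk
    chromosome_weights: np.ndarray = field(default_factory=_default_chromosome_weights)
    sex_error_rate: float = 0.01
    zygotic_segmental_rate: float = 0.10  # arm-scale errors present in all cells

    p_abnormal_first_division: float = 0.26
    p_abnormal_second_division: float = 0.097
    abnormal_pattern_probs: tuple = (0.40, 0.35, 0.12, 0.13)  # multipolar/precocious/reverse/failed
    tripolar_coordination: float = 0.55
    chaos_after_polyploid: float = 0.9
    per_division_missegregation_rate: float = 0.0005  # per chromosome per division
    segmental_missegregation_rate: float = 0.0004

    arrest_intercept: float = -1.66  # logit of the 0.16 euploid arrest baseline
    arrest_per_chromosome: float = 0.60  # per aneuploid autosome, capped at 5
    arrest_abnormal_division: float = 1.6
    patient_sd: float = 0.5  # random-intercept SD, logit scale

    clone_fitness_penalty: float = 0.0  # per unit copy-number burden, clone growth
    blastocyst_cells_mean: float = 110.0
    blastocyst_cells_sd: float = 20.0
    biopsy_cells_min: int = 5
    biopsy_cells_max: int = 10

    sequencing_depth: float = 300.0  # mean reads per bin at copy number 2
    read_dispersion: float = 0.005  # NB overdispersion; 0 -> Poisson
    background_rate: float = 0.01  # reads per bin per unit depth, copy-independent
    qc_fail_rate: float = 0.02  # base QC failure probability per sample
    low_dna_fail_rate: float = 0.35  # QC failure for whole-embryo samples of <= 5 cells

    grade_aneuploidy_shift: float = 1.0  # latent ordinal shift toward grade D
    biopsy_day_base_p: float = 0.35  # day = 5 + Binomial(2, p)
    biopsy_day_aneuploidy_shift: float = 0.11  # per-trial shift; mean day shift 0.22

    seed: int = 0

    def __post_init__(self) -> None:
        self.chromosome_weights = np.asarray(self.chromosome_weights, dtype=float)
        self.validate()

    def validate(self) -> None:
        probs = {
            "p_abnormal_first_division": self.p_abnormal_first_division,
            "p_abnormal_second_division": self.p_abnormal_second_division,
            "per_division_missegregation_rate": self.per_division_missegregation_rate,
            "segmental_missegregation_rate": self.segmental_missegregation_rate,
            "sex_error_rate": self.sex_error_rate,
            "zygotic_segmental_rate": self.zygotic_segmental_rate,
            "qc_fail_rate": self.qc_fail_rate,
            "low_dna_fail_rate": self.low_dna_fail_rate,
            "tripolar_coordination": self.tripolar_coordination,
            "chaos_after_polyploid": self.chaos_after_polyploid,
            "biopsy_day_base_p": self.biopsy_day_base_p,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        if self.chromosome_weights.shape != (22,) or (self.chromosome_weights < 0).any():
            raise ConfigError("chromosome_weights must be 22 nonnegative values")
        if self.chromosome_weights.sum() <= 0:
            raise ConfigError("chromosome_weights must not all be zero")
        if self.sequencing_depth <= 0:
            raise ConfigError("sequencing_depth must be positive")
        if not (1 <= self.biopsy_cells_min <= self.biopsy_cells_max):
            raise ConfigError("biopsy cell bounds must satisfy 1 <= min <= max")
        if abs(sum(self.abnormal_pattern_probs) - 1.0) > 1e-9:
            raise ConfigError("abnormal_pattern_probs must sum to 1")

    # -- YAML round trip ------------------------------------------------------

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["chromosome_weights"] = [float(w) for w in self.chromosome_weights]
        d["abnormal_pattern_probs"] = list(self.abnormal_pattern_probs)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "abnormal_pattern_probs" in d:
            d["abnormal_pattern_probs"] = tuple(d["abnormal_pattern_probs"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Core domain types
# ---------------------------------------------------------------------------


@dataclass
class CellKaryotype:
    """Integer copy number per chromosome arm for one cell.

    ``copies`` has shape (24, 2): rows are chr1..chr22, chrX, chrY; columns
    are the p and q arms.  A disomic female cell is 2 everywhere except chrY.
    """

    copies: np.ndarray

    def __post_init__(self) -> None:
        self.copies = np.asarray(self.copies, dtype=np.int16)
        if self.copies.shape != (N_CHROMS, 2):
            raise ValueError("karyotype must have shape (24, 2)")
        if (self.copies < 0).any():
            raise ValueError("copy numbers must be nonnegative")

    @classmethod
    def disomic(cls, sex: str = "XX") -> "CellKaryotype":
        c = np.full((N_CHROMS, 2), 2, dtype=np.int16)
        if sex == "XY":
            c[X] = 1
            c[Y] = 1
        else:
            c[Y] = 0
        return cls(c)

    def copy(self) -> "CellKaryotype":
        return CellKaryotype(self.copies.copy())


@dataclass
class DivisionRecord:
    division_index: int  # 1 or 2
    pattern: str  # normal / multipolar / precocious / reverse / failed
    cells_after_first_division: str = ""  # '1','2','3','4','>4' (division 1 only)

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown division pattern {self.pattern!r}")


@dataclass
class EmbryoRecord:
    embryo_id: str
    patient_id: str
    cycle_id: str
    maternal_age: float
    zygote_karyotype: CellKaryotype
    meiotic_calls_truth: list  # [(chrom_index, 'gain'|'loss'), ...]
    divisions: list  # [DivisionRecord, ...]
    clones: list  # [(CellKaryotype, n_cells), ...] after expansion
    mitotic_chroms_truth: set  # autosome indices hit by mitotic events
    segmental_truth: set  # (chrom_index, arm) pairs, zygotic or mitotic
    outcome: str  # early_arrest / mid_arrest / late_arrest / blastocyst
    icm_grade: str | None = None
    te_grade: str | None = None
    biopsy_day: int | None = None

    @property
    def final_cells(self) -> list:
        """Expanded list of CellKaryotype for every final cell."""
        out = []
        for karyo, n in self.clones:
            out.extend(karyo for _ in range(n))
        return out

    @property
    def n_final_cells(self) -> int:
        return sum(n for _, n in self.clones)

    @property
    def abnormal_division(self) -> bool:
        return any(d.pattern != "normal" for d in self.divisions)

    @property
    def is_truth_euploid(self) -> bool:
        """No meiotic errors, no mitotic per-chromosome events, no segmentals."""
        return (
            not self.meiotic_calls_truth
            and not self.mitotic_chroms_truth
            and not self.segmental_truth
        )

    @property
    def n_aneuploid_truth(self) -> int:
        chroms = {c for c, _ in self.meiotic_calls_truth} | set(self.mitotic_chroms_truth)
        chroms |= {c for c, _ in self.segmental_truth}
        return len([c for c in chroms if c < 22])


@dataclass
class BiopsySample:
    sample_id: str
    embryo_id: str
    sample_type: str  # 'TE_biopsy' | 'whole_arrested'
    cells: list  # [CellKaryotype, ...]

    def __post_init__(self) -> None:
        if self.sample_type == "TE_biopsy" and not (1 <= len(self.cells) <= 20):
            raise ValueError("TE biopsy must contain a handful of cells")

    def mean_arm_copies(self) -> np.ndarray:
        stack = np.stack([c.copies for c in self.cells])
        return stack.mean(axis=0)


@dataclass
class BinnedCounts:
    sample_id: str
    counts: np.ndarray  # per-bin nonnegative integers, aligned to a GenomeModel
    qc_pass: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------


def sample_meiotic_errors(age: float, config: SimulationConfig, rng) -> list:
    """Whole-chromosome meiotic gains/losses for one zygote.

    The probability of carrying at least one error follows
    ``invlogit(intercept + slope * (age - age_mean))``; affected autosomes are
    drawn by the configured weights (without replacement), with one extra
    error count drawn Poisson so complex meiotic karyotypes occur.
    """
    p_any = expit(config.meiotic_intercept + config.meiotic_age_slope * (age - config.maternal_age_mean))
    if rng.random() >= p_any:
        return []
    n_errors = 1 + rng.poisson(config.meiotic_extra_mean)
    n_errors = min(n_errors, 22)
    w = config.chromosome_weights / config.chromosome_weights.sum()
    chroms = rng.choice(22, size=n_errors, replace=False, p=w)
    return [(int(c), "gain" if rng.random() < 0.5 else "loss") for c in chroms]


def make_zygote(meiotic_errors: list, sex: str, config: SimulationConfig, rng) -> CellKaryotype:
    z = CellKaryotype.disomic(sex)
    for chrom, direction in meiotic_errors:
        step = 1 if direction == "gain" else -1
        z.copies[chrom] = np.maximum(z.copies[chrom] + step, 0)
    if rng.random() < config.sex_error_rate:
        chrom = X if sex == "XX" or rng.random() < 0.5 else Y
        step = 1 if rng.random() < 0.5 else -1
        z.copies[chrom] = np.maximum(z.copies[chrom] + step, 0)
    return z


# ---------------------------------------------------------------------------
# Cleavage
# ---------------------------------------------------------------------------


class _Cell:
    __slots__ = ("copies", "polyploid")

    def __init__(self, copies: np.ndarray, polyploid: bool = False):
        self.copies = copies
        self.polyploid = polyploid


def _divide_normal(cell: _Cell, rate: float, seg_rate: float, rng, events: set, seg_events: set):
    """Bipolar division with reciprocal per-chromosome missegregation."""
    d1 = cell.copies.copy()
    d2 = cell.copies.copy()
    if rate > 0:
        for chrom in np.nonzero(rng.random(N_CHROMS) < rate)[0]:
            if cell.copies[chrom].min() < 1:
                continue
            s = 1 if rng.random() < 0.5 else -1
            d1[chrom] += s
            d2[chrom] -= s
            if chrom < 22:
                events.add(int(chrom))
    if seg_rate > 0:
        for chrom in np.nonzero(rng.random(N_CHROMS) < seg_rate)[0]:
            arm = int(rng.integers(2))
            if cell.copies[chrom, arm] < 1:
                continue
            s = 1 if rng.random() < 0.5 else -1
            d1[chrom, arm] += s
            d2[chrom, arm] -= s
            if chrom < 22:
                seg_events.add((int(chrom), arm))
    return [_Cell(d1, cell.polyploid), _Cell(d2, cell.polyploid)]


def _divide_tripolar(cell: _Cell, coord_p: float, rng, events: set):
    """Tripolar mitosis: each chromosome's replicated chromatids (2 per
    homolog) are pulled to 2 of the 3 spindle poles, so the daughters'
    per-chromosome copies sum to twice the mother's and hypodiploid,
    partially complementary clones arise."""
    daughters = np.zeros((3, N_CHROMS, 2), dtype=np.int16)
    for chrom in range(N_CHROMS):
        v = cell.copies[chrom]
        h = int(v.max())
        if h == 0:
            continue
        coordinated = rng.random() < coord_p
        shared = tuple(rng.choice(3, size=2, replace=False))
        for k in range(h):
            poles = shared if coordinated else tuple(rng.choice(3, size=2, replace=False))
            for arm in range(2):
                if v[arm] > k:
                    for pole in poles:
                        daughters[pole, chrom, arm] += 1
        if chrom < 22:
            events.add(chrom)
    return [_Cell(daughters[i]) for i in range(3)]


def simulate_cleavage(zygote: CellKaryotype, config: SimulationConfig, rng, age: float | None = None):
    """Simulate the first three division rounds of one embryo.

    Returns ``(division_records, ancestor_cells, mitotic_chroms, segmental_chroms)``
    where ``ancestor_cells`` are the clone founders whose descendants make up
    the final embryo, in lineage order (adjacent cells are lineage
    neighbours).
    """
    if age is None:
        age = config.maternal_age_mean
    rate = config.per_division_missegregation_rate
    seg_rate = config.segmental_missegregation_rate
    events: set = set()  # rounds 1-2: events hitting a large cell fraction
    minor_events: set = set()  # round 3: events confined to ~1/8 of the embryo
    seg_events: set = set()
    records: list = []

    # the mitotic age trend acts on every mitotic-error channel (division
    # abnormality and per-chromosome missegregation) on the logit scale, so
    # the marginal P(mitotic error | age) follows the configured slope
    age_term = config.mitotic_age_slope * (age - config.maternal_age_mean)
    p_abn1 = expit(logit(config.p_abnormal_first_division) + age_term) if config.p_abnormal_first_division > 0 else 0.0
    p_abn2 = expit(logit(config.p_abnormal_second_division) + age_term) if config.p_abnormal_second_division > 0 else 0.0
    if 0.0 < rate < 1.0:
        rate = float(expit(logit(rate) + age_term))
    if 0.0 < seg_rate < 1.0:
        seg_rate = float(expit(logit(seg_rate) + age_term))

    cells = [_Cell(zygote.copies.copy())]

    # --- division 1 ---------------------------------------------------------
    first_abnormal = rng.random() < p_abn1
    if first_abnormal:
        pattern = PATTERNS[1:][rng.choice(4, p=np.asarray(config.abnormal_pattern_probs))]
    else:
        pattern = "normal"
    cell = cells[0]
    if pattern == "normal":
        cells = _divide_normal(cell, rate, seg_rate, rng, events, seg_events)
        cells_after = "2"
    elif pattern == "multipolar":
        cells = _divide_tripolar(cell, config.tripolar_coordination, rng, events)
        cells_after = "3" if rng.random() < 0.8 else "4"
    elif pattern == "precocious":
        cells = _divide_normal(cell, rate, seg_rate, rng, events, seg_events)
        # premature, error-prone division of one daughter within the first
        # annotation window; modelled as a tripolar split of that daughter
        j = int(rng.integers(2))
        rushed = _divide_tripolar(cells[j], config.tripolar_coordination, rng, events)
        cells = cells[:j] + rushed + cells[j + 1 :]
        cells_after = "3"
    elif pattern == "reverse":
        merged = _Cell(cell.copies * 2, polyploid=True)
        cells = [merged]
        cells_after = "1"
    else:  # failed
        cells = [_Cell(cell.copies * 2, polyploid=True)]
        cells_after = "1"
    records.append(DivisionRecord(1, pattern, cells_after))

    # --- division 2 ---------------------------------------------------------
    second_abnormal = (not first_abnormal) and rng.random() < p_abn2
    pattern2 = "multipolar" if second_abnormal else "normal"
    chaotic_index = int(rng.integers(len(cells))) if second_abnormal else -1
    nxt: list = []
    for i, c in enumerate(cells):
        if i == chaotic_index or (c.polyploid and rng.random() < config.chaos_after_polyploid):
            nxt.extend(_divide_tripolar(c, config.tripolar_coordination, rng, events))
        else:
            nxt.extend(_divide_normal(c, rate, seg_rate, rng, events, seg_events))
    cells = nxt
    records.append(DivisionRecord(2, pattern2))

    # --- division 3 ---------------------------------------------------------
    nxt = []
    for c in cells:
        if c.polyploid and rng.random() < config.chaos_after_polyploid:
            nxt.extend(_divide_tripolar(c, config.tripolar_coordination, rng, events))
        else:
            nxt.extend(_divide_normal(c, rate, seg_rate, rng, minor_events, seg_events))
    cells = nxt

    ancestors = [CellKaryotype(c.copies) for c in cells]
    return records, ancestors, events, minor_events, seg_events


# ---------------------------------------------------------------------------
# Outcome
# ---------------------------------------------------------------------------

GRADES = ("A", "B", "C", "D")
_GRADE_CUTS = (-1.2, -0.2, 0.8)


def assign_outcome(
    n_aneuploid: int,
    abnormal_division: bool,
    any_aneuploidy: bool,
    patient_effect: float,
    config: SimulationConfig,
    rng,
):
    """Draw (outcome, total_cells, icm_grade, te_grade, biopsy_day).

    Arrest probability is ``invlogit(b0 + b1*min(n,5) + b2*abnormal +
    patient_effect)``; arrest stage skews earlier for more abnormal lineages;
    blastocyst grades come from a shared latent ordinal score shifted toward
    D under aneuploidy, and biopsy day is 5 + Binomial(2, p) with p shifted
    upward by aneuploidy so the mean day shifts by ~0.22.
    """
    eta = (
        config.arrest_intercept
        + config.arrest_per_chromosome * min(n_aneuploid, 5)
        + config.arrest_abnormal_division * float(abnormal_division)
        + patient_effect
    )
    if rng.random() < expit(eta):
        score = min(n_aneuploid, 5) + 2.0 * float(abnormal_division) + rng.normal(0, 1.5)
        if score > 4.0:
            outcome, n_cells = "early_arrest", int(rng.integers(2, 11))
        elif score > 2.0:
            outcome, n_cells = "mid_arrest", int(rng.integers(11, 31))
        else:
            outcome, n_cells = "late_arrest", int(rng.integers(31, 81))
        return outcome, n_cells, None, None, None

    n_cells = int(np.clip(rng.normal(config.blastocyst_cells_mean, config.blastocyst_cells_sd), 60, 180))
    latent = rng.normal() + config.grade_aneuploidy_shift * float(any_aneuploidy)
    icm = GRADES[int(np.searchsorted(_GRADE_CUTS, latent + rng.normal(0, 0.4)))]
    te = GRADES[int(np.searchsorted(_GRADE_CUTS, latent + rng.normal(0, 0.4)))]
    p_day = float(np.clip(
        config.biopsy_day_base_p
        + config.biopsy_day_aneuploidy_shift * float(any_aneuploidy)
        + 0.1 * patient_effect,
        0.0, 1.0,
    ))
    day = 5 + int(rng.binomial(2, p_day))
    return "blastocyst", n_cells, icm, te, day


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def simulate_reads(sample: BiopsySample, genome: GenomeModel, config: SimulationConfig, rng) -> BinnedCounts:
    """Binned read counts whose expectation is linear in mean cell copy number.

    Expected count in bin b = depth * (mean copy of b's arm across sampled
    cells) / 2, plus a small copy-independent background; counts are negative
    binomial (Poisson when ``read_dispersion`` is 0).  QC failures corrupt
    the depth profile with heavy multiplicative noise.
    """
    if not sample.cells:
        raise ValueError(f"sample {sample.sample_id} contains no cells")
    mean_copies = sample.mean_arm_copies()  # (24, 2)
    mu = config.sequencing_depth * mean_copies[genome.bin_chrom, genome.bin_arm] / 2.0
    mu = mu + config.sequencing_depth * config.background_rate
    # whole-embryo samples from very early arrests carry little input DNA and
    # fail amplification far more often than trophectoderm biopsies
    p_fail = config.qc_fail_rate
    if sample.sample_type == "whole_arrested" and len(sample.cells) <= 5:
        p_fail = max(p_fail, config.low_dna_fail_rate)
    qc_pass = rng.random() >= p_fail
    if not qc_pass:
        mu = mu * np.exp(rng.normal(0.0, 0.9, size=mu.shape))
    if config.read_dispersion > 0:
        n = 1.0 / config.read_dispersion
        counts = rng.negative_binomial(n, n / (n + mu))
    else:
        counts = rng.poisson(mu)
    return BinnedCounts(sample.sample_id, counts, qc_pass=qc_pass)


# ---------------------------------------------------------------------------
# Cohort orchestration
# ---------------------------------------------------------------------------


def _truncated_normal(mean, sd, lo, hi, rng) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(x, lo, hi))


def _clone_burden(karyo: CellKaryotype) -> float:
    """Aneuploidy burden of a clone founder: summed per-chromosome copy
    deviation from disomy over the autosomes (arms averaged)."""
    dev = np.abs(karyo.copies[:22].astype(float) - 2.0)
    return float(dev.mean(axis=1).sum())


def _expand_clones(ancestors: list, total_cells: int, penalty: float, rng) -> list:
    """Multinomial clone expansion with Dirichlet-varied proportions tilted
    against aneuploid clones: growth weight is damped by
    ``exp(-penalty * (burden - min_burden))``, so the least-aneuploid
    lineages dominate and chaotic divisions leave sparse, chromosome-specific
    mosaic displacement rather than a uniform (normalized-away) shift."""
    k = len(ancestors)
    burden = np.array([_clone_burden(a) for a in ancestors])
    fitness = np.exp(-penalty * (burden - burden.min()))
    weights = rng.dirichlet(np.full(k, 1.0)) * fitness
    weights /= weights.sum()
    counts = rng.multinomial(total_cells, weights)  # founders may die out
    return [(ancestors[i], int(counts[i])) for i in range(k) if counts[i] > 0]


def _te_biopsy_cells(clones: list, n_cells: int, rng) -> list:
    """Sample a contiguous window of cells from the lineage-ordered clones,
    emulating the spatial clustering of a trophectoderm biopsy."""
    seq = []
    for karyo, n in clones:
        seq.extend([karyo] * n)
    start = int(rng.integers(len(seq)))
    return [seq[(start + i) % len(seq)] for i in range(min(n_cells, len(seq)))]


def simulate_cohort(config: SimulationConfig, genome: GenomeModel | None = None, with_reads: bool = True):
    """Simulate a full cohort.

    Returns ``(embryos, samples, counts)``; ``samples`` and ``counts`` are
    empty when ``with_reads`` is False (truth-only simulation for statistical
    calibration work).  Fully reproducible given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    # separate stream for biopsy sampling and sequencing noise, so the truth
    # cohort is identical whether or not reads are generated
    rng_reads = np.random.default_rng((config.seed, 1))
    embryos: list = []
    samples: list = []
    counts: list = []
    e_ix = s_ix = 0

    for p in range(config.n_patients):
        patient_id = f"P{p + 1:03d}"
        age = _truncated_normal(
            config.maternal_age_mean, config.maternal_age_sd,
            config.maternal_age_min, config.maternal_age_max, rng,
        )
        patient_effect = rng.normal(0.0, config.patient_sd) if config.patient_sd > 0 else 0.0
        n_cycles = 1 + rng.poisson(config.extra_cycles_rate)
        for cyc in range(n_cycles):
            cycle_id = f"{patient_id}-C{cyc + 1}"
            n_zygotes = max(int(rng.poisson(config.zygotes_per_cycle_mean)), 1)
            for _ in range(n_zygotes):
                e_ix += 1
                embryo_id = f"E{e_ix:04d}"
                sex = "XX" if rng.random() < 0.5 else "XY"
                meiotic = sample_meiotic_errors(age, config, rng)
                zygote = make_zygote(meiotic, sex, config, rng)
                seg_truth: set = set()
                if rng.random() < config.zygotic_segmental_rate:
                    chrom = int(rng.integers(22))
                    arm = int(rng.integers(2))
                    s = 1 if rng.random() < 0.5 else -1
                    if zygote.copies[chrom, arm] + s >= 0:
                        zygote.copies[chrom, arm] += s
                        seg_truth.add((chrom, arm))

                records, ancestors, mito_major, mito_minor, seg_mito = simulate_cleavage(
                    zygote, config, rng, age
                )
                seg_truth |= seg_mito
                mito = mito_major | mito_minor
                abnormal = any(r.pattern != "normal" for r in records)
                meio_chroms = {c for c, _ in meiotic}
                any_aneu = bool(meio_chroms or mito or seg_truth)
                # arrest risk scales with the compromised cell fraction:
                # third-round events (confined to ~1/8 of cells) are excluded
                n_major = len({c for c in (meio_chroms | mito_major | {c for c, _ in seg_truth}) if c < 22})

                outcome, n_cells, icm, te, day = assign_outcome(
                    n_major, abnormal, any_aneu, patient_effect, config, rng
                )
                clones = _expand_clones(ancestors, n_cells, config.clone_fitness_penalty, rng)
                emb = EmbryoRecord(
                    embryo_id=embryo_id,
                    patient_id=patient_id,
                    cycle_id=cycle_id,
                    maternal_age=age,
                    zygote_karyotype=zygote,
                    meiotic_calls_truth=meiotic,
                    divisions=records,
                    clones=clones,
                    mitotic_chroms_truth=mito,
                    segmental_truth=seg_truth,
                    outcome=outcome,
                    icm_grade=icm,
                    te_grade=te,
                    biopsy_day=day,
                )
                embryos.append(emb)

                if with_reads:
                    s_ix += 1
                    sample_id = f"S{s_ix:04d}"
                    if outcome == "blastocyst":
                        k = int(rng_reads.integers(config.biopsy_cells_min, config.biopsy_cells_max + 1))
                        cells = _te_biopsy_cells(clones, k, rng_reads)
                        sample = BiopsySample(sample_id, embryo_id, "TE_biopsy", cells)
                    else:
                        sample = BiopsySample(sample_id, embryo_id, "whole_arrested", emb.final_cells)
                    samples.append(sample)
                    counts.append(simulate_reads(sample, genome, config, rng_reads))
    return embryos, samples, counts


def embryos_to_frame(embryos: list) -> pd.DataFrame:
    """Tidy per-embryo truth table used by the statistics modules."""
    rows = []
    for e in embryos:
        first = e.divisions[0] if e.divisions else None
        rows.append(
            {
                "embryo_id": e.embryo_id,
                "patient_id": e.patient_id,
                "cycle_id": e.cycle_id,
                "maternal_age": e.maternal_age,
                "n_meiotic_truth": len({c for c, _ in e.meiotic_calls_truth}),
                "n_mitotic_truth": len(e.mitotic_chroms_truth),
                "n_segmental_truth": len(e.segmental_truth),
                "meiotic_truth": bool(e.meiotic_calls_truth),
                "mitotic_truth": bool(e.mitotic_chroms_truth),
                "truth_euploid": e.is_truth_euploid,
                "abnormal_division": e.abnormal_division,
                "first_division_pattern": first.pattern if first else "",
                "cells_after_first_division": first.cells_after_first_division if first else "",
                "outcome": e.outcome,
                "arrested": e.outcome != "blastocyst",
                "icm_grade": e.icm_grade or "",
                "te_grade": e.te_grade or "",
                "biopsy_day": e.biopsy_day if e.biopsy_day is not None else np.nan,
                "n_final_cells": e.n_final_cells,
            }
        )
    return pd.DataFrame(rows)
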