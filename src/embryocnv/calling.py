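"""Copy-number displacement calling from binned read counts.

Bulk low-coverage sequencing of a multi-cell sample (trophectoderm biopsy or
whole arrested embryo) averages chromosome copy number across cells, so the
normalized read depth of a chromosome sits anywhere between the disomic
baseline and a full single-copy change.  The *displacement* d expresses the
deviation as a percentage of a full copy change (d = |c_hat - 2| x 100 for
autosomes).  Whole-autosome displacements above 70% are called meiotic in
origin (present in all cells), displacements between 30 and 70% are called
mitotic (mosaic), and values below 30% are treated as normal disomy.  Sex
chromosomes and arm-scale segmental events are called but never stratified
into meiotic/mitotic origin classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import trim_mean

from .genome import GenomeModel, P_ARM, Q_ARM

#: displacement thresholds, percent of a full single-copy change
DISOMY_MAX = 30.0
MEIOTIC_MIN = 70.0

#: displacements are rounded to this many decimals before thresholding, so
#: analytically exact fractions (e.g. 3 trisomic cells of 10 -> d = 30) land
#: on the boundary rather than a half-ulp away
_DISP_DECIMALS = 6

TRIM = 0.1  # fraction trimmed from each tail for per-chromosome means

DEFAULT_QC_NOISE_THRESHOLD = 0.15

#: arms represented by fewer bins than this have too little signal for
#: arm-level inference; calling falls back to the chromosome scale
MIN_ARM_BINS = 5

Y_AMBIGUOUS = (0.15, 0.35)
Y_MALE_MIN = 0.25


class QCError(RuntimeError):
    """Raised when calling is attempted on a QC-failed sample."""


class DegenerateInputError(ValueError):
    """Raised for inputs on which normalization is undefined (zero median)."""


@dataclass
class AneuploidyCall:
    """One chromosome- or arm-level aneuploidy event."""

    chrom: str
    scope: str  # 'whole' | 'segmental_p' | 'segmental_q'
    direction: str  # 'gain' | 'loss'
    displacement: float  # percent of a full single-copy change
    origin: str  # 'meiotic' | 'mitotic' | 'not_classified'

    def __post_init__(self) -> None:
        if self.scope not in ("whole", "segmental_p", "segmental_q"):
            raise ValueError(f"bad scope {self.scope!r}")
        if self.origin not in ("meiotic", "mitotic", "not_classified"):
            raise ValueError(f"bad origin {self.origin!r}")


@dataclass
class CopyNumberProfile:
    """Normalized per-bin ratios plus per-chromosome copy estimates."""

    sample_id: str
    ratios: np.ndarray  # per-bin normalized depth, 1.0 = disomic expectation
    chrom_copy: np.ndarray  # c_hat per chromosome (24,)
    chrom_disp: np.ndarray  # displacement vs disomy, percent (24,)
    arm_copy: np.ndarray  # c_hat per (chromosome, arm), (24, 2)
    noise_score: float  # median absolute pairwise (adjacent-bin) deviation
    baseline_unreliable: bool = False
    sex: str = ""  # filled by infer_sex: 'XX' | 'XY' | 'uncertain'
    notes: list = field(default_factory=list)


def _arm_stat(ratios: np.ndarray, genome: GenomeModel, chrom: int, arm: int) -> float:
    vals = ratios[genome.bins_of(chrom, arm)]
    if len(vals) == 0:
        return np.nan
    return float(trim_mean(vals, TRIM))


def _round_disp(d) -> np.ndarray:
    return np.round(d, _DISP_DECIMALS)


def noise_score(ratios: np.ndarray, genome: GenomeModel) -> float:
    """Median absolute pairwise deviation (MAPD) between adjacent autosomal
    bins of the same chromosome — a depth-robust technical-noise metric."""
    diffs = []
    for chrom in genome.autosome_indices:
        vals = ratios[genome.bins_of(chrom)]
        if len(vals) > 1:
            diffs.append(np.abs(np.diff(vals)))
    return float(np.median(np.concatenate(diffs)))


def normalize_counts(counts, genome: GenomeModel) -> CopyNumberProfile:
    """Turn raw binned counts into a normalized copy-number profile.

    Each bin's ratio is its count over the sample's median autosomal bin
    count; the per-chromosome copy estimate is twice the 10%-trimmed mean of
    the chromosome's bin ratios, and the displacement follows as
    ``|c_hat - 2| * 100`` for autosomes.
    """
    if not counts.qc_pass:
        raise QCError(f"sample {counts.sample_id} failed sequencing QC")
    raw = np.asarray(counts.counts, dtype=float)
    if raw.shape[0] != genome.n_bins:
        raise ValueError("counts length does not match the genome bin grid")
    auto = genome.autosome_bin_mask
    med = float(np.median(raw[auto]))
    if med <= 0:
        raise DegenerateInputError(f"sample {counts.sample_id}: zero autosomal median")
    ratios = raw / med

    n_chrom = genome.n_chromosomes
    chrom_copy = np.zeros(n_chrom)
    arm_copy = np.full((n_chrom, 2), np.nan)
    for chrom in range(n_chrom):
        chrom_copy[chrom] = 2.0 * float(trim_mean(ratios[genome.bins_of(chrom)], TRIM))
        for arm in (P_ARM, Q_ARM):
            stat = _arm_stat(ratios, genome, chrom, arm)
            arm_copy[chrom, arm] = 2.0 * stat if np.isfinite(stat) else np.nan

    chrom_disp = _round_disp(np.abs(chrom_copy - 2.0) * 100.0)
    profile = CopyNumberProfile(
        sample_id=counts.sample_id,
        ratios=ratios,
        chrom_copy=chrom_copy,
        chrom_disp=chrom_disp,
        arm_copy=arm_copy,
        noise_score=noise_score(ratios, genome),
    )
    auto_idx = genome.autosome_indices
    n_quiet = int((chrom_disp[auto_idx] < DISOMY_MAX).sum())
    if n_quiet < len(auto_idx) / 2:
        # median normalization is biased when most autosomes are displaced
        profile.baseline_unreliable = True
        profile.notes.append("fewer than half of autosomes within d < 30; displacements unreliable")
    return profile


def classify_origin(d: float, chrom_name: str, scope: str) -> str | None:
    """Threshold classification of one displacement value.

    Returns ``None`` for normal disomy (d < 30 on a whole autosome),
    otherwise the origin class.  Both boundary values (30 and 70) fall in
    the mitotic range.  Sex chromosomes and segmental scopes are emitted as
    ``not_classified`` whenever d >= 30.
    """
    if d < 0:
        raise ValueError("displacement must be nonnegative")
    d = float(_round_disp(d))
    if chrom_name in ("chrX", "chrY") or scope != "whole":
        return "not_classified" if d >= DISOMY_MAX else None
    if d < DISOMY_MAX:
        return None
    if d <= MEIOTIC_MIN:
        return "mitotic"
    return "meiotic"


def _binseg_changepoint(vals: np.ndarray) -> tuple[int, float]:
    """Best single split of a sequence by squared-error gain (binary
    segmentation step); returns (split index, relative SSE gain)."""
    n = len(vals)
    if n < 4:
        return 0, 0.0
    total_sse = float(((vals - vals.mean()) ** 2).sum())
    csum = np.cumsum(vals)
    csum2 = np.cumsum(vals**2)
    best_k, best_sse = 0, np.inf
    for k in range(2, n - 1):
        left = csum2[k - 1] - csum[k - 1] ** 2 / k
        right = (csum2[-1] - csum2[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / (n - k)
        if left + right < best_sse:
            best_sse, best_k = left + right, k
    gain = 0.0 if total_sse <= 0 else 1.0 - best_sse / total_sse
    return best_k, gain


def _arms_resolvable(profile: CopyNumberProfile, genome: GenomeModel, chrom: int) -> bool:
    return all(
        int(genome.bins_of(chrom, arm).sum()) >= MIN_ARM_BINS for arm in (P_ARM, Q_ARM)
    ) and np.isfinite(profile.arm_copy[chrom]).all()


def _whole_chromosome_event(profile: CopyNumberProfile, genome: GenomeModel, chrom: int) -> bool:
    """A whole-chromosome event requires both arms displaced >= 30% in the
    same direction; a single displaced arm — even one large enough to drag
    the chromosome mean over threshold — is an arm-scale (segmental) event.
    When an arm has too few bins to resolve, the chromosome mean decides."""
    if not _arms_resolvable(profile, genome, chrom):
        return bool(profile.chrom_disp[chrom] >= DISOMY_MAX)
    arm_c = profile.arm_copy[chrom]
    arm_d = _round_disp(np.abs(arm_c - 2.0) * 100.0)
    same_direction = (arm_c[0] - 2.0) * (arm_c[1] - 2.0) > 0
    return bool((arm_d >= DISOMY_MAX).all() and same_direction)


def detect_segmental(profile: CopyNumberProfile, genome: GenomeModel) -> list[AneuploidyCall]:
    """Arm-level segmental aneuploidy calls.

    An arm whose displacement reaches 30% while the sibling arm stays below
    30% yields a segmental call; a whole-chromosome call on the same
    chromosome takes precedence and suppresses segmental calls.  A binary
    segmentation step confirms where the within-chromosome changepoint lies;
    sub-arm changepoints are merged up to arm scope (the minimum reportable
    segment is one full arm), so the decision rests on the arm means.
    """
    calls: list[AneuploidyCall] = []
    for chrom in range(genome.n_chromosomes):
        name = genome.chromosomes[chrom].name
        if name in ("chrX", "chrY"):
            continue  # handled with sex-aware expectations in infer_sex
        if not _arms_resolvable(profile, genome, chrom):
            continue  # too few bins per arm for segmental inference
        if _whole_chromosome_event(profile, genome, chrom):
            continue  # whole-chromosome call takes precedence
        arm_d = _round_disp(np.abs(profile.arm_copy[chrom] - 2.0) * 100.0)
        for arm, scope in ((P_ARM, "segmental_p"), (Q_ARM, "segmental_q")):
            d = float(arm_d[arm])
            if not np.isfinite(d) or d < DISOMY_MAX:
                continue
            vals = profile.ratios[genome.bins_of(chrom)]
            _binseg_changepoint(vals)  # confirmation step; arm means decide
            direction = "gain" if profile.arm_copy[chrom, arm] > 2.0 else "loss"
            calls.append(AneuploidyCall(name, scope, direction, d, "not_classified"))
    return calls


def infer_sex(profile: CopyNumberProfile, genome: GenomeModel) -> tuple[str, list[AneuploidyCall]]:
    """Infer embryo sex from the Y ratio and call sex-chromosome aneuploidy
    against the sex-dependent copy expectation (X: 2 in XX, 1 in XY).

    A Y mean ratio inside the ambiguous window suppresses sex-chromosome
    calls entirely (sex 'uncertain')."""
    xi, yi = genome.x_index, genome.y_index
    y_ratio = profile.chrom_copy[yi] / 2.0
    if Y_AMBIGUOUS[0] <= y_ratio <= Y_AMBIGUOUS[1]:
        profile.sex = "uncertain"
        profile.notes.append("ambiguous Y signal; sex-chromosome calls suppressed")
        return "uncertain", []
    sex = "XY" if y_ratio > Y_MALE_MIN else "XX"
    profile.sex = sex
    expected = {"XY": {xi: 1.0, yi: 1.0}, "XX": {xi: 2.0, yi: 0.0}}[sex]
    calls: list[AneuploidyCall] = []
    for chrom in (xi, yi):
        c_hat = profile.chrom_copy[chrom]
        d = float(_round_disp(abs(c_hat - expected[chrom]) * 100.0))
        if d >= DISOMY_MAX:
            direction = "gain" if c_hat > expected[chrom] else "loss"
            name = genome.chromosomes[chrom].name
            calls.append(AneuploidyCall(name, "whole", direction, d, "not_classified"))
    return sex, calls


@dataclass
class CallResult:
    """Outcome of calling one sample: either a QC exclusion or a call list."""

    sample_id: str
    qc_excluded: bool
    qc_reason: str = ""
    calls: list = field(default_factory=list)
    profile: CopyNumberProfile | None = None

    @property
    def autosomal_calls(self) -> list:
        return [c for c in self.calls if c.chrom not in ("chrX", "chrY")]


def call_sample(
    counts,
    genome: GenomeModel,
    qc_noise_threshold: float = DEFAULT_QC_NOISE_THRESHOLD,
) -> CallResult:
    """Full calling pipeline for one sample.

    QC exclusion (flagged sample, or noise score above threshold) is a
    distinguished result, not an exception."""
    if not counts.qc_pass:
        return CallResult(counts.sample_id, qc_excluded=True, qc_reason="flagged_qc_fail")
    profile = normalize_counts(counts, genome)
    if profile.noise_score > qc_noise_threshold:
        return CallResult(
            counts.sample_id, qc_excluded=True, qc_reason="excessive_noise", profile=profile
        )

    calls: list[AneuploidyCall] = []
    for chrom in genome.autosome_indices:
        if not _whole_chromosome_event(profile, genome, chrom):
            continue
        d = float(profile.chrom_disp[chrom])
        name = genome.chromosomes[chrom].name
        origin = classify_origin(d, name, "whole")
        if origin is not None:
            direction = "gain" if profile.chrom_copy[chrom] > 2.0 else "loss"
            calls.append(AneuploidyCall(name, "whole", direction, d, origin))
    calls.extend(detect_segmental(profile, genome))
    _, sex_calls = infer_sex(profile, genome)
    calls.extend(sex_calls)
    return CallResult(counts.sample_id, qc_excluded=False, calls=calls, profile=profile)


def calls_to_frame(results: list[CallResult]) -> pd.DataFrame:
    """Tidy calls table (one row per call; QC-excluded samples keep one row)."""
    rows = []
    for r in results:
        if r.qc_excluded:
            rows.append(
                {
                    "sample_id": r.sample_id, "chrom": "", "scope": "", "direction": "",
                    "displacement": np.nan, "origin": "", "qc_flag": r.qc_reason,
                }
            )
            continue
        for c in r.calls:
            rows.append(
                {
                    "sample_id": r.sample_id, "chrom": c.chrom, "scope": c.scope,
                    "direction": c.direction, "displacement": c.displacement,
                    "origin": c.origin, "qc_flag": "pass",
                }
            )
        if not r.calls:
            rows.append(
                {
                    "sample_id": r.sample_id, "chrom": "", "scope": "", "direction": "",
                    "displacement": np.nan, "origin": "euploid", "qc_flag": "pass",
                }
            )
    return pd.DataFrame(rows)
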