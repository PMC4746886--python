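"""Binomial model for sex linkage of scaffolds.

With male and female DNA sequenced in separate libraries, the number of
male reads in a scaffold of ``n`` reads is binomial.  Writing ``p`` for
the genome-wide male-read proportion, an autosome-like scaffold is
all-male purely by chance with probability ``p**n``; scaffolds below a
minimum read count are therefore excluded before calling all-male
scaffolds Y candidates.  Expected male fractions per chromosome class
follow from copy numbers — autosomes 2:2 in (male, female), X 1:2,
Y 1:0 — and the per-copy male:female sampling-rate ratio
``r = p / (1 - p)``:

    E[male fraction | A] = r / (r + 1)
    E[male fraction | X] = r / (r + 2)
    E[male fraction | Y] = 1
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from ylinkage.errors import UndefinedStatisticsError
from ylinkage.provenance import ScaffoldReadCount


class ChromClass(str, Enum):
    A = "A"
    X = "X"
    Y = "Y"


#: (male copies, female copies) per diploid individual.
COPY_NUMBERS: dict[ChromClass, tuple[int, int]] = {
    ChromClass.A: (2, 2),
    ChromClass.X: (1, 2),
    ChromClass.Y: (1, 0),
}


class Call(str, Enum):
    Y_CANDIDATE = "Y_candidate"
    X_BAND = "X_band"
    AUTOSOME_LIKE = "autosome_like"
    EXCLUDED_LOW_READS = "excluded_low_reads"
    EXCLUDED_CONTAMINANT = "excluded_contaminant"
    NO_READS = "no_reads"


RETAINED_CALLS = frozenset({Call.Y_CANDIDATE, Call.X_BAND, Call.AUTOSOME_LIKE})


@dataclass(frozen=True)
class GlobalReadStats:
    """Genome-wide read totals and derived sampling-rate ratio."""

    total_male: int
    total_female: int

    def __post_init__(self):
        if self.total_male < 0 or self.total_female < 0:
            raise ValueError("read totals must be non-negative")
        if self.total_male + self.total_female == 0:
            raise UndefinedStatisticsError("no reads: p_male undefined")

    @property
    def p_male(self) -> float:
        return self.total_male / (self.total_male + self.total_female)

    @property
    def r_rate_ratio(self) -> float:
        """Per-chromosome-copy male:female sampling-rate ratio.

        Estimated as p/(1-p) from autosome-dominated totals.
        """
        p = self.p_male
        if p in (0.0, 1.0):
            raise UndefinedStatisticsError("r undefined when one sex has no reads")
        return p / (1.0 - p)


@dataclass(frozen=True)
class ModelConfig:
    """Thresholds of the false-positive model.

    ``alpha`` is the per-scaffold false-positive bound (default 1/200).
    ``min_reads`` is the smallest total read count a scaffold must have
    to be classified: the published filter drops scaffolds "with 10
    reads or less", i.e. ``min_reads = 11``.  Note that with p = 0.585
    the model itself would already admit 10-read scaffolds
    (0.585**10 <= 1/200); :func:`min_read_threshold` reports that
    model-derived value so the discrepancy stays visible.
    ``x_band_halfwidth`` flags scaffolds whose male fraction falls near
    the X expectation r/(r+2); this is a weak flag, not a confident
    call, since autosomal sampling noise overlaps the band heavily.
    """

    alpha: float = 1.0 / 200.0
    min_reads: int = 11
    x_band_halfwidth: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.x_band_halfwidth < 0.0:
            raise ValueError("x_band_halfwidth must be >= 0")


@dataclass(frozen=True)
class LinkageCall:
    scaffold_id: str
    call: Call
    fp_probability: float | None = None

    def __post_init__(self):
        if (self.call is Call.Y_CANDIDATE) != (self.fp_probability is not None):
            raise ValueError("fp_probability is defined iff call is Y_candidate")


def global_male_fraction(counts: Iterable[ScaffoldReadCount]) -> GlobalReadStats:
    """Sum male/female reads over all scaffolds.

    Raises :class:`UndefinedStatisticsError` when the input holds no
    reads at all.
    """
    total_male = total_female = 0
    for c in counts:
        total_male += c.n_male
        total_female += c.n_female
    return GlobalReadStats(total_male=total_male, total_female=total_female)


def fp_probability(n_reads: int, p_male: float) -> float:
    """Probability that an autosome-like scaffold of n reads is all-male.

    All ``n`` independent reads must come from the male libraries:
    ``p_male ** n_reads``.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0.0 < p_male <= 1.0:
        raise ValueError("p_male must be in (0, 1]")
    return p_male**n_reads


def min_read_threshold(p_male: float, alpha: float) -> int:
    """Smallest read count n with p_male**n <= alpha.

    Closed form n = ceil(ln alpha / ln p); the result is nudged to be
    robust to floating-point edge cases so that p**n <= alpha < p**(n-1)
    holds exactly.
    """
    if not 0.0 < p_male < 1.0:
        raise ValueError("p_male must be in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n = max(1, math.ceil(math.log(alpha) / math.log(p_male)))
    while n > 1 and p_male ** (n - 1) <= alpha:
        n -= 1
    while p_male**n > alpha:
        n += 1
    return n


def expected_male_fraction(chrom_class: ChromClass | str, r_rate_ratio: float) -> float:
    """Expected male-read fraction for a chromosome class.

    From copy numbers (m, f) per class and the per-copy rate ratio r:
    m*r / (m*r + f).  At r = 1 this gives 1/2 for autosomes, 1/3 for X
    (female fraction 2/3) and 1 for Y.
    """
    if r_rate_ratio <= 0.0:
        raise ValueError("r_rate_ratio must be > 0")
    m, f = COPY_NUMBERS[ChromClass(chrom_class)]
    return m * r_rate_ratio / (m * r_rate_ratio + f)


def classify_scaffold(
    count: ScaffoldReadCount,
    stats: GlobalReadStats,
    cfg: ModelConfig = ModelConfig(),
    contaminant_ids: frozenset[str] | set[str] = frozenset(),
) -> LinkageCall:
    """Assign exactly one chromosomal-class call to a scaffold.

    Precedence: contaminant > no reads > low-read exclusion > all-male
    (Y candidate, with its chance false-positive probability attached) >
    X band > autosome-like.
    """
    sid = count.scaffold_id
    if sid in contaminant_ids:
        return LinkageCall(sid, Call.EXCLUDED_CONTAMINANT)
    if count.n_total == 0:
        return LinkageCall(sid, Call.NO_READS)
    if count.n_total < cfg.min_reads:
        return LinkageCall(sid, Call.EXCLUDED_LOW_READS)
    if count.n_male == count.n_total:
        return LinkageCall(
            sid,
            Call.Y_CANDIDATE,
            fp_probability=fp_probability(count.n_total, stats.p_male),
        )
    # X band needs r = p/(1-p); degenerate p (all reads one sex) leaves
    # the band undefined and the scaffold autosome-like
    if 0.0 < stats.p_male < 1.0:
        x_expect = expected_male_fraction(ChromClass.X, stats.r_rate_ratio)
        if abs(count.male_fraction - x_expect) <= cfg.x_band_halfwidth:
            return LinkageCall(sid, Call.X_BAND)
    return LinkageCall(sid, Call.AUTOSOME_LIKE)


def classify_all(
    counts: Sequence[ScaffoldReadCount],
    stats: GlobalReadStats | None = None,
    cfg: ModelConfig = ModelConfig(),
    contaminant_ids: frozenset[str] | set[str] = frozenset(),
) -> list[LinkageCall]:
    """Classify every scaffold; ``stats`` defaults to the input's totals."""
    if stats is None:
        stats = global_male_fraction(counts)
    return [classify_scaffold(c, stats, cfg, contaminant_ids) for c in counts]


@dataclass
class CandidateSummary:
    """Per-percent histograms and Y-candidate totals over retained scaffolds."""

    n_scaffolds: int
    n_retained: int
    n_y_candidates: int
    y_candidate_bp: int
    retained_bp: int
    pct_of_retained_genome: float
    expected_false_positives: float
    hist_scaffolds: dict[int, int]
    hist_bp: dict[int, int]


def _percent_bin(count: ScaffoldReadCount) -> int:
    # 100 is reserved for exactly all-male so 99.6 % cannot round into
    # the Y bin.
    if count.n_male == count.n_total:
        return 100
    return min(int(math.floor(100.0 * count.male_fraction)), 99)


def summarize_candidates(
    calls: Sequence[LinkageCall],
    counts: Sequence[ScaffoldReadCount],
    stats: GlobalReadStats | None = None,
) -> CandidateSummary:
    """Histogram retained scaffolds by integer male-read percent.

    Also reports the number of Y candidates, their summed length, the
    share of the retained assembly they cover, and the expected number
    of chance all-male scaffolds (sum of p**n over retained scaffolds).
    """
    by_id: Mapping[str, ScaffoldReadCount] = {c.scaffold_id: c for c in counts}
    if stats is None:
        stats = global_male_fraction(counts)
    hist_scaffolds: dict[int, int] = {}
    hist_bp: dict[int, int] = {}
    n_retained = n_y = 0
    y_bp = retained_bp = 0
    expected_fp = 0.0
    for call in calls:
        if call.call not in RETAINED_CALLS:
            continue
        count = by_id[call.scaffold_id]
        n_retained += 1
        retained_bp += count.length_bp
        if stats.p_male > 0.0:
            expected_fp += fp_probability(count.n_total, stats.p_male)
        b = _percent_bin(count)
        hist_scaffolds[b] = hist_scaffolds.get(b, 0) + 1
        hist_bp[b] = hist_bp.get(b, 0) + count.length_bp
        if call.call is Call.Y_CANDIDATE:
            n_y += 1
            y_bp += count.length_bp
    pct = 100.0 * y_bp / retained_bp if retained_bp else 0.0
    return CandidateSummary(
        n_scaffolds=len(calls),
        n_retained=n_retained,
        n_y_candidates=n_y,
        y_candidate_bp=y_bp,
        retained_bp=retained_bp,
        pct_of_retained_genome=round(pct, 1),
        expected_false_positives=expected_fp,
        hist_scaffolds=dict(sorted(hist_scaffolds.items())),
        hist_bp=dict(sorted(hist_bp.items())),
    )
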