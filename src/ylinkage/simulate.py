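"""Synthetic sex-separated read-provenance data with known truth.

The generator emulates the statistical world the linkage model assumes:
scaffolds belong to chromosome classes A/X/Y with copy numbers
(2,2)/(1,2)/(1,0) in (male, female); each scaffold receives a Poisson
number of reads proportional to its length and copy weight; the male
share of those reads is binomial with the class' expected male
fraction; optional contamination flips each read's sex label
independently.  Copy weights are normalised so ``reads_per_bp`` is the
read density of one female autosomal copy-pair:

    weight(class) = (m_copies * r + f_copies) / 2,   r = e / (1 - e)

with ``e`` the male share of total sequencing effort.  No sequences,
read lengths or GC bias are modelled — only read provenance counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ylinkage.errors import AlignmentError
from ylinkage.linkage import (
    Call,
    ChromClass,
    COPY_NUMBERS,
    GlobalReadStats,
    LinkageCall,
    RETAINED_CALLS,
    fp_probability,
)
from ylinkage.provenance import LibraryCatalog, ScaffoldReadCount, Sex


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Stated world of a simulated sex-separated sequencing project.

    Defaults describe a desk-scale genome: about a thousand scaffolds,
    mostly autosomal with a small Y fraction, log-uniform lengths from
    0.5 to 100 kb (real assemblies of this kind are heavily skewed
    toward short scaffolds), read density 0.01 reads/bp per female
    autosomal copy-pair (a few million reads over a few hundred Mb),
    and male libraries contributing 58.5 % of total effort as realised
    in the motivating dataset.  ``fixed_n_total`` bypasses the Poisson
    draw to give every scaffold the same read count (for calibration
    studies at fixed n).
    """

    n_autosomal: int = 900
    n_x: int = 60
    n_y: int = 40
    length_dist: tuple[int, int] = (500, 100_000)
    reads_per_bp: float = 0.01
    effort_male_fraction: float = 0.585
    contamination_rate: float = 0.0
    seed: int = 0
    fixed_n_total: int | None = None

    def __post_init__(self):
        if min(self.n_autosomal, self.n_x, self.n_y) < 0:
            raise ValueError("scaffold counts must be >= 0")
        if self.n_autosomal + self.n_x + self.n_y < 1:
            raise ValueError("at least one scaffold required")
        lo, hi = self.length_dist
        if not 0 < lo <= hi:
            raise ValueError("length_dist must satisfy 0 < min <= max")
        if self.reads_per_bp <= 0:
            raise ValueError("reads_per_bp must be > 0")
        if not 0.0 < self.effort_male_fraction < 1.0:
            raise ValueError("effort_male_fraction must be in (0, 1)")
        if not 0.0 <= self.contamination_rate < 1.0:
            raise ValueError("contamination_rate must be in [0, 1)")
        if self.fixed_n_total is not None and self.fixed_n_total < 0:
            raise ValueError("fixed_n_total must be >= 0")

    @property
    def r_rate_ratio(self) -> float:
        e = self.effort_male_fraction
        return e / (1.0 - e)


@dataclass(frozen=True)
class SyntheticTruth:
    scaffold_id: str
    true_class: ChromClass
    length_bp: int
    n_total: int
    n_male: int

    def __post_init__(self):
        if self.n_male > self.n_total:
            raise ValueError("n_male must be <= n_total")


@dataclass
class RecoveryReport:
    """How well classification recovered the simulated truth.

    Rates are computed over scaffolds that were retained (classified,
    not excluded); ``sensitivity_y`` is None when no true-Y scaffold
    was retained.  ``expected_fp_rate`` is the analytic mean of p**n
    over retained non-Y scaffolds (None when counts/stats not given).
    """

    sensitivity_y: float | None
    fp_rate_autosomal: float | None
    fp_rate_x: float | None
    expected_fp_rate: float | None
    n_excluded_low_reads: int

    def as_dict(self) -> dict:
        return {
            "sensitivity_y": self.sensitivity_y,
            "fp_rate_autosomal": self.fp_rate_autosomal,
            "fp_rate_x": self.fp_rate_x,
            "expected_fp_rate": self.expected_fp_rate,
            "n_excluded_low_reads": self.n_excluded_low_reads,
        }


def simulate_counts(
    spec: SyntheticGenomeSpec,
) -> tuple[list[ScaffoldReadCount], list[SyntheticTruth]]:
    """Draw per-scaffold read counts under the stated world.

    Deterministic under a fixed spec (including seed).  Scaffold ids
    are class-blind (``SYN000123``) so nothing downstream can key on
    the truth.
    """
    rng = np.random.default_rng(spec.seed)
    classes = (
        [ChromClass.A] * spec.n_autosomal
        + [ChromClass.X] * spec.n_x
        + [ChromClass.Y] * spec.n_y
    )
    n = len(classes)
    lo, hi = spec.length_dist
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(np.int64)
    lengths = np.maximum(lengths, lo)

    r = spec.r_rate_ratio
    m_copies = np.array([COPY_NUMBERS[c][0] for c in classes], dtype=float)
    f_copies = np.array([COPY_NUMBERS[c][1] for c in classes], dtype=float)
    weight = (m_copies * r + f_copies) / 2.0
    q_male = m_copies * r / (m_copies * r + f_copies)

    if spec.fixed_n_total is not None:
        n_total = np.full(n, spec.fixed_n_total, dtype=np.int64)
    else:
        n_total = rng.poisson(lengths * spec.reads_per_bp * weight)
    n_male = rng.binomial(n_total, q_male)

    eps = spec.contamination_rate
    if eps > 0.0:
        # each read's sex label flips independently with probability eps
        kept_male = rng.binomial(n_male, 1.0 - eps)
        gained_male = rng.binomial(n_total - n_male, eps)
        n_male = kept_male + gained_male

    counts: list[ScaffoldReadCount] = []
    truths: list[SyntheticTruth] = []
    for i, cls in enumerate(classes):
        sid = f"SYN{i:06d}"
        tot, male = int(n_total[i]), int(n_male[i])
        counts.append(
            ScaffoldReadCount(
                scaffold_id=sid,
                length_bp=int(lengths[i]),
                n_total=tot,
                n_male=male,
                n_female=tot - male,
            )
        )
        truths.append(
            SyntheticTruth(
                scaffold_id=sid,
                true_class=cls,
                length_bp=int(lengths[i]),
                n_total=tot,
                n_male=male,
            )
        )
    return counts, truths


def emit_read_map(
    truths: Iterable[SyntheticTruth],
    catalog: LibraryCatalog,
    path: str | Path,
    seed: int = 0,
) -> None:
    """Write a read map whose recount reproduces each truth exactly.

    Each truth contributes ``n_male`` rows with male-library prefixes
    and ``n_total - n_male`` rows with female prefixes; the prefix for
    each read is drawn uniformly among that sex's libraries, and read
    names get globally unique numeric suffixes.  Deterministic under a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    male_prefixes = catalog.prefixes(Sex.MALE)
    female_prefixes = catalog.prefixes(Sex.FEMALE)
    counter = 0
    with open(path, "w") as fh:
        fh.write("#scaffold_id\tread_id\n")
        for t in truths:
            for sex_prefixes, n in (
                (male_prefixes, t.n_male),
                (female_prefixes, t.n_total - t.n_male),
            ):
                for _ in range(n):
                    prefix = sex_prefixes[rng.integers(len(sex_prefixes))]
                    fh.write(f"{t.scaffold_id}\t{prefix}{counter:09d}\n")
                    counter += 1


def write_truth_table(truths: Iterable[SyntheticTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold_id\ttrue_class\tlength_bp\tn_total\tn_male\n")
        for t in truths:
            fh.write(
                f"{t.scaffold_id}\t{t.true_class.value}\t{t.length_bp}\t"
                f"{t.n_total}\t{t.n_male}\n"
            )


def read_truth_table(path: str | Path) -> list[SyntheticTruth]:
    truths: list[SyntheticTruth] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            sid, cls, length, tot, male = line.rstrip("\n").split("\t")
            truths.append(
                SyntheticTruth(
                    scaffold_id=sid,
                    true_class=ChromClass(cls),
                    length_bp=int(length),
                    n_total=int(tot),
                    n_male=int(male),
                )
            )
    return truths


def score_recovery(
    calls: Sequence[LinkageCall],
    truths: Sequence[SyntheticTruth],
    counts: Sequence[ScaffoldReadCount] | None = None,
    stats: GlobalReadStats | None = None,
) -> RecoveryReport:
    """Score classification calls against simulated truth.

    Sensitivity is the fraction of retained true-Y scaffolds called Y;
    false-positive rates are the fractions of retained true-A and
    true-X scaffolds called Y.  When ``counts`` and ``stats`` are
    supplied, the analytic expectation mean(p**n) over retained non-Y
    scaffolds is reported for comparison with the realised A-rate.
    """
    truth_by_id = {t.scaffold_id: t for t in truths}
    counts_by_id = {c.scaffold_id: c for c in counts} if counts is not None else None

    y_called = {ChromClass.A: 0, ChromClass.X: 0, ChromClass.Y: 0}
    retained = {ChromClass.A: 0, ChromClass.X: 0, ChromClass.Y: 0}
    n_low = 0
    expected_fp_sum = 0.0
    expected_fp_n = 0
    for call in calls:
        truth = truth_by_id.get(call.scaffold_id)
        if truth is None:
            raise AlignmentError(f"scaffold {call.scaffold_id!r} missing from truths")
        if call.call is Call.EXCLUDED_LOW_READS:
            n_low += 1
        if call.call not in RETAINED_CALLS:
            continue
        retained[truth.true_class] += 1
        if call.call is Call.Y_CANDIDATE:
            y_called[truth.true_class] += 1
        if (
            truth.true_class is not ChromClass.Y
            and counts_by_id is not None
            and stats is not None
        ):
            expected_fp_sum += fp_probability(
                counts_by_id[call.scaffold_id].n_total, stats.p_male
            )
            expected_fp_n += 1

    def rate(cls: ChromClass) -> float | None:
        return y_called[cls] / retained[cls] if retained[cls] else None

    return RecoveryReport(
        sensitivity_y=rate(ChromClass.Y),
        fp_rate_autosomal=rate(ChromClass.A),
        fp_rate_x=rate(ChromClass.X),
        expected_fp_rate=(
            expected_fp_sum / expected_fp_n if expected_fp_n else None
        ),
        n_excluded_low_reads=n_low,
    )
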