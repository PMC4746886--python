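"""Read provenance: resolve each read's sex and count reads per scaffold.

In a sex-separated sequencing project every read name carries a library
prefix that identifies the sex of the DNA donor.  Given the assembler's
read-tracking records (here standardised as a 2-column TSV of
``scaffold_id, read_id``) this module tallies, per scaffold, the total
number of reads and how many came from male vs female libraries — the
table on which all downstream linkage inference operates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

from ylinkage.errors import (
    CatalogError,
    ReadMapFormatError,
    UnknownLibraryError,
)

COUNT_TABLE_COLUMNS = (
    "scaffold_id",
    "length_bp",
    "n_total",
    "n_male",
    "n_female",
    "pct_male",
)


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class MatchMode(str, Enum):
    PREFIX = "prefix"
    EXACT = "exact"


@dataclass(frozen=True)
class LibraryCatalog:
    """Maps read-name library prefixes to the sex of the DNA donor.

    Prefixes must be unambiguous: no prefix may be a prefix of another,
    so the first match is the only match and longest-match logic is
    unnecessary.  Matching is case-sensitive.
    """

    entries: tuple[tuple[str, Sex], ...]
    match_mode: MatchMode = MatchMode.PREFIX

    def __post_init__(self):
        object.__setattr__(
            self,
            "entries",
            tuple((p, Sex(s)) for p, s in self.entries),
        )
        prefixes = [p for p, _ in self.entries]
        if not prefixes:
            raise CatalogError("catalog has no entries")
        if any(not p for p in prefixes):
            raise CatalogError("catalog contains an empty prefix")
        if len(set(prefixes)) != len(prefixes):
            raise CatalogError("catalog contains duplicate prefixes")
        for i, a in enumerate(prefixes):
            for j, b in enumerate(prefixes):
                if i != j and b.startswith(a):
                    raise CatalogError(
                        f"ambiguous catalog: {a!r} is a prefix of {b!r}"
                    )
        sexes = {s for _, s in self.entries}
        if sexes != {Sex.MALE, Sex.FEMALE}:
            raise CatalogError("catalog needs at least one male and one female library")

    def sex_of(self, read_id: str) -> Sex:
        for prefix, sex in self.entries:
            if self.match_mode is MatchMode.EXACT:
                if read_id == prefix:
                    return sex
            elif read_id.startswith(prefix):
                return sex
        raise UnknownLibraryError(f"read {read_id!r} matches no library prefix")

    def prefixes(self, sex: Sex) -> list[str]:
        return [p for p, s in self.entries if s is sex]


#: Library catalog of the RproC1 Rhodnius prolixus assembly: male DNA was
#: sequenced in libraries NAAX (Sanger) and GFL7EVZ (454 Roche); female DNA
#: in Sanger libraries NADD, NADK and NADN.
RPROC1_LIBRARIES = LibraryCatalog(
    entries=(
        ("NAAX", Sex.MALE),
        ("GFL7EVZ", Sex.MALE),
        ("NADD", Sex.FEMALE),
        ("NADK", Sex.FEMALE),
        ("NADN", Sex.FEMALE),
    )
)


@dataclass(frozen=True)
class ReadAssignment:
    """One read-tracking record: this read was used in this scaffold."""

    read_id: str
    scaffold_id: str

    def __post_init__(self):
        if not self.read_id or not self.scaffold_id:
            raise ValueError("read_id and scaffold_id must be non-empty")


@dataclass(frozen=True)
class ScaffoldReadCount:
    """Per-scaffold read tally; ``male_fraction`` is None when no reads."""

    scaffold_id: str
    length_bp: int
    n_total: int
    n_male: int
    n_female: int

    def __post_init__(self):
        if min(self.length_bp, self.n_total, self.n_male, self.n_female) < 0:
            raise ValueError("counts and length must be non-negative")
        if self.n_male + self.n_female != self.n_total:
            raise ValueError(
                f"{self.scaffold_id}: n_male + n_female != n_total "
                f"({self.n_male} + {self.n_female} != {self.n_total})"
            )

    @property
    def male_fraction(self) -> float | None:
        if self.n_total == 0:
            return None
        return self.n_male / self.n_total


@dataclass
class ParseSummary:
    """Filled in as a read-map stream is consumed."""

    n_rows: int = 0
    n_comment_lines: int = 0


def sex_of_read(read_id: str, catalog: LibraryCatalog) -> Sex:
    """Resolve a read's sex of origin from its library prefix.

    Raises :class:`UnknownLibraryError` when no prefix matches.
    """
    return catalog.sex_of(read_id)


def parse_read_map(
    path: str | Path, summary: ParseSummary | None = None
) -> Iterator[ReadAssignment]:
    """Stream ``(scaffold_id, read_id)`` assignments from a 2-column TSV.

    Lines starting with ``#`` are treated as header/comments.  A row with
    the wrong column count raises :class:`ReadMapFormatError` carrying the
    1-based line number.  If ``summary`` is given its fields are updated
    as rows are yielded.
    """
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if summary is not None:
                    summary.n_comment_lines += 1
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ReadMapFormatError(
                    f"line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}",
                    line_number=lineno,
                )
            scaffold_id, read_id = fields
            if summary is not None:
                summary.n_rows += 1
            yield ReadAssignment(read_id=read_id, scaffold_id=scaffold_id)


@dataclass
class CountingResult:
    counts: list[ScaffoldReadCount]
    n_assignments: int = 0
    n_unknown_skipped: int = 0
    n_duplicates_collapsed: int = 0

    def by_id(self) -> dict[str, ScaffoldReadCount]:
        return {c.scaffold_id: c for c in self.counts}


def count_reads_per_scaffold(
    assignments: Iterable[ReadAssignment],
    catalog: LibraryCatalog,
    lengths: Mapping[str, int],
    *,
    skip_unknown: bool = False,
) -> CountingResult:
    """Tally male/female reads for every scaffold.

    A read assigned to several scaffolds contributes once to each (the
    assembler's view); duplicate ``(scaffold, read)`` pairs are collapsed.
    Scaffolds present in ``lengths`` but with no assigned reads appear
    with ``n_total = 0``.  Scaffolds missing from ``lengths`` get length
    0 with a warning.

    Unknown library prefixes raise :class:`UnknownLibraryError` unless
    ``skip_unknown`` is set, in which case they are counted in
    ``n_unknown_skipped`` — silent misclassification would corrupt the
    male fraction.
    """
    seen: set[tuple[str, str]] = set()
    male: dict[str, int] = {}
    female: dict[str, int] = {}
    result = CountingResult(counts=[])
    for a in assignments:
        key = (a.scaffold_id, a.read_id)
        if key in seen:
            result.n_duplicates_collapsed += 1
            continue
        seen.add(key)
        try:
            sex = catalog.sex_of(a.read_id)
        except UnknownLibraryError:
            if skip_unknown:
                result.n_unknown_skipped += 1
                continue
            raise
        result.n_assignments += 1
        tally = male if sex is Sex.MALE else female
        tally[a.scaffold_id] = tally.get(a.scaffold_id, 0) + 1

    scaffold_ids = sorted(set(male) | set(female) | set(lengths))
    missing_length = [s for s in scaffold_ids if s not in lengths]
    if missing_length:
        warnings.warn(
            f"{len(missing_length)} scaffold(s) absent from the length table; "
            "recording length 0 (first: " + missing_length[0] + ")",
            stacklevel=2,
        )
    for sid in scaffold_ids:
        n_m = male.get(sid, 0)
        n_f = female.get(sid, 0)
        result.counts.append(
            ScaffoldReadCount(
                scaffold_id=sid,
                length_bp=int(lengths.get(sid, 0)),
                n_total=n_m + n_f,
                n_male=n_m,
                n_female=n_f,
            )
        )
    return result


def write_count_table(counts: Iterable[ScaffoldReadCount], path: str | Path) -> None:
    """Write the canonical six-column count table.

    Columns: scaffold_id, length_bp, n_total, n_male, n_female, pct_male
    (one decimal; "NA" for zero-read scaffolds).  Integer fields
    round-trip bit-exactly through :func:`read_count_table`.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(COUNT_TABLE_COLUMNS) + "\n")
        for c in counts:
            mf = c.male_fraction
            pct = "NA" if mf is None else f"{100.0 * mf:.1f}"
            fh.write(
                f"{c.scaffold_id}\t{c.length_bp}\t{c.n_total}\t"
                f"{c.n_male}\t{c.n_female}\t{pct}\n"
            )


def read_count_table(path: str | Path) -> list[ScaffoldReadCount]:
    """Read a six-column count table back into records."""
    df = pd.read_csv(path, sep="\t", dtype={"scaffold_id": str})
    missing = set(COUNT_TABLE_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ReadMapFormatError(f"count table missing columns: {sorted(missing)}")
    return [
        ScaffoldReadCount(
            scaffold_id=row.scaffold_id,
            length_bp=int(row.length_bp),
            n_total=int(row.n_total),
            n_male=int(row.n_male),
            n_female=int(row.n_female),
        )
        for row in df.itertuples()
    ]


def read_lengths(path: str | Path) -> dict[str, int]:
    """Load scaffold lengths from FASTA or a 2-column TSV.

    FASTA is detected by a leading ``>``; lengths are then computed from
    the sequences.  Otherwise the file is read as ``scaffold_id<TAB>length``
    with an optional ``#``-prefixed header.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ReadMapFormatError(
                    f"line {lineno}: expected 2 columns in length table",
                    line_number=lineno,
                )
            lengths[fields[0]] = int(fields[1])
    return lengths
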