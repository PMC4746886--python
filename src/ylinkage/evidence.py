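"""Homology-evidence triage of Y-candidate scaffolds.

Candidate scaffolds are screened against protein, transposable-element
and species-specific transcript/gene databases (searches run upstream;
this module consumes their 12-column tabular output).  Scaffolds with
high-identity bacterial or TE matches are discarded as contaminants;
the remaining hits are filtered by per-database e-value/identity
thresholds, ranked into a five-tier evidence order (transcript support
counted separately as the strongest evidence), and candidates with hits
in enough distinct databases are selected for downstream linkage
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ylinkage.errors import ConfigError, HitTableFormatError, MetadataError


class Database(str, Enum):
    REFSEQ = "refseq"
    NR = "nr"
    BACTERIAL = "bacterial"
    TE = "te"
    RPRO_TRANSCRIPTS = "rpro_transcripts"
    RPRO_GENEID = "rpro_geneid"
    RPRO_GENEID_TRASH = "rpro_geneid_trash"


#: Databases that count as gene evidence (contaminant screens excluded).
GENE_EVIDENCE_DATABASES = frozenset(
    {
        Database.REFSEQ,
        Database.NR,
        Database.RPRO_TRANSCRIPTS,
        Database.RPRO_GENEID,
        Database.RPRO_GENEID_TRASH,
    }
)

CONTAMINANT_DATABASES = frozenset({Database.BACTERIAL, Database.TE})


class IdentityKind(str, Enum):
    NUCLEOTIDE = "nucleotide"
    AMINO_ACID = "amino_acid"


class Conservation(str, Enum):
    KNOWN = "known"
    CONSERVED_HYPOTHETICAL = "conserved_hypothetical"
    UNCONSERVED_HYPOTHETICAL = "unconserved_hypothetical"


@dataclass(frozen=True)
class HomologyHit:
    scaffold_id: str
    database: Database
    subject_id: str
    pct_identity: float
    evalue: float
    align_start: int
    align_end: int
    identity_kind: IdentityKind

    def __post_init__(self):
        if self.align_start > self.align_end:
            raise ValueError("align_start must be <= align_end")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity must be in [0, 100]")


@dataclass(frozen=True)
class EvidenceRecord:
    scaffold_id: str
    databases_hit: frozenset[Database]
    has_transcript: bool
    tier: int | None
    selected_for_testing: bool = False

    def __post_init__(self):
        if self.has_transcript != (Database.RPRO_TRANSCRIPTS in self.databases_hit):
            raise ValueError("has_transcript must mirror the transcript database hit")
        if self.tier is not None and self.tier not in range(1, 6):
            raise ValueError("tier must be in 1..5 or None")


def parse_tabular_hits(
    path: str | Path,
    database: Database | str,
    identity_kind: IdentityKind | str,
) -> list[HomologyHit]:
    """Parse standard 12-column tabular homology output (BLAST outfmt 6).

    Columns: query, subject, pct_identity, length, mismatches, gaps,
    qstart, qend, sstart, send, evalue, bitscore.  The query is the
    scaffold; qstart/qend give the alignment interval on it (stored
    sorted so start <= end regardless of strand).
    """
    database = Database(database)
    identity_kind = IdentityKind(identity_kind)
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise HitTableFormatError(
                    f"line {lineno}: expected 12 columns, got {len(fields)}",
                    line_number=lineno,
                )
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                hits.append(
                    HomologyHit(
                        scaffold_id=fields[0],
                        database=database,
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        evalue=float(fields[10]),
                        align_start=min(qstart, qend),
                        align_end=max(qstart, qend),
                        identity_kind=identity_kind,
                    )
                )
            except ValueError as exc:
                raise HitTableFormatError(
                    f"line {lineno}: {exc}", line_number=lineno
                ) from exc
    return hits


@dataclass(frozen=True)
class DatabaseThresholds:
    max_evalue: float
    min_identity: float | None = None  # None: no identity requirement


#: Search-stage thresholds: BLASTx/tBLASTx searches at e <= 1e-6 for the
#: protein and TE databases; BLASTn at e <= 1e-8 and 100 % identity for
#: the species' own transcripts and annotated genes.
DEFAULT_FILTERS: dict[Database, DatabaseThresholds] = {
    Database.REFSEQ: DatabaseThresholds(1e-6),
    Database.NR: DatabaseThresholds(1e-6),
    Database.BACTERIAL: DatabaseThresholds(1e-6),
    Database.TE: DatabaseThresholds(1e-6),
    Database.RPRO_TRANSCRIPTS: DatabaseThresholds(1e-8, min_identity=100.0),
    Database.RPRO_GENEID: DatabaseThresholds(1e-8, min_identity=100.0),
    Database.RPRO_GENEID_TRASH: DatabaseThresholds(1e-8, min_identity=100.0),
}


def apply_search_filters(
    hits: Iterable[HomologyHit],
    cfg: Mapping[Database, DatabaseThresholds] = DEFAULT_FILTERS,
) -> list[HomologyHit]:
    """Drop hits failing their database's e-value/identity thresholds.

    Idempotent: filtering a filtered list changes nothing.  Raises
    :class:`ConfigError` if a hit's database has no thresholds.
    """
    kept: list[HomologyHit] = []
    for hit in hits:
        thr = cfg.get(hit.database)
        if thr is None:
            raise ConfigError(f"no filter thresholds for database {hit.database.value}")
        if hit.evalue > thr.max_evalue:
            continue
        if thr.min_identity is not None and hit.pct_identity < thr.min_identity:
            continue
        kept.append(hit)
    return kept


def flag_contaminant_segments(
    hits: Iterable[HomologyHit],
    identity_cutoff: float = 95.0,
    *,
    inclusive: bool = False,
) -> set[str]:
    """Scaffolds with a bacterial or TE hit above the identity cutoff.

    The candidate-level screen discards similarity strictly above 95 %
    (nucleotide or amino acid); the genome-level bacterial screen uses
    exact 100 % identity, expressed here as ``identity_cutoff=100,
    inclusive=True``.
    """
    if not 0.0 <= identity_cutoff <= 100.0:
        raise ValueError("identity_cutoff must be in [0, 100]")
    flagged: set[str] = set()
    for hit in hits:
        if hit.database not in CONTAMINANT_DATABASES:
            continue
        if hit.pct_identity > identity_cutoff or (
            inclusive and hit.pct_identity == identity_cutoff
        ):
            flagged.add(hit.scaffold_id)
    return flagged


def _hit_tier(
    hit: HomologyHit, conservation: Mapping[str, Conservation]
) -> int | None:
    """Evidence rank contributed by one hit (lower is stronger).

    1. conserved known gene in RefSeq or NR
    2. conserved hypothetical gene in RefSeq
    3. annotated gene of the species itself
    4. unconserved hypothetical gene in RefSeq or NR
    5. discarded annotation (GeneID trash)

    Transcript hits carry no tier: transcript support is tracked as a
    separate, strongest line of evidence.
    """
    db = hit.database
    if db in (Database.REFSEQ, Database.NR):
        label = conservation.get(hit.subject_id)
        if label is None:
            raise MetadataError(
                f"no conservation label for {db.value} subject {hit.subject_id!r}"
            )
        label = Conservation(label)
        if label is Conservation.KNOWN:
            return 1
        if label is Conservation.CONSERVED_HYPOTHETICAL:
            return 2 if db is Database.REFSEQ else None
        return 4
    if db is Database.RPRO_GENEID:
        return 3
    if db is Database.RPRO_GENEID_TRASH:
        return 5
    return None


def assign_tier(
    scaffold_id: str,
    hits: Sequence[HomologyHit],
    conservation: Mapping[str, Conservation] = {},
) -> EvidenceRecord:
    """Summarise one scaffold's filtered hits into an evidence record.

    ``hits`` must already be filtered and contaminant-screened; only
    this scaffold's hits may be passed.  The record's tier is the best
    (lowest) rank any hit provides, or None when no hit qualifies.
    Conservation labels are supplied metadata, never inferred.
    """
    dbs: set[Database] = set()
    best: int | None = None
    for hit in hits:
        if hit.scaffold_id != scaffold_id:
            raise ValueError(
                f"hit for {hit.scaffold_id!r} passed to assign_tier({scaffold_id!r})"
            )
        if hit.database not in GENE_EVIDENCE_DATABASES:
            continue
        dbs.add(hit.database)
        rank = _hit_tier(hit, conservation)
        if rank is not None and (best is None or rank < best):
            best = rank
    return EvidenceRecord(
        scaffold_id=scaffold_id,
        databases_hit=frozenset(dbs),
        has_transcript=Database.RPRO_TRANSCRIPTS in dbs,
        tier=best,
    )


def build_evidence_records(
    hits: Sequence[HomologyHit],
    conservation: Mapping[str, Conservation] = {},
) -> list[EvidenceRecord]:
    """Group filtered hits by scaffold and assign tiers to each."""
    per_scaffold: dict[str, list[HomologyHit]] = {}
    for hit in hits:
        per_scaffold.setdefault(hit.scaffold_id, []).append(hit)
    return [
        assign_tier(sid, scaffold_hits, conservation)
        for sid, scaffold_hits in sorted(per_scaffold.items())
    ]


def select_testable(
    records: Iterable[EvidenceRecord], min_databases: int = 3
) -> list[EvidenceRecord]:
    """Mark candidates with hits in enough distinct databases.

    A record is selected when it has qualifying hits in at least
    ``min_databases`` distinct gene-evidence databases, with transcript
    support preferred.  Output ordering: transcript-bearing first, then
    by tier (unranked last), then by number of databases (descending),
    then scaffold id for determinism.
    """
    if min_databases < 1:
        raise ValueError("min_databases must be >= 1")
    out = [
        EvidenceRecord(
            scaffold_id=r.scaffold_id,
            databases_hit=r.databases_hit,
            has_transcript=r.has_transcript,
            tier=r.tier,
            selected_for_testing=len(r.databases_hit) >= min_databases,
        )
        for r in records
    ]
    out.sort(
        key=lambda r: (
            not r.has_transcript,
            r.tier if r.tier is not None else 6,
            -len(r.databases_hit),
            r.scaffold_id,
        )
    )
    return out


def write_evidence_table(records: Iterable[EvidenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "scaffold_id\tdatabases_hit\thas_transcript\ttier\tselected_for_testing\n"
        )
        for r in records:
            dbs = ",".join(sorted(d.value for d in r.databases_hit)) or "-"
            tier = str(r.tier) if r.tier is not None else "NA"
            fh.write(
                f"{r.scaffold_id}\t{dbs}\t{int(r.has_transcript)}\t{tier}\t"
                f"{int(r.selected_for_testing)}\n"
            )


def read_conservation_labels(path: str | Path) -> dict[str, Conservation]:
    """Read a 2-column TSV of subject_id -> conservation label."""
    labels: dict[str, Conservation] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise MetadataError(
                    f"line {lineno}: expected 2 columns in conservation table"
                )
            try:
                labels[fields[0]] = Conservation(fields[1])
            except ValueError as exc:
                raise MetadataError(f"line {lineno}: {exc}") from exc
    return labels
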