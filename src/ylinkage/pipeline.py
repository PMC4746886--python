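"""Pipeline orchestration: count -> screen -> classify -> report.

Each stage writes a plain TSV/JSON intermediate, and the final run
report is recomputed from those emitted files rather than from
in-memory state, so a report-only rerun reproduces it bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

import ylinkage
from ylinkage.errors import ConfigError
from ylinkage.evidence import (
    Conservation,
    Database,
    DEFAULT_FILTERS,
    IdentityKind,
    apply_search_filters,
    build_evidence_records,
    flag_contaminant_segments,
    parse_tabular_hits,
    read_conservation_labels,
    select_testable,
    write_evidence_table,
)
from ylinkage.linkage import (
    Call,
    LinkageCall,
    ModelConfig,
    classify_all,
    global_male_fraction,
    min_read_threshold,
    summarize_candidates,
)
from ylinkage.provenance import (
    LibraryCatalog,
    MatchMode,
    RPROC1_LIBRARIES,
    Sex,
    count_reads_per_scaffold,
    parse_read_map,
    read_count_table,
    read_lengths,
    write_count_table,
)

logger = logging.getLogger("ylinkage")

CATALOG_PRESETS: dict[str, LibraryCatalog] = {"rproc1": RPROC1_LIBRARIES}

CALLS_COLUMNS = ("scaffold_id", "call", "n_total", "n_male", "pct_male", "fp_probability")


class PipelineStageError(ConfigError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class HitTableSpec:
    path: str
    database: Database
    identity_kind: IdentityKind


@dataclass
class PipelineConfig:
    read_map: str
    lengths: str
    out_dir: str
    catalog: LibraryCatalog = RPROC1_LIBRARIES
    model: ModelConfig = field(default_factory=ModelConfig)
    hit_tables: tuple[HitTableSpec, ...] = ()
    conservation: str | None = None
    contaminant_identity_cutoff: float = 95.0
    contaminant_inclusive: bool = False
    min_databases: int = 3
    skip_unknown: bool = False
    seed: int = 0

    def validate(self) -> None:
        for fieldname in ("read_map", "lengths"):
            p = getattr(self, fieldname)
            if not Path(p).is_file():
                raise ConfigError(f"config field {fieldname!r}: no such file: {p}")
        for h in self.hit_tables:
            if not Path(h.path).is_file():
                raise ConfigError(f"hit table not found: {h.path}")
        if self.conservation is not None and not Path(self.conservation).is_file():
            raise ConfigError(f"conservation table not found: {self.conservation}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration.

    ``libraries`` is either a preset name (``rproc1``) or a list of
    ``{prefix, sex}`` mappings; ``model`` holds alpha / min_reads /
    x_band_halfwidth; ``hits`` is a list of
    ``{path, database, identity_kind}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        libraries = raw.get("libraries", "rproc1")
        if isinstance(libraries, str):
            catalog = CATALOG_PRESETS[libraries.lower()]
        else:
            catalog = LibraryCatalog(
                entries=tuple((e["prefix"], Sex(e["sex"])) for e in libraries),
                match_mode=MatchMode(raw.get("match_mode", "prefix")),
            )
        model = ModelConfig(**raw.get("model", {}))
        hit_tables = tuple(
            HitTableSpec(
                path=h["path"],
                database=Database(h["database"]),
                identity_kind=IdentityKind(h["identity_kind"]),
            )
            for h in raw.get("hits", [])
        )
        return PipelineConfig(
            read_map=raw["read_map"],
            lengths=raw["lengths"],
            out_dir=raw.get("out_dir", "ylinkage_out"),
            catalog=catalog,
            model=model,
            hit_tables=hit_tables,
            conservation=raw.get("conservation"),
            contaminant_identity_cutoff=raw.get("contaminant_identity_cutoff", 95.0),
            contaminant_inclusive=raw.get("contaminant_inclusive", False),
            min_databases=raw.get("min_databases", 3),
            skip_unknown=raw.get("skip_unknown", False),
            seed=raw.get("seed", 0),
        )
    except KeyError as exc:
        raise ConfigError(f"missing config field: {exc}") from exc


def write_calls_table(
    calls: Sequence[LinkageCall],
    counts_by_id: Mapping[str, Any],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CALLS_COLUMNS) + "\n")
        for call in calls:
            c = counts_by_id[call.scaffold_id]
            mf = c.male_fraction
            pct = "NA" if mf is None else f"{100.0 * mf:.1f}"
            fp = "NA" if call.fp_probability is None else repr(call.fp_probability)
            fh.write(
                f"{call.scaffold_id}\t{call.call.value}\t{c.n_total}\t"
                f"{c.n_male}\t{pct}\t{fp}\n"
            )


def read_calls_table(path: str | Path) -> list[LinkageCall]:
    calls: list[LinkageCall] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            sid, callname, _tot, _male, _pct, fp = line.rstrip("\n").split("\t")
            calls.append(
                LinkageCall(
                    scaffold_id=sid,
                    call=Call(callname),
                    fp_probability=None if fp == "NA" else float(fp),
                )
            )
    return calls


@dataclass
class RunReport:
    """Headline numbers of one pipeline run.

    Every value is recomputed from the emitted TSVs (see
    :func:`report_from_outputs`), so the report is a pure function of
    the run's on-disk artifacts.
    """

    n_scaffolds: int
    total_male_reads: int
    total_female_reads: int
    p_male_pct: float
    min_reads_used: int
    min_reads_model: int
    alpha: float
    n_retained: int
    n_y_candidates: int
    y_candidate_bp: int
    retained_bp: int
    pct_of_retained_genome: float
    expected_false_positives: float
    n_contaminants: int
    tier_table: dict[str, int]
    n_selected_for_testing: int
    version: str
    config_fingerprint: str
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def genome_fraction(candidate_bp: float, genome_bp: float) -> float:
    """Percent of the genome covered by candidates, to one decimal.

    genome_fraction(1.6e6, 700e6) -> 0.2
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be > 0")
    return round(100.0 * candidate_bp / genome_bp, 1)


def _fingerprint(cfg: PipelineConfig) -> str:
    blob = json.dumps(
        {
            "read_map": cfg.read_map,
            "lengths": cfg.lengths,
            "catalog": [[p, s.value] for p, s in cfg.catalog.entries],
            "model": [cfg.model.alpha, cfg.model.min_reads, cfg.model.x_band_halfwidth],
            "hits": [[h.path, h.database.value, h.identity_kind.value] for h in cfg.hit_tables],
            "contaminant_cutoff": cfg.contaminant_identity_cutoff,
            "min_databases": cfg.min_databases,
            "seed": cfg.seed,
            "version": ylinkage.__version__,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def report_from_outputs(
    out_dir: str | Path, cfg: PipelineConfig
) -> RunReport:
    """Recompute the run report purely from emitted intermediates."""
    out = Path(out_dir)
    counts = read_count_table(out / "counts.tsv")
    calls = read_calls_table(out / "calls.tsv")
    contaminants_path = out / "contaminants.txt"
    n_contaminants = (
        sum(1 for line in open(contaminants_path) if line.strip())
        if contaminants_path.is_file()
        else 0
    )
    stats = global_male_fraction(counts)
    summary = summarize_candidates(calls, counts, stats)
    tier_table: dict[str, int] = {}
    n_selected = 0
    evidence_path = out / "evidence.tsv"
    if evidence_path.is_file():
        with open(evidence_path) as fh:
            fh.readline()
            for line in fh:
                _sid, _dbs, _tr, tier, selected = line.rstrip("\n").split("\t")
                tier_table[tier] = tier_table.get(tier, 0) + 1
                n_selected += int(selected)
    return RunReport(
        n_scaffolds=len(counts),
        total_male_reads=stats.total_male,
        total_female_reads=stats.total_female,
        p_male_pct=round(100.0 * stats.p_male, 1),
        min_reads_used=cfg.model.min_reads,
        min_reads_model=min_read_threshold(stats.p_male, cfg.model.alpha),
        alpha=cfg.model.alpha,
        n_retained=summary.n_retained,
        n_y_candidates=summary.n_y_candidates,
        y_candidate_bp=summary.y_candidate_bp,
        retained_bp=summary.retained_bp,
        pct_of_retained_genome=summary.pct_of_retained_genome,
        expected_false_positives=summary.expected_false_positives,
        n_contaminants=n_contaminants,
        tier_table=dict(sorted(tier_table.items())),
        n_selected_for_testing=n_selected,
        version=ylinkage.__version__,
        config_fingerprint=_fingerprint(cfg),
        seed=cfg.seed,
    )


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute count -> screen -> classify -> report, writing intermediates.

    Outputs in ``cfg.out_dir``: counts.tsv, calls.tsv, summary.json,
    contaminants.txt + evidence.tsv (when hit tables are given) and
    report.json.  Any stage error aborts with the stage named.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "count"
    try:
        lengths = read_lengths(cfg.lengths)
        counting = count_reads_per_scaffold(
            parse_read_map(cfg.read_map),
            cfg.catalog,
            lengths,
            skip_unknown=cfg.skip_unknown,
        )
        counts = counting.counts
        write_count_table(counts, out / "counts.tsv")
        if counting.n_unknown_skipped:
            logger.warning(
                "%d reads with unknown library prefixes skipped",
                counting.n_unknown_skipped,
            )
        stats = global_male_fraction(counts)

        stage = "evidence"
        contaminants: set[str] = set()
        if cfg.hit_tables:
            hits = []
            for h in cfg.hit_tables:
                hits.extend(parse_tabular_hits(h.path, h.database, h.identity_kind))
            hits = apply_search_filters(hits, DEFAULT_FILTERS)
            contaminants = flag_contaminant_segments(
                hits,
                cfg.contaminant_identity_cutoff,
                inclusive=cfg.contaminant_inclusive,
            )
            clean_hits = [h for h in hits if h.scaffold_id not in contaminants]
            conservation: Mapping[str, Conservation] = (
                read_conservation_labels(cfg.conservation) if cfg.conservation else {}
            )
            records = select_testable(
                build_evidence_records(clean_hits, conservation),
                min_databases=cfg.min_databases,
            )
            write_evidence_table(records, out / "evidence.tsv")
            with open(out / "contaminants.txt", "w") as fh:
                for sid in sorted(contaminants):
                    fh.write(sid + "\n")

        stage = "classify"
        model_n = min_read_threshold(stats.p_male, cfg.model.alpha)
        if model_n != cfg.model.min_reads:
            logger.warning(
                "configured min_reads=%d differs from model-derived threshold %d "
                "at p=%.4f, alpha=%g",
                cfg.model.min_reads,
                model_n,
                stats.p_male,
                cfg.model.alpha,
            )
        calls = classify_all(counts, stats, cfg.model, contaminants)
        write_calls_table(calls, {c.scaffold_id: c for c in counts}, out / "calls.tsv")
        summary = summarize_candidates(calls, counts, stats)
        with open(out / "summary.json", "w") as fh:
            json.dump(
                {
                    "p_male": stats.p_male,
                    "total_male": stats.total_male,
                    "total_female": stats.total_female,
                    "min_reads_used": cfg.model.min_reads,
                    "min_reads_model": model_n,
                    "n_retained": summary.n_retained,
                    "n_y_candidates": summary.n_y_candidates,
                    "y_candidate_bp": summary.y_candidate_bp,
                    "retained_bp": summary.retained_bp,
                    "pct_of_retained_genome": summary.pct_of_retained_genome,
                    "expected_false_positives": summary.expected_false_positives,
                    "hist_scaffolds": summary.hist_scaffolds,
                    "hist_bp": summary.hist_bp,
                },
                fh,
                indent=2,
            )

        stage = "report"
        report = report_from_outputs(out, cfg)
        with open(out / "report.json", "w") as fh:
            fh.write(report.to_json() + "\n")
        return report
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
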