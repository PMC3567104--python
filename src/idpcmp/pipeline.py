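"""End-to-end orchestration of the comparative disorder study.

``run_pipeline`` drives the full workflow from a single config: read and
filter both proteomes, obtain per-residue score tracks (from files or the
built-in predictor), compute per-protein metrics, summarize each proteome
(disorder-content table and binned distributions), run the single-organism
enrichment of disordered proteins, the per-GO-class cross-species comparison,
the three-way categorization of the two resulting term lists, semantic
summarization of each list, and — when an ortholog table is supplied — the
ortholog-restricted validation.

All outputs are plain TSV/JSON.  run_log.json records parameters, package and
library versions and input checksums; identical inputs and config reproduce
byte-identical outputs.  Wall-clock timings go to a separate timings.json,
which is the only non-deterministic artifact.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy
import statsmodels
import yaml

from . import __version__
from .class_comparison import compare_classes, results_to_frame
from .disorder import (
    BIN_EDGES_FINE,
    DisorderMetrics,
    bin_fractions,
    metrics_table,
    parse_scores,
    predict_proteome,
)
from .enrichment import filter_enrichment, term_enrichment
from .errors import ConfigError, DataError
from .go_ontology import (
    expand_annotations,
    parse_obo,
    read_annotations,
    shared_terms,
)
from .go_summarization import information_content, summarize_terms, superclusters
from .ortholog_validation import (
    class_ortholog_summary,
    ortholog_t_tests,
    read_orthologs,
)
from .sequence_io import FILTER_RULES, filter_proteome, read_fasta


@dataclass
class RunConfig:
    """Every user-facing parameter of the study, with its default."""

    fasta_a: str
    fasta_b: str
    obo: str
    annotations_a: str
    annotations_b: str
    outdir: str
    organism_a: str = "organism_a"
    organism_b: str = "organism_b"
    scores_a: str | None = None
    scores_b: str | None = None
    dbr_scores_a: str | None = None
    dbr_scores_b: str | None = None
    orthologs: str | None = None
    score_dialect: str = "long_tsv"
    predictor: str = "builtin"  # used when score paths are absent
    filters: Sequence[str] = FILTER_RULES
    threshold: float = 0.5
    dbr_threshold: float = 0.5
    ldw_min: int = 30
    dbr_min_len: int = 6
    disordered_cutoff: float = 50.0
    criteria: Sequence[str] = ("ldw",)
    alpha: float = 0.05
    min_excess: float = 0.05
    enrichment_method: str = "ease"
    min_count: int = 2
    relations: Sequence[str] = ("is_a",)
    sim_threshold: float = 0.7
    supercluster_threshold: float = 0.5
    bin_edges: Sequence[float] = BIN_EDGES_FINE
    ortholog_mode: str = "paired"
    ortholog_metric: str = "pct_disordered"
    ortholog_membership: str = "either"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as handle:
            data = yaml.safe_load(handle)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def validate(self) -> None:
        if not self.criteria:
            raise ConfigError("criteria must be non-empty")
        for key in ("fasta_a", "fasta_b", "obo", "annotations_a", "annotations_b"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise ConfigError(f"{key}: path does not exist: {p}")
        for key in ("scores_a", "scores_b", "dbr_scores_a", "dbr_scores_b",
                    "orthologs"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{key}: path does not exist: {p}")


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _summary_row(metrics: Mapping[str, DisorderMetrics]) -> dict[str, float]:
    """Proteome-level disorder summary (mirrors the per-organism table)."""
    values = list(metrics.values())
    n = len(values)
    has_dbr = all(m.n_dbr is not None for m in values) and n > 0
    row = {
        "n_proteins": n,
        "mean_pct_disordered": float(np.mean([m.pct_disordered for m in values])),
        "pct_proteins_with_ldw": 100.0 * sum(m.n_ldw >= 1 for m in values) / n,
        "mean_n_ldw": float(np.mean([m.n_ldw for m in values])),
        "mean_pct_in_ldw": float(np.mean([m.pct_in_ldw for m in values])),
        "pct_disordered_proteins": 100.0
        * sum(m.is_disordered_protein for m in values) / n,
    }
    if has_dbr:
        row["pct_proteins_with_dbr"] = (
            100.0 * sum((m.n_dbr or 0) >= 1 for m in values) / n
        )
        row["mean_n_dbr"] = float(np.mean([m.n_dbr for m in values]))
        row["mean_pct_dbr_residues"] = float(
            np.mean([m.pct_dbr_residues for m in values])
        )
    return row


def _metrics_frame(metrics: Mapping[str, DisorderMetrics]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(m) for m in metrics.values()])
    return frame.sort_values("protein_id").reset_index(drop=True)


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run the full comparative study; returns artifact name -> path."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def stage(name: str):
        return _StageTimer(name, timings)

    try:
        with stage("input"):
            proteome_a, report_a = filter_proteome(
                read_fasta(cfg.fasta_a, cfg.organism_a), cfg.filters
            )
            proteome_b, report_b = filter_proteome(
                read_fasta(cfg.fasta_b, cfg.organism_b), cfg.filters
            )
            dag = parse_obo(cfg.obo, relations=tuple(cfg.relations))
            ann_a = expand_annotations(
                dag, read_annotations(cfg.annotations_a, cfg.organism_a)
            )
            ann_b = expand_annotations(
                dag, read_annotations(cfg.annotations_b, cfg.organism_b)
            )
        for label, report in (("a", report_a), ("b", report_b)):
            path = outdir / f"filter_report_{label}.json"
            path.write_text(report.to_json() + "\n")
            artifacts[f"filter_report_{label}"] = path

        with stage("scores"):
            profiles_a = _load_profiles(cfg, proteome_a, cfg.scores_a)
            profiles_b = _load_profiles(cfg, proteome_b, cfg.scores_b)
            dbr_a = (
                parse_scores(cfg.dbr_scores_a, cfg.score_dialect, "dbr")
                if cfg.dbr_scores_a
                else None
            )
            dbr_b = (
                parse_scores(cfg.dbr_scores_b, cfg.score_dialect, "dbr")
                if cfg.dbr_scores_b
                else None
            )

        with stage("metrics"):
            metrics_a = metrics_table(
                profiles_a, dbr_a, cfg.threshold, cfg.dbr_threshold,
                cfg.ldw_min, cfg.disordered_cutoff, cfg.dbr_min_len,
            )
            metrics_b = metrics_table(
                profiles_b, dbr_b, cfg.threshold, cfg.dbr_threshold,
                cfg.ldw_min, cfg.disordered_cutoff, cfg.dbr_min_len,
            )
            # score files may cover more proteins than survived filtering
            ids_a, ids_b = set(proteome_a.ids()), set(proteome_b.ids())
            metrics_a = {p: m for p, m in metrics_a.items() if p in ids_a}
            metrics_b = {p: m for p, m in metrics_b.items() if p in ids_b}
        for label, metrics in (("a", metrics_a), ("b", metrics_b)):
            path = outdir / f"metrics_{label}.tsv"
            _write_tsv(_metrics_frame(metrics), path)
            artifacts[f"metrics_{label}"] = path
        summary = pd.DataFrame(
            [
                {"organism": cfg.organism_a, **_summary_row(metrics_a)},
                {"organism": cfg.organism_b, **_summary_row(metrics_b)},
            ]
        )
        _write_tsv(summary, outdir / "disorder_summary.tsv")
        artifacts["disorder_summary"] = outdir / "disorder_summary.tsv"
        bins = []
        for organism, metrics in (
            (cfg.organism_a, metrics_a), (cfg.organism_b, metrics_b)
        ):
            frame = bin_fractions(
                metrics.values(), "pct_disordered", cfg.bin_edges
            )
            frame.insert(0, "organism", organism)
            bins.append(frame)
        _write_tsv(pd.concat(bins, ignore_index=True), outdir / "disorder_bins.tsv")
        artifacts["disorder_bins"] = outdir / "disorder_bins.tsv"

        with stage("enrichment"):
            study = sorted(
                pid for pid, m in metrics_a.items() if m.n_ldw >= 1
            )
            enr = term_enrichment(
                study, proteome_a.ids(), ann_a, method=cfg.enrichment_method
            )
            enr_kept = filter_enrichment(enr, cfg.alpha, cfg.min_count)
        enr_frame = pd.DataFrame([vars(r) for r in enr]) if enr else pd.DataFrame()
        _write_tsv(enr_frame, outdir / "enrichment_a.tsv")
        artifacts["enrichment_a"] = outdir / "enrichment_a.tsv"
        enrichment_terms = sorted(r.term_id for r in enr_kept)

        comparison_terms: list[str] = []
        with stage("comparison"):
            for criterion in cfg.criteria:
                results = compare_classes(
                    metrics_a, metrics_b, ann_a, ann_b,
                    criterion=criterion, alpha=cfg.alpha,
                    min_excess=cfg.min_excess,
                )
                frame = results_to_frame(results)
                path = outdir / f"comparison_{criterion}.tsv"
                _write_tsv(frame, path)
                artifacts[f"comparison_{criterion}"] = path
                if criterion == cfg.criteria[0]:
                    comparison_terms = sorted(
                        r.term_id for r in results if r.significant
                    )

        with stage("categorize"):
            union = sorted(set(enrichment_terms) | set(comparison_terms))
            cat_frame = pd.DataFrame(
                {
                    "term_id": union,
                    "in_enrichment": [t in set(enrichment_terms) for t in union],
                    "in_comparison": [t in set(comparison_terms) for t in union],
                    "category": [
                        "both"
                        if t in set(enrichment_terms) and t in set(comparison_terms)
                        else "enrichment_only"
                        if t in set(enrichment_terms)
                        else "comparison_only"
                        for t in union
                    ],
                }
            )
            _write_tsv(cat_frame, outdir / "term_categories.tsv")
            artifacts["term_categories"] = outdir / "term_categories.tsv"

        with stage("summarize"):
            ic = information_content(ann_a, dag)
            for name, term_list, source in (
                ("clusters_enrichment", enrichment_terms,
                 {r.term_id: r.p_adj for r in enr_kept}),
                ("clusters_comparison", comparison_terms, None),
            ):
                pvals = (
                    source
                    if source is not None
                    else {t: 0.0 for t in term_list}
                )
                usable = {t: p for t, p in pvals.items() if t in ic}
                clusters = summarize_terms(usable, dag, ic, cfg.sim_threshold)
                super_map = superclusters(
                    clusters, dag, ic, cfg.supercluster_threshold
                )
                rows = [
                    {
                        "term_id": member,
                        "representative": c.representative,
                        "cluster": idx,
                        "supercluster": super_map[c.representative],
                        "uniqueness": c.uniqueness[member],
                        "p_adj": usable[member],
                    }
                    for idx, c in enumerate(clusters)
                    for member in c.members
                ]
                path = outdir / f"{name}.tsv"
                _write_tsv(pd.DataFrame(rows), path)
                artifacts[name] = path
    except (ConfigError, DataError):
        raise
    except Exception as exc:  # annotate unexpected failures with the stage
        raise DataError(f"pipeline stage failed: {exc}") from exc

    if cfg.orthologs:
        with stage("orthologs"):
            omap = read_orthologs(cfg.orthologs).resolve(
                proteome_a.ids(), proteome_b.ids()
            )
            summaries = [
                class_ortholog_summary(
                    t, omap, metrics_a, metrics_b, ann_a, ann_b,
                    cfg.ortholog_metric, cfg.ortholog_membership,
                )
                for t in comparison_terms
            ]
            _write_tsv(
                pd.DataFrame([vars(s) for s in summaries]),
                outdir / "ortholog_classes.tsv",
            )
            artifacts["ortholog_classes"] = outdir / "ortholog_classes.tsv"
            usable = [s for s in summaries if s.n_pairs > 0]
            report: dict = {"n_classes_tested": len(summaries),
                            "n_classes_with_orthologs": len(usable)}
            if len(usable) >= 2:
                tests = ortholog_t_tests(
                    usable, cfg.ortholog_mode, cfg.ortholog_metric
                )
                report["tests"] = asdict(tests)
            path = outdir / "ortholog_report.json"
            path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
            artifacts["ortholog_report"] = path

    log = {
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "parameters": _jsonable(asdict(cfg)),
        "input_checksums": {
            key: _sha256(getattr(cfg, key))
            for key in (
                "fasta_a", "fasta_b", "obo", "annotations_a", "annotations_b",
                "scores_a", "scores_b", "dbr_scores_a", "dbr_scores_b",
                "orthologs",
            )
            if getattr(cfg, key)
        },
        "n_shared_terms": len(shared_terms(ann_a, ann_b)),
        "seed": cfg.seed,
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    artifacts["run_log"] = log_path
    timing_path = outdir / "timings.json"
    timing_path.write_text(json.dumps(timings, indent=2, sort_keys=True) + "\n")
    artifacts["timings"] = timing_path
    return artifacts


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _load_profiles(cfg: RunConfig, proteome, scores_path):
    if scores_path:
        return parse_scores(scores_path, cfg.score_dialect)
    if cfg.predictor != "builtin":
        raise ConfigError(
            f"predictor {cfg.predictor!r} requires score files; "
            "only 'builtin' can run without them"
        )
    return predict_proteome(proteome)


class _StageTimer:
    def __init__(self, name: str, sink: dict[str, float]) -> None:
        self.name = name
        self.sink = sink

    def __enter__(self):
        self.start = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.sink[self.name] = round(time.perf_counter() - self.start, 3)
        if exc is not None and not isinstance(exc, (ConfigError, DataError)):
            raise DataError(f"stage {self.name!r} failed: {exc}") from exc
        return False
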