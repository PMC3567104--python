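"""Seeded generators for synthetic two-proteome disorder studies.

The generator emulates every input the comparative pipeline consumes: two
proteomes with sequences whose residue composition tracks a hidden
ordered/disordered state, per-residue disorder and binding-region score
tracks, a small GO DAG, annotation tables with *planted* class-level disorder
enrichment at a configurable effect size, and an ortholog pair table.

Each protein is drawn from one of two archetypes — mostly-ordered or
mostly-disordered — whose state tracks alternate ordered and disordered
segments with geometric lengths.  A two-state segmental model (rather than
i.i.d. residue flags) is used so that long-disordered-window statistics are
non-trivial: i.i.d. flags essentially never produce runs of 30.  Disordered
segments are enriched in disorder-promoting residues (P, E, S, K, Q ...), so
the built-in composition predictor responds to the same signal.

Planting acts on the class-conditional probability that a member protein is
disordered (>= 50% of residues called at threshold 0.5): members of a planted
term are sampled from the realized disordered/ordered pools at the configured
per-organism rates, so one truth table serves the >= 50%, LDW and DBR
criteria alike (the archetypes separate all three).

Identical seeds reproduce byte-identical studies; all randomness flows from a
single ``numpy.random.default_rng(seed)`` and no unordered container affects
output order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .disorder import DisorderProfile
from .errors import ConfigError
from .go_ontology import AnnotationSet, GoDag, GoTerm
from .ortholog_validation import OrthologMap, OrthologPair
from .sequence_io import ProteinRecord, Proteome

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Residue composition weights per hidden state (normalized at use).  The
# disordered profile is rich in P/E/S/K/Q/G, the ordered one in hydrophobics.
_ORDERED_WEIGHTS = np.array(
    [8, 2, 5, 5, 5, 7, 2, 7, 5, 10, 3, 4, 3, 3, 4, 5, 5, 8, 2, 4], dtype=float
)
_DISORDERED_WEIGHTS = np.array(
    [6, 1, 6, 10, 2, 8, 2, 2, 9, 3, 1, 4, 10, 8, 5, 11, 6, 3, 1, 1],
    dtype=float,
)


@dataclass
class SyntheticStudyConfig:
    """Study conditions for the synthetic benchmark.

    Defaults describe a proteome pair large enough to exercise the full
    class-comparison machinery: 600 proteins per organism, planted classes of
    200 members with disordered-protein rates 0.6 (organism A) vs 0.2
    (organism B).
    """

    seed: int = 0
    n_proteins: int = 600
    length_min: int = 80
    length_max: int = 400
    #: (ordered-run mean, disordered-run mean) for the mostly-ordered archetype
    ordered_type_run_means: tuple[float, float] = (70.0, 12.0)
    #: same for the mostly-disordered archetype
    disordered_type_run_means: tuple[float, float] = (15.0, 60.0)
    #: per-state Beta score means (ordered-state, disordered-state)
    score_means: tuple[float, float] = (0.15, 0.80)
    score_concentration: float = 12.0
    #: probability that a disordered segment is also a binding (DBR) segment
    dbr_segment_prob: float = 0.35
    #: baseline probability of the disordered archetype, per organism
    p_disordered_type: tuple[float, float] = (0.30, 0.30)
    n_terms: int = 60
    max_parents: int = 2
    n_planted_terms: int = 3
    #: disordered-protein probability within planted classes, per organism
    planted_rates: tuple[float, float] = (0.60, 0.20)
    planted_class_size: int = 200
    term_size_range: tuple[int, int] = (20, 60)
    ortholog_fraction: float = 0.5

    def validate(self) -> None:
        probs = [
            *self.p_disordered_type, *self.planted_rates,
            self.dbr_segment_prob, *self.score_means, self.ortholog_fraction,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if self.n_planted_terms > self.n_terms - 1:
            raise ConfigError("n_planted_terms must leave room for the root")
        if self.length_min < 1 or self.length_max < self.length_min:
            raise ConfigError("invalid protein length range")
        if self.n_proteins < 1 or self.n_terms < 1:
            raise ConfigError("n_proteins and n_terms must be positive")
        if self.planted_class_size > self.n_proteins:
            raise ConfigError("planted_class_size exceeds n_proteins")


@dataclass
class SyntheticStudy:
    """A fully cross-referenced synthetic dataset plus its ground truth."""

    config: SyntheticStudyConfig
    proteome_a: Proteome
    proteome_b: Proteome
    profiles_a: dict[str, DisorderProfile]
    profiles_b: dict[str, DisorderProfile]
    dbr_profiles_a: dict[str, DisorderProfile]
    dbr_profiles_b: dict[str, DisorderProfile]
    dag: GoDag
    annotations_a: AnnotationSet
    annotations_b: AnnotationSet
    ortholog_map: OrthologMap
    #: planted term -> (rate_a, rate_b); empty for null studies
    truth: dict[str, tuple[float, float]] = field(default_factory=dict)


def _geometric_lengths(rng: np.random.Generator, mean: float, k: int) -> np.ndarray:
    p = min(1.0, 1.0 / max(mean, 1.0))
    return rng.geometric(p, size=k)


def _state_track(
    rng: np.random.Generator, length: int, run_means: tuple[float, float]
) -> np.ndarray:
    """Alternating ordered(0)/disordered(1) segments with geometric lengths."""
    mean_o, mean_d = run_means
    # stationary start-state probability proportional to mean run length
    start_disordered = rng.random() < mean_d / (mean_o + mean_d)
    n_segments = max(4, int(2 * length / min(mean_o, mean_d)) + 4)
    lens_o = _geometric_lengths(rng, mean_o, n_segments)
    lens_d = _geometric_lengths(rng, mean_d, n_segments)
    track = np.empty(length, dtype=bool)
    pos = 0
    state = bool(start_disordered)
    i = 0
    while pos < length:
        seg = int(lens_d[i] if state else lens_o[i])
        end = min(pos + seg, length)
        track[pos:end] = state
        pos = end
        state = not state
        i += 1
        if i >= n_segments:  # pragma: no cover - defensive refill
            lens_o = _geometric_lengths(rng, mean_o, n_segments)
            lens_d = _geometric_lengths(rng, mean_d, n_segments)
            i = 0
    return track


def _beta_scores(
    rng: np.random.Generator, n: int, mean: float, concentration: float
) -> np.ndarray:
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return rng.beta(a, b, size=n)


def _sample_sequence(
    rng: np.random.Generator, states: np.ndarray
) -> str:
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    p_ord = _ORDERED_WEIGHTS / _ORDERED_WEIGHTS.sum()
    p_dis = _DISORDERED_WEIGHTS / _DISORDERED_WEIGHTS.sum()
    n = states.size
    seq = np.empty(n, dtype=np.uint8)
    n_dis = int(states.sum())
    if n_dis:
        seq[states] = rng.choice(aa, size=n_dis, p=p_dis)
    if n - n_dis:
        seq[~states] = rng.choice(aa, size=n - n_dis, p=p_ord)
    return seq.tobytes().decode()


def _generate_organism(
    rng: np.random.Generator,
    cfg: SyntheticStudyConfig,
    label: str,
    prefix: str,
    p_disordered_type: float,
) -> tuple[Proteome, dict[str, DisorderProfile], dict[str, DisorderProfile], np.ndarray]:
    """Build one proteome with score tracks; returns realized disorder flags."""
    records: list[ProteinRecord] = []
    profiles: dict[str, DisorderProfile] = {}
    dbr_profiles: dict[str, DisorderProfile] = {}
    flags = np.zeros(cfg.n_proteins, dtype=bool)
    mean_o, mean_d = cfg.score_means
    width = len(str(cfg.n_proteins))
    for i in range(cfg.n_proteins):
        pid = f"{prefix}{i + 1:0{width}d}"
        length = int(rng.integers(cfg.length_min, cfg.length_max + 1))
        is_disordered_type = rng.random() < p_disordered_type
        run_means = (
            cfg.disordered_type_run_means
            if is_disordered_type
            else cfg.ordered_type_run_means
        )
        states = _state_track(rng, length, run_means)
        scores = np.where(
            states,
            _beta_scores(rng, length, mean_d, cfg.score_concentration),
            _beta_scores(rng, length, mean_o, cfg.score_concentration),
        )
        # binding regions: whole disordered segments, switched on per segment
        binding = np.zeros(length, dtype=bool)
        padded = np.concatenate(([False], states, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            if rng.random() < cfg.dbr_segment_prob:
                binding[s:e] = True
        dbr_scores = np.where(
            binding,
            _beta_scores(rng, length, mean_d, cfg.score_concentration),
            _beta_scores(rng, length, mean_o, cfg.score_concentration),
        )
        records.append(ProteinRecord(pid, _sample_sequence(rng, states)))
        profiles[pid] = DisorderProfile(pid, "synthetic", scores)
        dbr_profiles[pid] = DisorderProfile(pid, "synthetic_dbr", dbr_scores)
        # realized status under the >= 50% rule at threshold 0.5
        flags[i] = float(np.mean(scores >= 0.5)) >= 0.5
    return Proteome(label, records), profiles, dbr_profiles, flags


def _generate_dag(rng: np.random.Generator, cfg: SyntheticStudyConfig) -> GoDag:
    terms: dict[str, GoTerm] = {}
    ids = [f"GO:{i + 1:07d}" for i in range(cfg.n_terms)]
    terms[ids[0]] = GoTerm(ids[0], "synthetic root", "biological_process")
    for i in range(1, cfg.n_terms):
        n_par = int(rng.integers(1, cfg.max_parents + 1))
        n_par = min(n_par, i)
        parent_idx = sorted(rng.choice(i, size=n_par, replace=False).tolist())
        terms[ids[i]] = GoTerm(
            ids[i],
            f"synthetic process {i}",
            "biological_process",
            parents={"is_a": tuple(ids[j] for j in parent_idx)},
        )
    return GoDag(terms)


def _leaves(dag: GoDag) -> list[str]:
    has_child: set[str] = set()
    for tid in dag:
        for parent in dag.parents_of(tid):
            has_child.add(parent)
    return sorted(t for t in dag if t not in has_child)


def _planted_members(
    rng: np.random.Generator,
    flags: np.ndarray,
    size: int,
    rate: float,
    term_id: str,
) -> np.ndarray:
    n_dis = int(round(rate * size))
    pool_dis = np.flatnonzero(flags)
    pool_ord = np.flatnonzero(~flags)
    if n_dis > pool_dis.size or size - n_dis > pool_ord.size:
        raise ConfigError(
            f"planted term {term_id}: rate {rate} at size {size} is "
            f"unreachable (pools: {pool_dis.size} disordered, "
            f"{pool_ord.size} ordered)"
        )
    chosen_dis = rng.choice(pool_dis, size=n_dis, replace=False)
    chosen_ord = rng.choice(pool_ord, size=size - n_dis, replace=False)
    return np.sort(np.concatenate([chosen_dis, chosen_ord]))


def generate_study(cfg: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate a complete seeded study (see module docstring)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    proteome_a, profiles_a, dbr_a, flags_a = _generate_organism(
        rng, cfg, "organism_a", "A", cfg.p_disordered_type[0]
    )
    proteome_b, profiles_b, dbr_b, flags_b = _generate_organism(
        rng, cfg, "organism_b", "B", cfg.p_disordered_type[1]
    )
    dag = _generate_dag(rng, cfg)
    term_ids = sorted(dag)
    root = term_ids[0]
    leaves = _leaves(dag)
    if cfg.n_planted_terms > len(leaves):
        raise ConfigError(
            f"cannot plant {cfg.n_planted_terms} terms: only "
            f"{len(leaves)} leaves in the DAG"
        )
    planted = sorted(
        rng.choice(len(leaves), size=cfg.n_planted_terms, replace=False).tolist()
    )
    planted_terms = [leaves[i] for i in planted]
    truth = {
        t: (cfg.planted_rates[0], cfg.planted_rates[1]) for t in planted_terms
    }
    ann_a: dict[str, set[str]] = {pid: set() for pid in proteome_a.ids()}
    ann_b: dict[str, set[str]] = {pid: set() for pid in proteome_b.ids()}
    lo, hi = cfg.term_size_range
    for term_id in term_ids:
        if term_id == root:
            continue
        for ann, ids, flags, rate in (
            (ann_a, proteome_a.ids(), flags_a, cfg.planted_rates[0]),
            (ann_b, proteome_b.ids(), flags_b, cfg.planted_rates[1]),
        ):
            if term_id in truth:
                members = _planted_members(
                    rng, flags, cfg.planted_class_size, rate, term_id
                )
            else:
                size = int(rng.integers(lo, hi + 1))
                size = min(size, len(ids))
                members = np.sort(
                    rng.choice(len(ids), size=size, replace=False)
                )
            for idx in members.tolist():
                ann[ids[idx]].add(term_id)
    n_pairs = int(round(cfg.ortholog_fraction * cfg.n_proteins))
    idx_a = np.sort(rng.choice(cfg.n_proteins, size=n_pairs, replace=False))
    idx_b = rng.permutation(
        np.sort(rng.choice(cfg.n_proteins, size=n_pairs, replace=False))
    )
    ids_a, ids_b = proteome_a.ids(), proteome_b.ids()
    pairs = [
        OrthologPair(ids_a[int(i)], ids_b[int(j)], group=str(g + 1))
        for g, (i, j) in enumerate(zip(idx_a, idx_b))
    ]
    return SyntheticStudy(
        config=cfg,
        proteome_a=proteome_a,
        proteome_b=proteome_b,
        profiles_a=profiles_a,
        profiles_b=profiles_b,
        dbr_profiles_a=dbr_a,
        dbr_profiles_b=dbr_b,
        dag=dag,
        annotations_a=AnnotationSet(
            "organism_a", {p: frozenset(ts) for p, ts in ann_a.items()}
        ),
        annotations_b=AnnotationSet(
            "organism_b", {p: frozenset(ts) for p, ts in ann_b.items()}
        ),
        ortholog_map=OrthologMap(pairs),
        truth=truth,
    )


def generate_null_study(cfg: SyntheticStudyConfig) -> SyntheticStudy:
    """A study with no planted terms and one shared generating distribution."""
    null_cfg = replace(
        cfg,
        n_planted_terms=0,
        p_disordered_type=(cfg.p_disordered_type[0], cfg.p_disordered_type[0]),
    )
    return generate_study(null_cfg)


# ---------------------------------------------------------------------------
# plain-text serialization


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write a study as FASTA / TSV / OBO / JSON files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for suffix, proteome, profiles, dbr in (
        ("a", study.proteome_a, study.profiles_a, study.dbr_profiles_a),
        ("b", study.proteome_b, study.profiles_b, study.dbr_profiles_b),
    ):
        fasta = outdir / f"proteome_{suffix}.fasta"
        SeqIO.write(
            (
                SeqRecord(Seq(rec.sequence), id=rec.protein_id, description="")
                for rec in proteome
            ),
            str(fasta),
            "fasta",
        )
        paths[f"fasta_{suffix}"] = fasta
        paths[f"scores_{suffix}"] = _write_scores(
            outdir / f"scores_{suffix}.tsv", profiles
        )
        paths[f"dbr_scores_{suffix}"] = _write_scores(
            outdir / f"dbr_scores_{suffix}.tsv", dbr
        )
        annotations = (
            study.annotations_a if suffix == "a" else study.annotations_b
        )
        ann_path = outdir / f"annotations_{suffix}.tsv"
        with open(ann_path, "w") as handle:
            handle.write("protein_id\tterm_id\n")
            for pid in sorted(annotations.prot2terms):
                for tid in sorted(annotations.prot2terms[pid]):
                    handle.write(f"{pid}\t{tid}\n")
        paths[f"annotations_{suffix}"] = ann_path
    paths["obo"] = _write_obo(outdir / "ontology.obo", study.dag)
    ortho_path = outdir / "orthologs.tsv"
    with open(ortho_path, "w") as handle:
        handle.write("id_a\tid_b\tgroup\n")
        for pair in study.ortholog_map.pairs:
            handle.write(
                f"{pair.protein_id_a}\t{pair.protein_id_b}\t{pair.group or ''}\n"
            )
    paths["orthologs"] = ortho_path
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as handle:
        json.dump(
            {
                "seed": study.config.seed,
                "planted": {
                    t: {"rate_a": r[0], "rate_b": r[1]}
                    for t, r in sorted(study.truth.items())
                },
            },
            handle,
            indent=2,
            sort_keys=True,
        )
        handle.write("\n")
    paths["truth"] = truth_path
    return paths


def _write_scores(
    path: Path, profiles: Mapping[str, DisorderProfile]
) -> Path:
    with open(path, "w") as handle:
        handle.write("protein_id\tposition\tscore\n")
        for pid in sorted(profiles):
            for pos, score in enumerate(profiles[pid].scores, start=1):
                handle.write(f"{pid}\t{pos}\t{score:.4f}\n")
    return path


def _write_obo(path: Path, dag: GoDag) -> Path:
    with open(path, "w") as handle:
        handle.write("format-version: 1.2\nontology: synthetic\n")
        for tid in sorted(dag):
            term = dag.terms[tid]
            handle.write(f"\n[Term]\nid: {tid}\nname: {term.name}\n")
            if term.namespace:
                handle.write(f"namespace: {term.namespace}\n")
            for parent in term.parents.get("is_a", ()):
                handle.write(f"is_a: {parent} ! {dag.terms[parent].name}\n")
            for rel, targets in sorted(term.parents.items()):
                if rel == "is_a":
                    continue
                for target in targets:
                    handle.write(f"relationship: {rel} {target}\n")
            if term.obsolete:
                handle.write("is_obsolete: true\n")
    return path
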