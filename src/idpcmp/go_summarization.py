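"""Semantic summarization of GO term lists (REVIGO-style, SimRel measure).

Class-level tests emit long, redundant GO term lists.  To compress them, each
term gets an information content IC(t) = -ln p(t), with p(t) the fraction of
proteins in an explicit reference annotation corpus annotated to t (after
ancestor expansion, so p is monotone non-decreasing toward the root).  The
SimRel similarity between two terms combines the IC of their most informative
common ancestor c with its annotation probability::

    sim(t1, t2) = (2 * IC(c) / (IC(t1) + IC(t2))) * (1 - p(c))

so sharing only the root (IC = 0) gives 0, and the (1 - p) factor discounts
very common ancestors.  Terms are then clustered by single-linkage at a
similarity threshold (repeatedly merging the most similar pair above the
threshold until none remains), each cluster labeled by its member with the
best p-value.  A term's "uniqueness" is one minus its mean similarity to all
other input terms; low uniqueness marks redundant terms.  Cluster
representatives are joined into looser "superclusters" at a lower threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ConfigError, DataError
from .go_ontology import AnnotationSet, GoDag


@dataclass
class TermIC:
    """Annotation probability and information content of one term."""

    term_id: str
    probability: float
    ic: float


@dataclass
class TermCluster:
    representative: str
    members: tuple[str, ...]
    #: member -> uniqueness relative to the whole input list
    uniqueness: dict[str, float]


def information_content(
    annotations: AnnotationSet, dag: GoDag
) -> dict[str, TermIC]:
    """Resnik-style IC from an expanded reference annotation corpus.

    p(t) = (proteins annotated to t) / (proteins annotated to t's namespace
    root), so the root has p = 1 and IC = 0 (natural log).  Terms with zero
    annotations in the corpus are simply absent from the result; annotated
    terms missing from the DAG are skipped with a warning.
    """
    if not annotations.expanded:
        raise DataError("information_content requires an expanded annotation set")
    root_counts: dict[str, int] = {}
    for namespace in {dag.terms[t].namespace for t in dag}:
        roots = dag.roots(namespace)
        count = max(
            (len(annotations.proteins_for(r)) for r in roots), default=0
        )
        root_counts[namespace] = count
    out: dict[str, TermIC] = {}
    skipped = 0
    for term_id, prots in annotations.term2prots.items():
        if term_id not in dag:
            skipped += 1
            continue
        denom = root_counts.get(dag.terms[term_id].namespace, 0)
        if denom == 0 or not prots:
            continue
        p = len(prots) / denom
        out[term_id] = TermIC(term_id, p, -math.log(p))
    if skipped:
        warnings.warn(
            f"{skipped} annotated term(s) missing from the DAG were skipped",
            stacklevel=2,
        )
    return out


def simrel(
    dag: GoDag, ic: Mapping[str, TermIC], t1: str, t2: str
) -> float:
    """SimRel similarity in [0, 1]; symmetric; 0 across disjoint branches."""
    if t1 not in ic or t2 not in ic:
        raise DataError(f"terms must have IC: {t1!r}, {t2!r}")
    anc1 = set(dag.ancestors(t1)) | {t1}
    anc2 = set(dag.ancestors(t2)) | {t2}
    common = [tid for tid in anc1 & anc2 if tid in ic]
    if not common:
        return 0.0
    c = max(common, key=lambda tid: (ic[tid].ic, tid))
    ic_c = ic[c].ic
    denom = ic[t1].ic + ic[t2].ic
    if denom == 0.0 or ic_c == 0.0:
        return 0.0
    return (2.0 * ic_c / denom) * (1.0 - ic[c].probability)


def _pairwise_sims(
    dag: GoDag, ic: Mapping[str, TermIC], terms: Sequence[str]
) -> dict[tuple[str, str], float]:
    sims: dict[tuple[str, str], float] = {}
    for i, t1 in enumerate(terms):
        for t2 in terms[i + 1:]:
            sims[(t1, t2)] = simrel(dag, ic, t1, t2)
    return sims


def _components(
    terms: Sequence[str],
    sims: Mapping[tuple[str, str], float],
    threshold: float,
) -> list[list[str]]:
    """Single-linkage components of the sim >= threshold graph (deterministic)."""
    parent = {t: t for t in terms}

    def find(t: str) -> str:
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for (t1, t2), s in sorted(sims.items()):
        if s >= threshold:
            r1, r2 = find(t1), find(t2)
            if r1 != r2:
                parent[max(r1, r2)] = min(r1, r2)
    groups: dict[str, list[str]] = {}
    for t in terms:
        groups.setdefault(find(t), []).append(t)
    return [sorted(g) for g in sorted(groups.values())]


def summarize_terms(
    term_pvalues: Mapping[str, float],
    dag: GoDag,
    ic: Mapping[str, TermIC],
    threshold: float = 0.7,
) -> list[TermCluster]:
    """Collapse a scored GO term list into representative clusters.

    Clusters are the single-linkage groups at *threshold*; they partition the
    input, and raising the threshold can only split groups, never merge them.
    The representative is the member with the lowest p-value, ties broken by
    higher IC, then lexicographic term id.  Uniqueness is computed against
    the full input list.
    """
    if not 0.0 < threshold <= 1.0:
        raise ConfigError(f"threshold must be in (0, 1], got {threshold}")
    terms = sorted(term_pvalues)
    if not terms:
        return []
    missing = [t for t in terms if t not in ic]
    if missing:
        raise DataError(f"terms without IC cannot be summarized: {missing[:5]}")
    sims = _pairwise_sims(dag, ic, terms)
    uniqueness: dict[str, float] = {}
    for t in terms:
        others = [
            sims[(min(t, o), max(t, o))] for o in terms if o != t
        ]
        uniqueness[t] = 1.0 - (sum(others) / len(others)) if others else 1.0
    clusters = []
    for members in _components(terms, sims, threshold):
        rep = min(
            members,
            key=lambda t: (term_pvalues[t], -ic[t].ic, t),
        )
        clusters.append(
            TermCluster(
                representative=rep,
                members=tuple(members),
                uniqueness={t: uniqueness[t] for t in members},
            )
        )
    clusters.sort(key=lambda c: c.representative)
    return clusters


def superclusters(
    clusters: Sequence[TermCluster],
    dag: GoDag,
    ic: Mapping[str, TermIC],
    threshold: float = 0.5,
) -> dict[str, int]:
    """Join cluster representatives into loose groups at a lower threshold.

    Returns representative -> supercluster index (0-based, ordered by the
    lexicographically smallest representative in each group).
    """
    reps = sorted(c.representative for c in clusters)
    if not reps:
        return {}
    sims = _pairwise_sims(dag, ic, reps)
    groups = _components(reps, sims, threshold)
    groups.sort(key=lambda g: g[0])
    return {rep: idx for idx, group in enumerate(groups) for rep in group}
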