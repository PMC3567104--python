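"""Gene Ontology parsing, ancestor expansion and the shared-term universe.

The ontology is a directed acyclic graph of terms connected by parenthood
relations (``is_a`` by default, optionally ``part_of``).  Raw annotations
carry only the most specific term assignable to a protein; before any
class-level comparison each protein's term set is closed under the ancestor
relation so that two proteomes can be compared at whichever level they share
terms.  Obsolete terms are dropped prior to expansion.  The comparative
analysis then runs over the *shared* terms — those annotating at least one
protein in each organism after expansion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import obonet

from .errors import ConfigError, DataError

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
DEFAULT_RELATIONS = ("is_a",)


@dataclass
class GoTerm:
    term_id: str
    name: str = ""
    namespace: str | None = None
    #: relation name -> parent term ids (child-to-parent direction)
    parents: dict[str, tuple[str, ...]] = field(default_factory=dict)
    obsolete: bool = False


class GoDag:
    """Ontology terms plus the relation set used for traversal.

    Construction validates that every referenced parent exists, that edges in
    the traversal relations never cross namespaces, and that the traversal
    graph is acyclic.
    """

    def __init__(
        self,
        terms: Mapping[str, GoTerm],
        relations: Iterable[str] = DEFAULT_RELATIONS,
    ) -> None:
        self.terms: dict[str, GoTerm] = dict(terms)
        self.relations: tuple[str, ...] = tuple(relations)
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._validate()

    # -- container protocol -------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __iter__(self) -> Iterator[str]:
        return iter(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    # -- structure ----------------------------------------------------------

    def parents_of(self, term_id: str) -> tuple[str, ...]:
        """Direct parents of *term_id* under the traversal relations."""
        term = self._get(term_id)
        out: list[str] = []
        for rel in self.relations:
            out.extend(term.parents.get(rel, ()))
        return tuple(dict.fromkeys(out))

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Transitive parent closure, excluding the term itself (memoized)."""
        self._get(term_id)
        return self._ancestors_memo(term_id)

    def _ancestors_memo(self, term_id: str) -> frozenset[str]:
        cached = self._ancestor_cache.get(term_id)
        if cached is not None:
            return cached
        closure: set[str] = set()
        for parent in self.parents_of(term_id):
            closure.add(parent)
            closure |= self._ancestors_memo(parent)
        result = frozenset(closure)
        self._ancestor_cache[term_id] = result
        return result

    def roots(self, namespace: str | None = None) -> list[str]:
        """Terms without parents (optionally restricted to one namespace)."""
        return sorted(
            tid
            for tid, term in self.terms.items()
            if not self.parents_of(tid)
            and not term.obsolete
            and (namespace is None or term.namespace == namespace)
        )

    def _get(self, term_id: str) -> GoTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise DataError(f"unknown GO term {term_id!r}") from None

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for tid, term in self.terms.items():
            for rel in self.relations:
                for parent in term.parents.get(rel, ()):
                    if parent not in self.terms:
                        raise DataError(
                            f"term {tid!r}: dangling parent {parent!r} ({rel})"
                        )
                    pns = self.terms[parent].namespace
                    if (
                        term.namespace is not None
                        and pns is not None
                        and term.namespace != pns
                    ):
                        raise DataError(
                            f"cross-namespace edge {tid!r} ({term.namespace}) "
                            f"-> {parent!r} ({pns}) rejected"
                        )
                    graph.add_edge(tid, parent)
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[0][0]}"
        raise DataError(f"ontology contains a cycle: {path}")


def parse_obo(
    path: str | Path, relations: Iterable[str] = DEFAULT_RELATIONS
) -> GoDag:
    """Parse an OBO 1.2-style file into a :class:`GoDag`.

    Recognised stanza tags: ``id``, ``name``, ``namespace``, ``is_a``,
    ``relationship`` (e.g. ``part_of``), ``is_obsolete``.  Obsolete terms are
    retained in the DAG but flagged, so annotation cleaning can drop them
    explicitly.
    """
    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    dangling = sorted(tid for tid, data in graph.nodes(data=True) if not data)
    if dangling:
        raise DataError(f"{path}: dangling parent reference(s): {dangling[:10]}")
    terms: dict[str, GoTerm] = {}
    for tid, data in graph.nodes(data=True):
        parents: dict[str, list[str]] = {}
        for parent in data.get("is_a", []):
            parents.setdefault("is_a", []).append(parent)
        for entry in data.get("relationship", []):
            rel, _, target = entry.partition(" ")
            if target:
                parents.setdefault(rel, []).append(target.strip())
        terms[tid] = GoTerm(
            term_id=tid,
            name=data.get("name", ""),
            namespace=data.get("namespace"),
            parents={rel: tuple(ps) for rel, ps in parents.items()},
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
        )
    if not terms:
        raise DataError(f"{path}: no [Term] stanzas found")
    return GoDag(terms, relations)


def ancestors(dag: GoDag, term_id: str) -> frozenset[str]:
    """Module-level convenience for :meth:`GoDag.ancestors`."""
    return dag.ancestors(term_id)


@dataclass
class AnnotationSet:
    """Protein-to-term annotations for one organism."""

    organism_label: str
    prot2terms: dict[str, frozenset[str]]
    expanded: bool = False

    def __post_init__(self) -> None:
        self.prot2terms = {
            pid: frozenset(ts) for pid, ts in self.prot2terms.items()
        }
        self._term2prots: dict[str, frozenset[str]] | None = None

    @property
    def term2prots(self) -> dict[str, frozenset[str]]:
        """Inverted index term -> annotated proteins (computed lazily)."""
        if self._term2prots is None:
            inv: dict[str, set[str]] = {}
            for pid, terms in self.prot2terms.items():
                for tid in terms:
                    inv.setdefault(tid, set()).add(pid)
            self._term2prots = {t: frozenset(ps) for t, ps in inv.items()}
        return self._term2prots

    def terms(self) -> frozenset[str]:
        return frozenset(self.term2prots)

    def proteins_for(self, term_id: str) -> frozenset[str]:
        return self.term2prots.get(term_id, frozenset())

    def n_annotated_proteins(self) -> int:
        return sum(1 for ts in self.prot2terms.values() if ts)


def read_annotations(
    path: str | Path, organism_label: str, fmt: str = "auto"
) -> AnnotationSet:
    """Read protein->GO annotations from a GAF 2.x or 2-column TSV file.

    GAF: column 2 is the protein id, column 5 the GO id; comment lines start
    with ``!`` and rows whose qualifier (column 4) contains ``NOT`` are
    dropped.  TSV: ``protein_id<TAB>term_id`` with optional ``#`` comments and
    an optional header row.
    """
    path = Path(path)
    if fmt == "auto":
        with open(path) as handle:
            first = handle.readline()
        fmt = "gaf" if first.startswith("!") or len(first.split("\t")) >= 15 else "tsv"
    prot2terms: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("!"):
                continue
            cols = line.split("\t")
            if fmt == "gaf":
                if len(cols) < 5:
                    raise DataError(f"{path}: line {lineno}: too few GAF columns")
                if "NOT" in cols[3].split("|"):
                    continue
                pid, tid = cols[1], cols[4]
            else:
                if len(cols) < 2:
                    raise DataError(f"{path}: line {lineno}: expected 2 columns")
                pid, tid = cols[0], cols[1]
                if not tid.startswith("GO:") and lineno == 1:
                    continue  # header row
            prot2terms.setdefault(pid, set()).add(tid)
    if not prot2terms:
        raise DataError(f"{path}: no annotation rows found")
    return AnnotationSet(
        organism_label, {p: frozenset(ts) for p, ts in prot2terms.items()}
    )


def expand_annotations(
    dag: GoDag, raw: AnnotationSet, on_unknown: str = "warn"
) -> AnnotationSet:
    """Close each protein's term set under the ancestor relation.

    Annotations to obsolete terms are removed before expansion; annotations to
    terms absent from the DAG are dropped with a warning (``on_unknown="warn"``,
    the default, tolerant of release mismatches) or raise
    (``on_unknown="error"``).  The operation is idempotent and otherwise
    monotone: it never removes a valid annotation.
    """
    if on_unknown not in ("warn", "error"):
        raise ConfigError(f"on_unknown must be 'warn' or 'error', got {on_unknown!r}")
    unknown: set[str] = set()
    expanded: dict[str, frozenset[str]] = {}
    for pid, terms in raw.prot2terms.items():
        closed: set[str] = set()
        for tid in terms:
            if tid not in dag:
                unknown.add(tid)
                continue
            if dag.terms[tid].obsolete:
                continue
            closed.add(tid)
            closed |= dag.ancestors(tid)
        expanded[pid] = frozenset(closed)
    if unknown:
        if on_unknown == "error":
            raise DataError(f"annotations to unknown terms: {sorted(unknown)[:10]}")
        warnings.warn(
            f"{raw.organism_label}: dropped annotations to "
            f"{len(unknown)} unknown term(s)",
            stacklevel=2,
        )
    return AnnotationSet(raw.organism_label, expanded, expanded=True)


def shared_terms(a: AnnotationSet, b: AnnotationSet) -> frozenset[str]:
    """Terms annotating at least one protein in each of two expanded sets."""
    if not (a.expanded and b.expanded):
        raise DataError("shared_terms requires expanded annotation sets")
    return a.terms() & b.terms()
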