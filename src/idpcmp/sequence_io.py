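"""Proteome FASTA input and dataset filtering.

A proteome is read as an ordered collection of :class:`ProteinRecord`.  Before
any disorder prediction the record set is cleaned with the same rules used for
proteome-scale disorder surveys: exact-duplicate sequences, fragments, and
sequences containing residues outside the 20 standard amino acids are removed,
because such sequences are not tractable by (or bias) per-residue disorder
predictors.  Selenocysteine (U) and pyrrolysine (O) count as non-standard;
B, X, Z and J are treated as ambiguity codes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

from Bio import SeqIO

from .errors import ConfigError, DataError

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
NONSTANDARD_RESIDUES = frozenset("UO")
AMBIGUOUS_RESIDUES = frozenset("BXZJ")

#: Recognised filter rules, in the order they are applied to each record.
FILTER_RULES = ("duplicate", "fragment", "nonstandard", "ambiguous")

DEFAULT_FRAGMENT_MARKER = "(Fragment)"

_GENE_RE = re.compile(r"\bGN=(\S+)")


@dataclass
class ProteinRecord:
    """One identified amino-acid sequence."""

    protein_id: str
    sequence: str
    gene_id: str | None = None
    is_fragment: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"protein {self.protein_id!r}: empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """Ordered, uniquely identified protein records of one organism."""

    organism_label: str
    records: list[ProteinRecord] = field(default_factory=list)
    filtered: bool = False

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.protein_id in seen:
                raise DataError(
                    f"duplicate protein_id {rec.protein_id!r} in proteome "
                    f"{self.organism_label!r}"
                )
            seen.add(rec.protein_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.protein_id for r in self.records]

    def get(self, protein_id: str) -> ProteinRecord:
        for rec in self.records:
            if rec.protein_id == protein_id:
                return rec
        raise KeyError(protein_id)


@dataclass
class FilterReport:
    """Bookkeeping for :func:`filter_proteome`.

    ``input_total == output_total + sum(removed.values())`` always holds.
    """

    input_total: int
    output_total: int
    removed: dict[str, int]

    def __post_init__(self) -> None:
        if self.input_total != self.output_total + sum(self.removed.values()):
            raise DataError("filter report does not conserve record counts")

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_total": self.input_total,
                "output_total": self.output_total,
                "removed": dict(sorted(self.removed.items())),
            },
            indent=2,
        )


def read_fasta(
    path: str | Path,
    organism_label: str | None = None,
    fragment_marker: str = DEFAULT_FRAGMENT_MARKER,
) -> Proteome:
    """Read a FASTA file into a :class:`Proteome`.

    The first whitespace-delimited token of each header is the ``protein_id``.
    A header containing *fragment_marker* flags the record as a fragment; a
    UniProt-style ``GN=`` token, when present, fills ``gene_id``.
    """
    path = Path(path)
    _check_fasta_syntax(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        pid = seq_rec.id
        if pid in seen:
            raise DataError(f"{path}: duplicate protein_id {pid!r}")
        seen.add(pid)
        gene_match = _GENE_RE.search(seq_rec.description)
        records.append(
            ProteinRecord(
                protein_id=pid,
                sequence=str(seq_rec.seq),
                gene_id=gene_match.group(1) if gene_match else None,
                is_fragment=fragment_marker in seq_rec.description,
            )
        )
    if not records:
        raise DataError(f"{path}: no FASTA records found")
    return Proteome(organism_label or path.stem, records)


def _check_fasta_syntax(path: Path) -> None:
    """Reject empty files and files whose first record line is not a header."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise DataError(
                    f"{path}: line {lineno}: expected FASTA header starting "
                    f"with '>', got {line.strip()[:40]!r}"
                )
            return
    raise DataError(f"{path}: empty FASTA file")


def _residue_violation(sequence: str, alphabet: frozenset[str]) -> bool:
    return any(ch in alphabet for ch in sequence)


def filter_proteome(
    proteome: Proteome,
    rules: Sequence[str] = FILTER_RULES,
) -> tuple[Proteome, FilterReport]:
    """Apply dataset cleaning rules, returning the surviving proteome.

    Rules (any subset of :data:`FILTER_RULES`):

    duplicate
        Identical full amino-acid sequence to an earlier record; the first
        occurrence is kept.
    fragment
        Record flagged ``is_fragment`` at parse time.
    nonstandard
        Sequence contains U or O.
    ambiguous
        Sequence contains B, X, Z or J.

    A record matching several rules is counted once, under the first matching
    rule in :data:`FILTER_RULES` order.  Surviving records keep input order,
    so the operation is idempotent.
    """
    unknown = set(rules) - set(FILTER_RULES)
    if unknown:
        raise ConfigError(f"unknown filter rules: {sorted(unknown)}")
    active = [r for r in FILTER_RULES if r in rules]
    removed = {rule: 0 for rule in active}
    survivors: list[ProteinRecord] = []
    seen_sequences: set[str] = set()
    for rec in proteome.records:
        rule = _first_violation(rec, active, seen_sequences)
        if rule is None:
            survivors.append(rec)
            seen_sequences.add(rec.sequence)
        else:
            removed[rule] += 1
    out = Proteome(proteome.organism_label, survivors, filtered=True)
    report = FilterReport(
        input_total=len(proteome), output_total=len(out), removed=removed
    )
    return out, report


def _first_violation(
    rec: ProteinRecord, active: list[str], seen_sequences: set[str]
) -> str | None:
    for rule in active:
        if rule == "duplicate" and rec.sequence in seen_sequences:
            return rule
        if rule == "fragment" and rec.is_fragment:
            return rule
        if rule == "nonstandard" and _residue_violation(
            rec.sequence, NONSTANDARD_RESIDUES
        ):
            return rule
        if rule == "ambiguous" and _residue_violation(
            rec.sequence, AMBIGUOUS_RESIDUES
        ):
            return rule
    return None
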