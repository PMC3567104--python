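"""Ortholog-restricted validation of class-level disorder differences.

GO annotation depth differs between model organisms, so a class can look more
disordered in one organism purely through annotation bias.  The control:
restrict each significant class to cross-organism ortholog pairs, average a
disorder metric over each side's members, and test across classes whether the
difference persists — a two-tailed t-test for any difference and a one-tailed
t-test for the alternative that organism A's orthologs are more disordered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .disorder import DisorderMetrics
from .errors import ConfigError, DataError
from .go_ontology import AnnotationSet


@dataclass
class OrthologPair:
    protein_id_a: str
    protein_id_b: str
    group: str | None = None
    score: float | None = None


@dataclass
class OrthologMap:
    """Cross-organism ortholog pairs (e.g. an InParanoid-derived table)."""

    pairs: list[OrthologPair]

    def __len__(self) -> int:
        return len(self.pairs)

    def resolve(
        self, ids_a: Iterable[str], ids_b: Iterable[str]
    ) -> "OrthologMap":
        """Drop pairs whose members are missing from the proteomes (warned)."""
        set_a, set_b = set(ids_a), set(ids_b)
        kept = [
            p
            for p in self.pairs
            if p.protein_id_a in set_a and p.protein_id_b in set_b
        ]
        dropped = len(self.pairs) - len(kept)
        if dropped:
            warnings.warn(
                f"dropped {dropped} ortholog pair(s) with unresolvable ids",
                stacklevel=2,
            )
        return OrthologMap(kept)


def read_orthologs(path: str | Path) -> OrthologMap:
    """Read an ortholog TSV with columns id_a, id_b[, group[, score]].

    A header row is detected by a non-numeric fourth column or the literal
    column names; ``#`` comment lines are skipped.
    """
    path = Path(path)
    pairs: list[OrthologPair] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise DataError(f"{path}: line {lineno}: expected >= 2 columns")
            if lineno == 1 and cols[0].lower() in ("id_a", "protein_id_a"):
                continue
            score: float | None = None
            if len(cols) >= 4 and cols[3] != "":
                try:
                    score = float(cols[3])
                except ValueError as exc:
                    raise DataError(f"{path}: line {lineno}: bad score") from exc
            pairs.append(
                OrthologPair(
                    protein_id_a=cols[0],
                    protein_id_b=cols[1],
                    group=cols[2] if len(cols) >= 3 and cols[2] else None,
                    score=score,
                )
            )
    if not pairs:
        raise DataError(f"{path}: no ortholog pairs found")
    return OrthologMap(pairs)


@dataclass
class ClassOrthologSummary:
    """Mean disorder of the ortholog pairs retained for one GO class."""

    term_id: str
    n_pairs: int
    mean_disorder_a: float | None
    mean_disorder_b: float | None
    a_greater: bool | None


@dataclass
class OrthologTestReport:
    mode: str
    metric_field: str
    n_classes: int
    n_a_greater: int
    grand_mean_a: float
    grand_mean_b: float
    t_two_sided: float
    p_two_sided: float
    t_one_sided: float
    p_one_sided: float


def class_ortholog_summary(
    term_id: str,
    ortholog_map: OrthologMap,
    metrics_a: Mapping[str, DisorderMetrics],
    metrics_b: Mapping[str, DisorderMetrics],
    annotations_a: AnnotationSet,
    annotations_b: AnnotationSet,
    metric_field: str = "pct_disordered",
    membership: str = "either",
) -> ClassOrthologSummary:
    """Average *metric_field* over the ortholog pairs belonging to a class.

    ``membership="either"`` (default) retains a pair when at least one member
    is annotated to the term; ``"both"`` requires both.  Pairs lacking metrics
    on either side are skipped.  A class without retained pairs yields an
    explicit ``n_pairs=0`` summary with undefined means.
    """
    if membership not in ("either", "both"):
        raise ConfigError(
            f"membership must be 'either' or 'both', got {membership!r}"
        )
    prots_a = annotations_a.proteins_for(term_id)
    prots_b = annotations_b.proteins_for(term_id)
    vals_a: list[float] = []
    vals_b: list[float] = []
    for pair in ortholog_map.pairs:
        in_a = pair.protein_id_a in prots_a
        in_b = pair.protein_id_b in prots_b
        keep = (in_a or in_b) if membership == "either" else (in_a and in_b)
        if not keep:
            continue
        ma = metrics_a.get(pair.protein_id_a)
        mb = metrics_b.get(pair.protein_id_b)
        if ma is None or mb is None:
            continue
        va = getattr(ma, metric_field)
        vb = getattr(mb, metric_field)
        if va is None or vb is None:
            continue
        vals_a.append(float(va))
        vals_b.append(float(vb))
    if not vals_a:
        return ClassOrthologSummary(term_id, 0, None, None, None)
    mean_a = float(np.mean(vals_a))
    mean_b = float(np.mean(vals_b))
    return ClassOrthologSummary(
        term_id, len(vals_a), mean_a, mean_b, mean_a > mean_b
    )


def ortholog_t_tests(
    summaries: Sequence[ClassOrthologSummary],
    mode: str = "paired",
    metric_field: str = "pct_disordered",
) -> OrthologTestReport:
    """Test class-level mean disorder across organisms.

    ``paired`` (default) treats each class's (mean_a, mean_b) as a matched
    pair; ``welch`` compares the two collections of class means as independent
    samples with unequal variances.  The one-sided alternative is that
    organism A is more disordered.  Classes with zero retained pairs are
    excluded; at least two usable classes are required.
    """
    if mode not in ("paired", "welch"):
        raise ConfigError(f"mode must be 'paired' or 'welch', got {mode!r}")
    usable = [s for s in summaries if s.n_pairs > 0]
    if len(usable) < 2:
        raise DataError(
            f"ortholog_t_tests needs >= 2 classes with orthologs, got {len(usable)}"
        )
    a = np.array([s.mean_disorder_a for s in usable], dtype=float)
    b = np.array([s.mean_disorder_b for s in usable], dtype=float)
    if mode == "paired":
        if np.ptp(a - b) == 0 and (a - b)[0] == 0:
            # all class differences exactly zero: t is 0 by convention
            return OrthologTestReport(
                mode=mode, metric_field=metric_field, n_classes=len(usable),
                n_a_greater=0, grand_mean_a=float(a.mean()),
                grand_mean_b=float(b.mean()), t_two_sided=0.0, p_two_sided=1.0,
                t_one_sided=0.0, p_one_sided=0.5,
            )
        two = stats.ttest_rel(a, b)
        one = stats.ttest_rel(a, b, alternative="greater")
    else:
        two = stats.ttest_ind(a, b, equal_var=False)
        one = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return OrthologTestReport(
        mode=mode,
        metric_field=metric_field,
        n_classes=len(usable),
        n_a_greater=sum(1 for s in usable if s.a_greater),
        grand_mean_a=float(a.mean()),
        grand_mean_b=float(b.mean()),
        t_two_sided=float(two.statistic),
        p_two_sided=float(two.pvalue),
        t_one_sided=float(one.statistic),
        p_one_sided=float(one.pvalue),
    )
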